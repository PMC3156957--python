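# Methods

This note documents the statistical model behind each pipeline stage, the
generative model of the synthetic cohort, the numerical and design choices
that were genuinely open, and the limits of what the synthetic tests show.

## Study design being modelled

A quantitative trait (BMI, kg/m²) is dichotomized by extreme-tail sampling:
cases are individuals at or above `case_threshold` (default 40), controls at
or below `control_threshold` (default 30), drawn from a population whose
trait is approximately Normal (default mean 35, SD 7). Two candidate-gene
intervals (default 188 kb total) are deeply re-sequenced in 142 cases and
147 controls; association is tested per variant for common alleles and by
rare-variant collapsing for the rest.

## Variant quality control

SNV filtering is a fixed, logged cascade:

1. **Biallelic restriction.** Sites with more than one alternative allele
   are excluded from association and reported separately with the number of
   samples carrying any non-reference allele.
2. **HWE in controls.** The 1-df chi-square statistic
   Σ(obs−exp)²/exp over the three genotype classes, with expectations from
   the observed allele frequency; sites with *P* < 10⁻³ in the raw control
   genotypes are dropped. Monomorphic sites return (stat 0, *P* 1) rather
   than dividing by zero. An exact conditional test (enumeration over
   heterozygote counts) is available as an option, but the filter uses the
   chi-square: the pipeline's concordance reports quote chi-square
   statistics, and at these sample sizes the two agree except at very small
   minor-allele counts, where the rare-variant machinery, not the HWE
   filter, is the relevant guard.
3. **Genotype masking.** Calls with depth < 3 reads or phred consensus
   quality < 10 become missing. Thresholds are strict-less-than (a call at
   exactly 3 reads / phred 10 survives); masking is idempotent.
4. **Call rate.** Sites with < 90% called genotypes over *all* samples
   (cases + controls) after masking are dropped; the 0.9 bound is
   inclusive.

HWE is deliberately computed *before* masking (the order is part of the
contract and is logged); we do not re-test HWE on the masked genotypes.
Minor allele frequency is always computed over called alleles only, so a
site's MAF can change as masking removes calls.

## Indel genotyping

Indels come as per-sample candidates (position, signed length, allele
sequence) plus per-sample read support. Candidates are left-normalized
against the local reference sequence (shift left while the preceding base
equals the last allele base) and merged when identical in (position,
length, sequence); candidates with the same allele whose normalized
positions fall inside one homopolymer or di-nucleotide run also merge, with
the cluster anchored at the leftmost member. Without a reference sequence
only exact duplicates merge — the run extent cannot be known.

Genotypes come from the proportion *p* of indel-supporting reads:
heterozygous for 0.2 ≤ *p* ≤ 0.8 (the band boundaries are assigned to the
heterozygote and are configurable constants), homozygous reference below,
homozygous alternative above, missing at zero coverage. At ≥ 20× depth the
binomial tails put > 99.7% of true heterozygotes inside the band.

Site-level support requires at least one sample with ≥ 3 indel reads out of
≥ 8 covering reads; rare indels (MAF < 0.01, computed from the
proportion-based genotypes *before* the support filter) need ≥ 5 of ≥ 10.
Surviving sites face the same control-sample HWE filter as SNVs.

## Single-marker association

Per site the allelic 2×2 table (minor vs other allele × case vs control) is
counted over called genotypes, with the minor allele defined cohort-wide.
The statistic is the 1-df chi-square without continuity correction,
`N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`; the odds ratio is (a/b)/(c/d), with the
Haldane 0.5 correction applied (and flagged) only when a cell is zero.

Multiple testing is handled by max(T) permutation: case/control labels are
permuted preserving group sizes; each sample's whole genotype vector moves
with its label, which preserves LD between sites; missing genotypes stay
missing, so per-site denominators are recomputed in every permutation. The
per-site *P* is `(1 + #{perm max statistic ≥ observed}) / (n_perm + 1)` —
the +1 convention avoids zero *P* at finite permutation counts. The default
is 5,000 permutations.

## RareCover collapsing test

Windows of `window_size` (default 5,000 bp) are anchored at every rare
variant (cohort-wide MAF ≤ 0.1, indels excluded): S is all rare variants in
[pos, pos + window); windows with identical member sets collapse to the
leftmost anchor. The union-variant A_C of a subset C ⊆ S is 1 for samples
carrying ≥ 1 minor allele at any member; samples missing at every member
count as non-carriers (conservative) and their number is reported so users
can exclude them instead.

**Subset selection.** The optimal C maximizing the carrier-table chi-square
is approximated by forward greedy selection with strict improvement,
ties broken to the leftmost position. Because the 2×2 chi-square is
two-sided, a single greedy pass commits to the enrichment direction of its
first pick and can miss a control-enriched optimum in null windows; the
selection therefore runs one strict-improvement pass per enrichment
direction (candidate tables leaning the wrong way score negatively) and
keeps the larger statistic. Against the exhaustive-enumeration oracle
(all non-empty subsets, ties to the smallest then leftmost subset, refused
above 20 members) the greedy statistic matches in ≈ 97% of random
8-variant/60-sample instances drawn from the generator's rare-allele
spectrum and never exceeds it; disagreements are within-direction local
optima and the greedy value is a lower bound.

**Significance.** Locus *P* comes from label permutations that *re-run the
subset selection* inside every permutation — freezing the observed C is
anti-conservative, because the observed statistic carries selection bias
that the frozen null does not (a regression test demonstrates this on null
data). Gene-wide *P* applies the same permutations to every window of the
gene and compares each observed statistic to the permutation distribution
of the max over windows. Defaults are 10⁴ locus and 10⁶ gene-wide
permutations (full-scale analysis); the CLI exposes reduced counts for
desk-scale runs, and the acceptance checks use reduced counts (500–2,000)
with problem sizes of 8–12 kb intervals.

The permutation engine is vectorized across permutations (boolean union
tensors of shape perms × samples × candidates, processed in batches), which
keeps 10³–10⁴ re-optimized permutations per window at interactive speed.

## Concordance QC

Replicate genotype pairs are classified as: 1 concordant; 2 het vs hom-alt;
3 het vs hom-ref *with* the alternative allele present as the second most
likely raw consensus call (near-pass — rescuable by better calling);
4 het vs hom-ref without such evidence; 5 disagreement at a position
covered < 20× in either replicate. Status 5 pre-empts 2–4 (low coverage
explains the disagreement); classification is symmetric in the replicates;
pairs with a missing genotype are excluded from the taxonomy and counted
separately; hom-ref vs hom-alt disagreements (not covered by the taxonomy)
are grouped with status 2. Two disagreement groupings are always reported:
allele under-calling (statuses 3+2) and random miscalls (statuses 4+5).

Platform comparison counts, per shared site, genotypes where sequencing
shows fewer (under-call) or more (over-call) alternative alleles than the
orthogonal platform, or no call (N/N); both platforms get a per-site HWE
statistic, and any known variant within 50 bp of the assay site is flagged
as a potential hidden variant (systematic assay errors cluster at such
sites).

## Metabolite contrasts

Samples are partitioned by locus-variant carrier status × case/control;
unmeasured samples are dropped per metabolite (the two metabolites' group
sizes may differ). The contrast of interest — carrier cases vs non-carrier
controls — uses the pooled-variance two-sided *t*-test from group
summaries: sp² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2), df = n₁+n₂−2. The
pooled two-sided flavor reproduces published worked-example *P*-values from
rounded summaries where an unequal-variance test does not, and is the
default; percent difference is 100·(m₁−m₂)/m₂ with the non-carrier-control
mean as reference, reported unrounded and at integer precision.

## Synthetic cohort generator

The generator emulates the *structure* of the study data, not its sequence
content:

- **LD blocks.** Common variants live on founder haplotypes
  (`founder_haplotypes_per_block`, default 16) split into two clades per
  block; sites tag the clade partition with 8% per-founder flip noise and
  random orientation, and each sample haplotype copies one founder per
  block independently. This yields strong LD within a block (mean adjacent
  |r| ≈ 0.6) and none across the boundary, emulating a recombination
  hotspot, at negligible cost. A coalescent simulator would add realism
  (LD decay with distance) the analysis stages do not exploit.
- **Rare spectrum.** Independent rare sites get minor-allele counts of 1
  (singletons, with probability calibrated so singletons are
  `singleton_mass` ≈ 37% of all sites) or 2 + geometric, capped at
  MAF 0.1; alleles are placed on chromosomes uniformly, so neutral sites
  sit at HWE by construction. Defaults (3.3 common + 4.1 rare sites per
  kb over 188 kb) give ≈ 1,400 polymorphic sites with ≈ 55% below 1% MAF.
- **Planted causal window.** `n_causal` variants (default 15) in a 5-kb
  window; each carrier holds one heterozygous causal allele. Carrier
  prevalence is solved in closed form from the target number of carrier
  cases under the liability model BMI = Normal(bmi_base) +
  `carrier_bmi_shift`·carrier (default +10 kg/m²), followed by tail
  selection until the case and control quotas fill. With the default
  target of 23 carrier cases the implied prevalence is ≈ 5.7% and the
  expected carrier controls ≈ 0.6. The liability mechanism is the simplest
  one that makes tail sampling enrich carriers among cases.
- **Depth, quality, missingness.** Depth is negative-binomial (mean 60,
  size 8); quality is a monotone function of depth (4 phred per read,
  capped at 60). Missingness is realized mechanistically as low-depth
  no-calls at rate `missing_rate`. Causal carrier genotypes are exempt
  from the random mask so the truth record round-trips exactly through the
  emitted matrix; planted sites that end up with zero carriers are dropped
  from both the matrix and the truth record (a variant nobody carries is
  unobservable). Sites monomorphic in the sampled cohort are likewise
  dropped.
- **Replicates.** Error rates are per compared genotype pair; the drawn
  number of events per category is placed on randomly chosen eligible
  genotypes (well-covered heterozygotes for statuses 2–4, any well-covered
  call for status 5) and logged, so the replicate matrix differs from the
  original only at logged positions and classification round-trips the log
  exactly.
- **Metabolites.** Non-carriers ~ Normal(mean, sd) truncated at zero (by
  redraw); carriers have the mean scaled by `carrier_metabolite_multiplier`
  (default 1.24 for anandamide, 1.51 for the second metabolite).

What the generator does **not** emulate: read-level errors and alignment
artifacts (alt-evidence flags are planted, not derived from reads), GC- or
amplicon-driven coverage structure along the interval, LD decay within
blocks, population stratification, and relatedness. Tests passing on this
generator therefore validate the statistical machinery under its stated
assumptions, not robustness to those real-data pathologies.

## Numerical choices

- Permutation *P*-values use (R+1)/(B+1) throughout.
- Greedy improvement uses an absolute epsilon of 10⁻⁹ on the chi-square to
  keep tie-breaking deterministic under floating-point noise; permutation
  exceedance comparisons subtract 10⁻¹² before `>=`.
- Chi-square with any zero margin is defined as 0 (P = 1).
- Degenerate inputs fail loudly: empty control sets, sites with no called
  genotypes, groups with n < 2 in the t-test, unreachable sampling quotas
  (bounded at `max_draws` with the offending parameter named).
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit parameters; every CLI stage is byte-reproducible for a fixed
  seed, and outputs contain no timestamps.

## Known limitations

- The greedy subset statistic is a lower bound on the exhaustive optimum;
  on ~3% of small null windows it is strictly smaller. Since the same
  selection runs inside every permutation, locus *P*-values remain
  calibrated, but the reported C can be locally rather than globally
  optimal.
- Gene-wide correction at the full 10⁶ permutations is computationally
  heavy for genome-scale window counts; it is intended for one or two
  candidate-gene intervals.
- Overlapping significant windows are all reported; merging them into
  distinct associated intervals is narrative, not algorithmic, and is left
  to the user.
- The indel caller genotypes each sample against the clustered allele only;
  samples whose reads support two different indel alleles at one site are
  not modelled.
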