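"""Synthetic extreme-phenotype cohort generator.

Emulates the data structure of a targeted re-sequencing association study of
BMI extremes: a genotype matrix over two LD blocks separated by a
recombination break (haplotype copying from founder haplotypes), a skewed
rare-variant frequency spectrum with a controllable singleton fraction, a
planted causal rare-variant window acting on BMI through a Normal liability
model with additive carrier shift followed by tail selection, per-genotype
depth/quality, random missingness, replicate pairs with injected error
categories, indel read-support observations, and carrier-elevated metabolite
levels.  A truth record supports parameter-recovery tests.

All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix, VariantSite
from .rarecover import union_carrier

QUALITY_CAP = 60
QUALITY_PER_READ = 4  # phred points per supporting read, capped


@dataclass(frozen=True)
class PlantedWindow:
    """A causal rare-variant window: the union of its variants shifts BMI."""

    start: int
    n_causal: int = 15
    target_carrier_cases: int = 23
    target_carrier_controls: int = 0
    span: int = 5000


@dataclass
class SimulationParams:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the emulated study conditions: 142 cases sampled at
    BMI >= 40 and 147 controls at BMI <= 30 from a Normal(35, 7) kg/m^2
    population, ~1,400 variant sites over 188 kb with ~37% singletons and a
    majority of sites below 1% MAF, two LD blocks, and a planted 15-variant
    window whose union is carried by ~23 cases and ~0 controls.
    """

    n_cases: int = 142
    n_controls: int = 147
    chrom: str = "chr3"
    interval_length: int = 188_000
    n_blocks: int = 2
    founder_haplotypes_per_block: int = 16
    common_site_rate: float = 3.3  # sites per kb, LD-block sites
    rare_site_rate: float = 4.1  # sites per kb, independent rare sites
    singleton_mass: float = 0.37  # target fraction of all sites that are singletons
    planted_window: Optional[PlantedWindow] = field(
        default_factory=lambda: PlantedWindow(start=60_000)
    )
    bmi_base: tuple[float, float] = (35.0, 7.0)  # population mean, sd (kg/m^2)
    carrier_bmi_shift: float = 10.0  # kg/m^2 added to carrier liability
    case_threshold: float = 40.0
    control_threshold: float = 30.0
    missing_rate: float = 0.01
    depth_model: tuple[float, float] = (60.0, 8.0)  # negative binomial mean, size
    metabolite_base: tuple[float, float] = (13.76, 5.5)  # AEA pmol/ml mean, sd
    carrier_metabolite_multiplier: float = 1.24
    metabolite2_base: tuple[float, float] = (6.98, 4.15)  # 2-AG pmol/ml mean, sd
    carrier_metabolite2_multiplier: float = 1.51
    seed: int = 0
    max_draws: int = 500_000

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_blocks", "founder_haplotypes_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("singleton_mass", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.case_threshold <= self.control_threshold:
            raise ValueError("case_threshold must exceed control_threshold")
        if self.carrier_metabolite_multiplier <= 0:
            raise ValueError("carrier_metabolite_multiplier must be > 0")
        if self.planted_window is not None:
            w = self.planted_window
            if w.start < 1 or w.start + w.span > self.interval_length:
                raise ValueError("planted_window must lie fully inside the interval")
            if w.n_causal < 1:
                raise ValueError("planted_window.n_causal must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    causal_variant_positions: list[int]
    carrier: np.ndarray  # per-sample flag, 1 iff >=1 minor allele at >=1 causal variant
    liability_bmi: np.ndarray  # per-sample BMI before tail selection


@dataclass
class TruthErrorLog:
    """Injected replicate discrepancies: (sample index, site index, status)."""

    events: list[tuple[int, int, int]] = field(default_factory=list)


def carrier_prevalence(params: SimulationParams) -> float:
    """Population carrier prevalence implied by the planted carrier-case target.

    Under the liability model, BMI ~ Normal(mu + shift * carrier, sigma) and
    cases are the upper tail.  Solving
    ``target / n_cases = P(carrier | case)`` for the prevalence pi gives
    ``pi / (1 - pi) = q * P(case | non-carrier) / ((1 - q) * P(case | carrier))``
    with q the target carrier fraction among cases.
    """
    w = params.planted_window
    if w is None:
        return 0.0
    mu, sigma = params.bmi_base
    q = w.target_carrier_cases / params.n_cases
    if not 0 < q < 1:
        raise ValueError("target_carrier_cases must be strictly between 0 and n_cases")
    p_case_carrier = stats.norm.sf(params.case_threshold, mu + params.carrier_bmi_shift, sigma)
    p_case_noncarrier = stats.norm.sf(params.case_threshold, mu, sigma)
    if p_case_carrier <= 0:
        raise ValueError("carrier liability cannot reach case_threshold; check bmi_base")
    odds = q * p_case_noncarrier / ((1 - q) * p_case_carrier)
    return odds / (1 + odds)


def _sample_phenotypes(params: SimulationParams, rng: np.random.Generator):
    """Draw individuals until the case and control quotas are filled.

    Returns (carrier flags, liability BMI, case flag) for the selected
    samples, cases first.  Raises if the quotas are unreachable within
    ``max_draws`` draws.
    """
    mu, sigma = params.bmi_base
    pi = carrier_prevalence(params)
    cases_c, cases_b = [], []
    ctrls_c, ctrls_b = [], []
    drawn = 0
    batch = 2048
    while (len(cases_c) < params.n_cases or len(ctrls_c) < params.n_controls):
        if drawn >= params.max_draws:
            missing = "n_cases/case_threshold" if len(cases_c) < params.n_cases else (
                "n_controls/control_threshold"
            )
            raise RuntimeError(
                f"could not fill {missing} within max_draws={params.max_draws}; "
                "check bmi_base and the thresholds"
            )
        carrier = rng.random(batch) < pi
        bmi = rng.normal(mu, sigma, batch) + params.carrier_bmi_shift * carrier
        drawn += batch
        for c, b in zip(carrier, bmi):
            if b >= params.case_threshold and len(cases_c) < params.n_cases:
                cases_c.append(bool(c))
                cases_b.append(float(b))
            elif b <= params.control_threshold and len(ctrls_c) < params.n_controls:
                ctrls_c.append(bool(c))
                ctrls_b.append(float(b))
    carrier = np.array(cases_c + ctrls_c, dtype=bool)
    bmi = np.array(cases_b + ctrls_b, dtype=float)
    is_case = np.zeros(carrier.size, dtype=bool)
    is_case[: params.n_cases] = True
    return carrier, bmi, is_case


def _block_genotypes(params: SimulationParams, rng: np.random.Generator, n: int):
    """LD-block sites via haplotype copying from two founder clades per block.

    Every founder haplotype belongs to one of two clades; common sites tag
    the clade partition (with per-founder flip noise), so sites within a
    block are in strong LD while blocks are independent (the block boundary
    emulates a recombination break).
    """
    L = params.interval_length
    F = params.founder_haplotypes_per_block
    bounds = np.linspace(0, L, params.n_blocks + 1).astype(int)
    n_common = rng.poisson(params.common_site_rate * L / 1000)
    positions = np.sort(rng.choice(np.arange(1, L + 1), size=min(n_common, L), replace=False))
    genotypes = np.zeros((n, positions.size), dtype=np.int8)
    flip_noise = 0.08
    for b in range(params.n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        in_block = (positions > lo) & (positions <= hi)
        k = int(in_block.sum())
        if k == 0:
            continue
        clade_freq = rng.uniform(0.25, 0.75)
        clade = rng.random(F) < clade_freq
        if clade.all() or not clade.any():
            clade[0] = not clade[0]
        # founder allele columns: clade partition with flip noise, random orientation
        alleles = np.repeat(clade[:, None], k, axis=1)
        alleles ^= rng.random((F, k)) < flip_noise
        orient = rng.random(k) < 0.5
        alleles ^= orient[None, :]
        hapA = rng.integers(0, F, size=n)
        hapB = rng.integers(0, F, size=n)
        genotypes[:, in_block] = alleles[hapA].astype(np.int8) + alleles[hapB].astype(np.int8)
    return positions, genotypes


def _rare_genotypes(params: SimulationParams, rng: np.random.Generator, n: int, n_common: int):
    """Independent rare sites: singletons plus a skewed low-count spectrum."""
    L = params.interval_length
    n_rare = rng.poisson(params.rare_site_rate * L / 1000)
    if n_rare == 0:
        return np.array([], dtype=int), np.zeros((n, 0), dtype=np.int8)
    positions = np.sort(rng.choice(np.arange(1, L + 1), size=min(n_rare, L), replace=False))
    p_singleton = min(1.0, params.singleton_mass * (n_common + n_rare) / n_rare)
    genotypes = np.zeros((n, positions.size), dtype=np.int8)
    max_count = max(2, int(0.1 * 2 * n))
    for j in range(positions.size):
        if rng.random() < p_singleton:
            m = 1
        else:
            m = min(1 + int(rng.geometric(0.45)), max_count)
        chroms = rng.choice(2 * n, size=m, replace=False)
        np.add.at(genotypes[:, j], chroms // 2, 1)
    return positions, genotypes


def simulate_cohort(
    params: SimulationParams,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """Generate a full synthetic cohort: genotypes, sample table, truth record.

    See the module docstring for the generative model.  The returned sample
    table has columns sample_id, sex, age, bmi, group, aea_pmol_ml,
    ag2_pmol_ml; the matrix carries per-genotype depth and quality with
    missingness realized as low-depth no-calls.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_cases + params.n_controls

    carrier, bmi, is_case = _sample_phenotypes(params, rng)

    common_pos, common_g = _block_genotypes(params, rng, n)
    rare_pos, rare_g = _rare_genotypes(params, rng, n, common_pos.size)

    causal_pos = np.array([], dtype=int)
    causal_g = np.zeros((n, 0), dtype=np.int8)
    if params.planted_window is not None:
        w = params.planted_window
        causal_pos = np.sort(
            rng.choice(np.arange(w.start, w.start + w.span), size=w.n_causal, replace=False)
        )
        causal_g = np.zeros((n, w.n_causal), dtype=np.int8)
        carrier_idx = np.flatnonzero(carrier)
        which = rng.integers(0, w.n_causal, size=carrier_idx.size)
        causal_g[carrier_idx, which] = 1  # one heterozygous causal variant per carrier

    # causal positions take precedence at collisions; common sites beat rare ones
    causal_set = set(causal_pos.tolist())
    keep_common = np.array([p not in causal_set for p in common_pos], dtype=bool)
    common_pos, common_g = common_pos[keep_common], common_g[:, keep_common]
    common_set = set(common_pos.tolist())
    keep_rare = np.array(
        [p not in causal_set and p not in common_set for p in rare_pos], dtype=bool
    )
    rare_pos, rare_g = rare_pos[keep_rare], rare_g[:, keep_rare]

    positions = np.concatenate([common_pos, rare_pos, causal_pos])
    genotypes = np.concatenate([common_g, rare_g, causal_g], axis=1)
    is_causal = np.concatenate(
        [np.zeros(common_pos.size + rare_pos.size, bool), np.ones(causal_pos.size, bool)]
    )
    order = np.argsort(positions, kind="stable")
    positions, genotypes, is_causal = positions[order], genotypes[:, order], is_causal[order]
    # drop sites monomorphic in the sampled cohort; a planted causal site no
    # selected sample carries is unobservable and is dropped from the truth
    # record too
    alt_counts = genotypes.sum(axis=0)
    keep = (alt_counts > 0) & (alt_counts < 2 * n)
    positions, genotypes, is_causal = positions[keep], genotypes[:, keep], is_causal[keep]

    # depth, quality, missingness
    mean_d, size_d = params.depth_model
    depth = rng.negative_binomial(size_d, size_d / (size_d + mean_d), size=genotypes.shape).astype(
        np.int32
    )
    depth = np.maximum(depth, 3)
    missing = rng.random(genotypes.shape) < params.missing_rate
    # keep the planted causal carrier genotypes intact so the truth record
    # round-trips exactly through the emitted matrix
    missing[:, is_causal] &= genotypes[:, is_causal] == 0
    depth[missing] = rng.integers(0, 3, size=int(missing.sum()))
    g_out = genotypes.copy()
    g_out[missing] = MISSING
    quality = np.minimum(QUALITY_CAP, QUALITY_PER_READ * depth).astype(np.int16)

    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    sites = []
    for i, pos in enumerate(positions):
        ref, alt = alleles[int(pos) % len(alleles)]
        sites.append(VariantSite(chrom=params.chrom, pos=int(pos), ref_allele=ref, alt_alleles=(alt,)))
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    matrix = GenotypeMatrix(
        sample_ids=sample_ids, sites=sites, genotypes=g_out, depth=depth, quality=quality
    )

    aea = simulate_metabolites(
        n, carrier, params.metabolite_base, params.carrier_metabolite_multiplier,
        seed=int(rng.integers(2**31)),
    )
    ag2 = simulate_metabolites(
        n, carrier, params.metabolite2_base, params.carrier_metabolite2_multiplier,
        seed=int(rng.integers(2**31)),
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": rng.choice(["M", "F"], size=n),
            "age": rng.integers(55, 78, size=n),
            "bmi": np.round(bmi, 2),
            "group": np.where(is_case, "case", "control"),
            "aea_pmol_ml": np.round(aea, 3),
            "ag2_pmol_ml": np.round(ag2, 3),
        }
    )

    causal_idx = np.flatnonzero(is_causal)
    emitted_carrier, _ = union_carrier(matrix, causal_idx.tolist())
    truth = TruthRecord(
        causal_variant_positions=[int(p) for p in positions[causal_idx]],
        carrier=emitted_carrier.astype(np.int8),
        liability_bmi=bmi,
    )
    return matrix, samples, truth


def simulate_metabolites(
    n_samples: int,
    carriers: np.ndarray,
    base: tuple[float, float],
    multiplier: float,
    seed: int,
) -> np.ndarray:
    """Plasma metabolite levels: Normal(base) truncated at 0; carrier mean scaled.

    Non-carriers ~ Normal(mean, sd) truncated at 0; carriers ~ Normal(mean *
    multiplier, sd) truncated at 0.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    carriers = np.asarray(carriers, dtype=bool)
    if carriers.size != n_samples:
        raise ValueError("carrier flags must match n_samples")
    rng = np.random.default_rng(seed)
    mean, sd = base
    means = np.where(carriers, mean * multiplier, mean)
    values = rng.normal(means, sd)
    while (values <= 0).any():  # truncation at zero by redraw
        bad = values <= 0
        values[bad] = rng.normal(means[bad], sd)
    return values


#: the five replicate matching statuses (1 is concordance, not an error)
REPLICATE_STATUSES = (1, 2, 3, 4, 5)


def simulate_replicate_pair(
    matrix: GenotypeMatrix,
    error_rates: dict[int, float],
    seed: int,
) -> tuple[GenotypeMatrix, GenotypeMatrix, TruthErrorLog]:
    """Inject replicate discrepancies of the four error categories.

    ``error_rates`` maps matching status (2-5) to a per-compared-pair
    probability; the expected event count for status s is
    ``rate[s] * n_pairs``.  Status 2: het flipped to hom-alt; 3: het
    under-called hom-ref with residual alternative evidence (near-pass);
    4: the same without evidence; 5: low-coverage corruption.  The second
    matrix differs from the first only at logged positions.
    """
    if set(error_rates) - set(REPLICATE_STATUSES):
        raise ValueError(f"error_rates keys must be among {REPLICATE_STATUSES}")
    rng = np.random.default_rng(seed)
    rep = matrix.copy()
    rep.alt_evidence = np.zeros(rep.genotypes.shape, dtype=bool)
    log = TruthErrorLog()

    called = matrix.genotypes != MISSING
    n_pairs = int(called.sum())
    well_covered = called & (matrix.depth >= 20)
    het = (matrix.genotypes == 1) & well_covered
    eligible = {2: het, 3: het, 4: het, 5: well_covered}
    taken = np.zeros(matrix.genotypes.shape, dtype=bool)

    for status in (3, 4, 2, 5):
        rate = error_rates.get(status, 0.0)
        if rate <= 0:
            continue
        k = rng.binomial(n_pairs, rate)
        pool = np.flatnonzero(eligible[status] & ~taken)
        if k > pool.size:
            k = pool.size
        if k == 0:
            continue
        chosen = rng.choice(pool, size=k, replace=False)
        rows, cols = np.unravel_index(chosen, matrix.genotypes.shape)
        taken[rows, cols] = True
        if status == 2:
            rep.genotypes[rows, cols] = 2
        elif status == 3:
            rep.genotypes[rows, cols] = 0
            rep.alt_evidence[rows, cols] = True
        elif status == 4:
            rep.genotypes[rows, cols] = 0
        else:  # low-coverage corruption
            rep.depth[rows, cols] = rng.integers(3, 20, size=k)
            g = matrix.genotypes[rows, cols]
            rep.genotypes[rows, cols] = np.where(g == 1, 0, 1)
            rep.quality[rows, cols] = np.minimum(
                QUALITY_CAP, QUALITY_PER_READ * rep.depth[rows, cols]
            )
        for r, c in zip(rows, cols):
            log.events.append((int(r), int(c), status))
    log.events.sort()
    return matrix, rep, log


def simulate_indel_observations(
    site_freqs: Sequence[float],
    n_samples: int,
    depth_model: tuple[float, float] = (60.0, 8.0),
    seed: int = 0,
    error_rate: float = 0.01,
    chrom: str = "chr3",
) -> pd.DataFrame:
    """Per-sample indel read support under HWE genotypes.

    For each site frequency, true genotypes are drawn at Hardy-Weinberg
    proportions; indel-supporting reads are Binomial(depth, p) with p equal
    to ``error_rate``, 0.5 or ``1 - error_rate`` for hom-ref, het and hom-alt
    respectively.  Returns a tidy table with columns sample_id, chrom, pos,
    length, seq, reads_total, reads_indel, true_genotype.
    """
    freqs = np.asarray(site_freqs, dtype=float)
    if ((freqs < 0) | (freqs > 0.5)).any():
        raise ValueError("site MAFs must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    mean_d, size_d = depth_model
    rows = []
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    for s_idx, q in enumerate(freqs):
        pos = 1000 * (s_idx + 1)
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        g = rng.choice(3, size=n_samples, p=probs)
        depth = np.maximum(
            rng.negative_binomial(size_d, size_d / (size_d + mean_d), size=n_samples), 1
        )
        p_read = np.choose(g, [error_rate, 0.5, 1 - error_rate])
        reads_indel = rng.binomial(depth, p_read)
        for i in range(n_samples):
            rows.append(
                {
                    "sample_id": sample_ids[i],
                    "chrom": chrom,
                    "pos": pos,
                    "length": -1,
                    "seq": "A",
                    "reads_total": int(depth[i]),
                    "reads_indel": int(reads_indel[i]),
                    "true_genotype": int(g[i]),
                }
            )
    return pd.DataFrame(rows)
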