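"""Staged SNV quality control.

The filter cascade mirrors the study design for sequence-derived genotypes:

1. restrict to biallelic sites (tri-/multi-allelic sites are reported aside),
2. Hardy-Weinberg equilibrium in the controls (chi-square, 1 df, drop P < 1e-3),
3. mask individual genotypes with depth < 3 reads or consensus quality < 10,
4. drop sites where fewer than 90% of all samples retain a valid call.

Each stage's survivor count is logged so the cascade is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import MISSING, GenotypeMatrix, VariantSite

HWE_P_THRESHOLD = 1e-3
CALL_RATE_THRESHOLD = 0.9
MIN_DEPTH = 3
MIN_QUALITY = 10


@dataclass
class SiteQCReport:
    """Per-site QC ledger entry."""

    site: VariantSite
    genotype_counts_controls: tuple[int, int, int]
    hwe_stat: float
    hwe_p: float
    het_direction: str  # "deficit" | "excess" | "none"
    call_rate: float
    maf: float
    minor_allele_count: int
    is_singleton: bool
    is_known: bool = False
    verdict: str = "pass"  # "pass" | "fail(not_biallelic)" | "fail(hwe)" | "fail(call_rate)"

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


@dataclass
class NoveltySummary:
    """Counts and fractions of known / novel / singleton / rare passing sites."""

    n_pass: int
    n_known: int
    n_novel: int
    n_singleton: int
    n_rare: int  # MAF < 0.01
    frac_known: float
    frac_novel: float
    frac_singleton: float
    frac_rare: float


def hwe_test(n_homref: int, n_het: int, n_homalt: int) -> tuple[float, float, str]:
    """Hardy-Weinberg chi-square test (1 df) from genotype counts.

    Expected counts come from the observed allele frequency.  Monomorphic
    sites return (0, 1, "none").  Returns ``(stat, p, het_direction)``.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("hwe_test needs at least one genotype")
    p_ref = (2 * n_homref + n_het) / (2 * n)
    q = 1.0 - p_ref
    if p_ref == 0.0 or q == 0.0:
        return 0.0, 1.0, "none"
    expected = np.array([n * p_ref**2, 2 * n * p_ref * q, n * q**2])
    observed = np.array([n_homref, n_het, n_homalt], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    if n_het < expected[1]:
        direction = "deficit"
    elif n_het > expected[1]:
        direction = "excess"
    else:
        direction = "none"
    return stat, p, direction


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional HWE test (two-sided, by heterozygote-count probability).

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of outcomes no more likely than the
    observed one.  Offered as an option; the filter cascade uses
    :func:`hwe_test`.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("exact HWE test needs at least one genotype")
    n_minor = min(2 * n_homref + n_het, 2 * n_homalt + n_het)
    if n_minor == 0:
        return 1.0
    hets = range(n_minor % 2, n_minor + 1, 2)
    logprobs = {}
    for h in hets:
        a = (n_minor - h) // 2  # minor homozygotes
        b = n - a - h
        if b < 0:
            continue
        logprobs[h] = (
            math.lgamma(n + 1)
            - math.lgamma(a + 1)
            - math.lgamma(h + 1)
            - math.lgamma(b + 1)
            + h * math.log(2)
            + math.lgamma(n_minor + 1)
            + math.lgamma(2 * n - n_minor + 1)
            - math.lgamma(2 * n + 1)
        )
    obs = logprobs[n_het]
    total = sum(math.exp(lp) for lp in logprobs.values())
    p = sum(math.exp(lp) for lp in logprobs.values() if lp <= obs + 1e-12) / total
    return min(1.0, p)


def mask_genotypes(
    matrix: GenotypeMatrix,
    min_depth: int = MIN_DEPTH,
    min_quality: int = MIN_QUALITY,
) -> GenotypeMatrix:
    """Set genotypes to missing where depth < ``min_depth`` or quality < ``min_quality``.

    Both thresholds are strict-less-than: a genotype at exactly 3 reads and
    phred 10 is retained.  Nothing else changes; the operation is idempotent.
    """
    out = matrix.copy()
    bad = (out.depth < min_depth) | (out.quality < min_quality)
    out.genotypes[bad] = MISSING
    return out


def compute_maf(matrix: GenotypeMatrix, site: int) -> tuple[float, int]:
    """Minor allele frequency and minor allele count over called genotypes."""
    g = matrix.genotypes[:, site]
    called = g != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError(f"no called genotypes at site {matrix.sites[site].id}")
    alt = int(g[called].sum())
    total = 2 * n_called
    f = alt / total
    maf = min(f, 1.0 - f)
    minor_count = min(alt, total - alt)
    return maf, minor_count


def genotype_counts(matrix: GenotypeMatrix, site: int, sample_idx: np.ndarray) -> tuple[int, int, int]:
    g = matrix.genotypes[sample_idx, site]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


@dataclass
class QCLedger:
    """Survivor counts after each filter stage."""

    n_input: int = 0
    n_biallelic: int = 0
    n_hwe_pass: int = 0
    n_call_rate_pass: int = 0
    n_multiallelic: int = 0

    @property
    def hwe_pass_pct(self) -> float:
        """Percent of biallelic sites in HWE in the controls."""
        return 100.0 * self.n_hwe_pass / self.n_biallelic if self.n_biallelic else float("nan")

    def as_dict(self) -> dict:
        return {
            "input_sites": self.n_input,
            "biallelic": self.n_biallelic,
            "hwe_pass": self.n_hwe_pass,
            "call_rate_pass": self.n_call_rate_pass,
            "multiallelic_excluded": self.n_multiallelic,
        }


@dataclass
class MultiallelicRecord:
    site: VariantSite
    n_alt_carriers: int  # samples carrying any non-reference allele


def qc_filter_sites(
    matrix: GenotypeMatrix,
    control_ids: Sequence[str],
) -> tuple[GenotypeMatrix, list[SiteQCReport], QCLedger, list[MultiallelicRecord]]:
    """Run the staged filter cascade; return the surviving matrix and the ledger.

    HWE is computed on the raw control genotypes (before masking); the
    call-rate denominator is all samples.  Reports are emitted for every
    biallelic input site with the verdict of the first failing stage.
    """
    if len(control_ids) == 0:
        raise ValueError("control sample set must be non-empty")
    control_idx = matrix.sample_indices(control_ids)

    ledger = QCLedger(n_input=matrix.n_sites)
    multiallelic: list[MultiallelicRecord] = []
    biallelic_idx = []
    for j, site in enumerate(matrix.sites):
        if site.is_biallelic:
            biallelic_idx.append(j)
        else:
            carriers = int((matrix.genotypes[:, j] > 0).sum())
            multiallelic.append(MultiallelicRecord(site, carriers))
    ledger.n_multiallelic = len(multiallelic)
    ledger.n_biallelic = len(biallelic_idx)

    # stage 2: HWE in controls on raw genotypes
    hwe_results = {}
    for j in biallelic_idx:
        counts = genotype_counts(matrix, j, control_idx)
        if sum(counts) == 0:
            hwe_results[j] = (0.0, 1.0, "none")
        else:
            hwe_results[j] = hwe_test(*counts)
    hwe_pass = [j for j in biallelic_idx if hwe_results[j][1] >= HWE_P_THRESHOLD]
    ledger.n_hwe_pass = len(hwe_pass)

    # stage 3: genotype masking
    masked = mask_genotypes(matrix)

    # stage 4: call rate over all samples
    call_rates = masked.called().mean(axis=0)
    survivors = [j for j in hwe_pass if call_rates[j] >= CALL_RATE_THRESHOLD]
    ledger.n_call_rate_pass = len(survivors)

    reports: list[SiteQCReport] = []
    for j in biallelic_idx:
        stat, p, direction = hwe_results[j]
        counts = genotype_counts(matrix, j, control_idx)
        g = masked.genotypes[:, j]
        if (g != MISSING).any():
            maf, minor_count = compute_maf(masked, j)
        else:
            maf, minor_count = float("nan"), 0
        if p < HWE_P_THRESHOLD:
            verdict = "fail(hwe)"
        elif call_rates[j] < CALL_RATE_THRESHOLD:
            verdict = "fail(call_rate)"
        else:
            verdict = "pass"
        reports.append(
            SiteQCReport(
                site=matrix.sites[j],
                genotype_counts_controls=counts,
                hwe_stat=stat,
                hwe_p=p,
                het_direction=direction,
                call_rate=float(call_rates[j]),
                maf=maf,
                minor_allele_count=minor_count,
                is_singleton=minor_count == 1,
                verdict=verdict,
            )
        )

    filtered = masked.subset_sites(survivors)
    return filtered, reports, ledger, multiallelic


def classify_variants(reports: Iterable[SiteQCReport], known_ids: set[str]) -> NoveltySummary:
    """Tally known/novel/singleton/rare fractions among passing sites."""
    passing = [r for r in reports if r.passed]
    for r in passing:
        r.is_known = r.site.id in known_ids
    n = len(passing)
    n_known = sum(r.is_known for r in passing)
    n_singleton = sum(r.is_singleton for r in passing)
    n_rare = sum(1 for r in passing if r.maf < 0.01)
    frac = lambda k: k / n if n else float("nan")  # noqa: E731
    return NoveltySummary(
        n_pass=n,
        n_known=n_known,
        n_novel=n - n_known,
        n_singleton=n_singleton,
        n_rare=n_rare,
        frac_known=frac(n_known),
        frac_novel=frac(n - n_known),
        frac_singleton=frac(n_singleton),
        frac_rare=frac(n_rare),
    )
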