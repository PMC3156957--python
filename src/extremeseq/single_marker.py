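"""Single-marker allelic case/control association.

Per variant: a 2x2 allelic contingency table, the 1-df chi-square statistic
(no continuity correction), the minor-allele odds ratio, and a family-wise
max(T) permutation P-value obtained by permuting sample labels while keeping
each sample's multi-site genotype vector intact (which preserves LD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix
from .variant_qc import compute_maf


@dataclass(frozen=True)
class AllelicTable:
    """Minor/other allele counts in cases (a, b) and controls (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "AllelicTable":
        return AllelicTable(self.c, self.d, self.a, self.b)


@dataclass
class SingleMarkerResult:
    site_id: str
    table: AllelicTable
    chi2: float
    p_asymptotic: float
    odds_ratio: float
    or_haldane: bool
    p_maxT: Optional[float] = None
    n_perm: int = 0


def allelic_table(matrix: GenotypeMatrix, site: int, status: np.ndarray) -> AllelicTable:
    """Count minor/other alleles in cases and controls at one site.

    ``status`` is a boolean vector (True = case).  Alleles are counted over
    called genotypes only; the minor allele is defined cohort-wide.
    """
    status = np.asarray(status, dtype=bool)
    g = matrix.genotypes[:, site]
    called = g != MISSING
    for label, grp in (("cases", status), ("controls", ~status)):
        if not (called & grp).any():
            raise ValueError(
                f"no called genotypes among {label} at site {matrix.sites[site].id}"
            )
    alt_cases = int(g[called & status].sum())
    alt_controls = int(g[called & ~status].sum())
    n_case_alleles = 2 * int((called & status).sum())
    n_control_alleles = 2 * int((called & ~status).sum())
    alt_total = alt_cases + alt_controls
    # cohort-wide minor allele
    if alt_total * 2 <= n_case_alleles + n_control_alleles:
        a, c = alt_cases, alt_controls
    else:
        a, c = n_case_alleles - alt_cases, n_control_alleles - alt_controls
    return AllelicTable(a, n_case_alleles - a, c, n_control_alleles - c)


def chisq_allelic(table: AllelicTable) -> tuple[float, float, float, bool]:
    """Chi-square (1 df, no continuity correction), asymptotic P, odds ratio.

    Returns ``(chi2, p, odds_ratio, haldane_flag)``.  A zero cell triggers the
    Haldane 0.5 correction for the odds ratio only (flagged); a zero margin
    yields chi2 = 0, p = 1 and an undefined (NaN) odds ratio.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        raise ValueError("empty allelic table")
    margins = [a + b, c + d, a + c, b + d]
    if 0 in margins:
        return 0.0, 1.0, float("nan"), False
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, df=1))
    haldane = 0 in (a, b, c, d)
    if haldane:
        ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds_ratio = (ah / bh) / (ch / dh)
    else:
        odds_ratio = (a / b) / (c / d)
    return float(chi2), p, float(odds_ratio), haldane


def _chi2_vectorized(a, b, c, d):
    """Allelic chi-square on arrays of table cells; zero margins give 0."""
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    c = c.astype(np.float64)
    d = d.astype(np.float64)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    num = n * (a * d - b * c) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, num / np.maximum(denom, 1.0), 0.0)
    return chi2


def _perm_chi2(matrix: GenotypeMatrix, sites: np.ndarray, case_mat: np.ndarray) -> np.ndarray:
    """Chi-square per (permutation, site) for a batch of case-label vectors.

    ``case_mat`` is (P, N) with entries 0/1.  Per-site denominators are
    recomputed per permutation because missing genotypes stay missing.
    """
    g = matrix.genotypes[:, sites]
    called = (g != MISSING).astype(np.float64)
    alt = np.where(g == MISSING, 0, g).astype(np.float64)
    case_mat = case_mat.astype(np.float64)
    alt_cases = case_mat @ alt  # (P, S)
    called_cases = case_mat @ called
    alt_total = alt.sum(axis=0)
    called_total = called.sum(axis=0)
    a = alt_cases
    b = 2 * called_cases - alt_cases
    c = alt_total - alt_cases
    d = 2 * (called_total - called_cases) - c
    return _chi2_vectorized(a, b, c, d)


def maxT_permutation(
    matrix: GenotypeMatrix,
    sites: Sequence[int],
    status: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    batch_size: int = 512,
) -> np.ndarray:
    """max(T) permutation P-values for a set of sites.

    For each of ``n_perm`` permutations of the case/control labels (group
    sizes preserved) every site's chi-square is recomputed and the maximum
    over sites recorded; ``p[site] = (1 + #{max >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    status = np.asarray(status, dtype=bool)
    sites = np.asarray(sites, dtype=int)
    rng = np.random.default_rng(seed)
    observed = _perm_chi2(matrix, sites, status[None, :].astype(np.float64))[0]
    n = matrix.n_samples
    n_cases = int(status.sum())
    exceed = np.zeros(len(sites), dtype=np.int64)
    done = 0
    while done < n_perm:
        p = min(batch_size, n_perm - done)
        perm = np.zeros((p, n), dtype=np.float64)
        for i in range(p):
            idx = rng.permutation(n)[:n_cases]
            perm[i, idx] = 1.0
        chi2 = _perm_chi2(matrix, sites, perm)
        maxstat = chi2.max(axis=1)
        exceed += (maxstat[:, None] >= observed[None, :] - 1e-12).sum(axis=0)
        done += p
    return (1 + exceed) / (n_perm + 1)


def single_marker_scan(
    matrix: GenotypeMatrix,
    status: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full scan over all sites: allelic table, chi-square, OR, max(T) P.

    Returns a results table mirroring the standard reporting layout (site,
    minor/major alleles, MAF in cohort/cases/controls, asymptotic and
    permutation P, odds ratio).
    """
    status = np.asarray(status, dtype=bool)
    site_idx = np.arange(matrix.n_sites)
    p_maxT = maxT_permutation(matrix, site_idx, status, n_perm=n_perm, seed=seed)
    rows = []
    for j in site_idx:
        site = matrix.sites[j]
        table = allelic_table(matrix, j, status)
        chi2, p, oratio, haldane = chisq_allelic(table)
        maf, _ = compute_maf(matrix, j)
        maf_cases = _group_maf(matrix, j, status, minor_is_alt=_minor_is_alt(matrix, j))
        maf_controls = _group_maf(matrix, j, ~status, minor_is_alt=_minor_is_alt(matrix, j))
        alt = site.alt_alleles[0] if site.is_biallelic else ",".join(site.alt_alleles)
        minor, major = (alt, site.ref_allele) if _minor_is_alt(matrix, j) else (site.ref_allele, alt)
        rows.append(
            {
                "site_id": site.id,
                "chrom": site.chrom,
                "pos": site.pos,
                "minor_allele": minor,
                "major_allele": major,
                "maf_cohort": maf,
                "maf_cases": maf_cases,
                "maf_controls": maf_controls,
                "chi2": chi2,
                "p_chi2": p,
                "odds_ratio": oratio,
                "or_haldane": haldane,
                "p_maxT": p_maxT[j],
                "n_perm": n_perm,
            }
        )
    return pd.DataFrame(rows)


def _minor_is_alt(matrix: GenotypeMatrix, site: int) -> bool:
    g = matrix.genotypes[:, site]
    called = g != MISSING
    alt = g[called].sum()
    return 2 * alt <= 2 * called.sum()


def _group_maf(matrix: GenotypeMatrix, site: int, group: np.ndarray, minor_is_alt: bool) -> float:
    g = matrix.genotypes[group, site]
    called = g != MISSING
    if not called.any():
        return float("nan")
    f_alt = g[called].sum() / (2 * called.sum())
    return float(f_alt if minor_is_alt else 1.0 - f_alt)
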