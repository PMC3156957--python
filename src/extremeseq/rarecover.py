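"""RareCover-style collapsing association test for rare variants.

A window of fixed width (default 5 kb) is anchored at each rare variant
(MAF <= 0.1); S is the set of rare variants inside.  The test greedily grows
a subset C of S maximizing the chi-square of the union-carrier 2x2 table:
the union-variant A_C is 1 for a sample carrying >= 1 minor allele at any
member of C.  Significance comes from case/control label permutations that
re-optimize C within every permutation, per window (locus P) and jointly over
all windows of a gene (gene-wide P, a max-over-windows correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import MISSING, GenotypeMatrix
from .variant_qc import compute_maf
from .single_marker import _chi2_vectorized

DEFAULT_MAF_THRESHOLD = 0.1
DEFAULT_WINDOW_SIZE = 5000


@dataclass
class LocusWindow:
    """A 5-kb window anchored at a rare variant, with member set S."""

    gene: str
    start: int
    end: int
    members: list[int]  # site indices into the matrix, ordered by position

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a window must contain at least one rare variant")


@dataclass
class LocusVariant:
    """The selected subset C with its union-carrier vector and statistic."""

    window: LocusWindow
    C: list[int]
    A_C: np.ndarray  # (n_samples,) uint8 union-carrier indicator
    carrier_table: tuple[int, int, int, int]  # carrier/non-carrier x case/control
    stat: float
    n_all_missing: int = 0
    p_locus: Optional[float] = None
    p_genewide: Optional[float] = None


def enumerate_windows(
    matrix: GenotypeMatrix,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    window_size: int = DEFAULT_WINDOW_SIZE,
    gene: str = "gene",
    include_indels: bool = False,
) -> list[LocusWindow]:
    """One window per rare variant: [pos(v), pos(v) + window_size).

    Windows whose member sets duplicate an earlier window collapse to the
    leftmost anchor.  Monomorphic sites and (by default) indels are excluded
    from eligibility.
    """
    rare = []
    for j, site in enumerate(matrix.sites):
        if site.var_class == "indel" and not include_indels:
            continue
        g = matrix.genotypes[:, j]
        if not (g != MISSING).any():
            continue
        maf, minor_count = compute_maf(matrix, j)
        if minor_count > 0 and maf <= maf_threshold:
            rare.append(j)
    rare.sort(key=lambda j: matrix.sites[j].pos)
    positions = [matrix.sites[j].pos for j in rare]
    windows: list[LocusWindow] = []
    seen: set[tuple[int, ...]] = set()
    for i, j in enumerate(rare):
        start = positions[i]
        end = start + window_size
        members = [rare[k] for k in range(len(rare)) if start <= positions[k] < end]
        key = tuple(members)
        if key in seen:
            continue
        seen.add(key)
        windows.append(LocusWindow(gene=gene, start=start, end=end, members=members))
    return windows


def union_carrier(matrix: GenotypeMatrix, C: Sequence[int]) -> tuple[np.ndarray, int]:
    """Union-variant indicator A_C and the count of samples missing at every member.

    A sample scores 1 iff it carries >= 1 minor allele at any member of C.
    Samples with no call at any member score 0 (conservative) and are counted
    separately so callers can exclude them instead.
    """
    C = list(C)
    if not C:
        return np.zeros(matrix.n_samples, dtype=np.uint8), 0
    g = matrix.genotypes[:, C]
    carrier = (g > 0).any(axis=1)
    all_missing = (g == MISSING).all(axis=1)
    return carrier.astype(np.uint8), int(all_missing.sum())


def _carrier_minor(matrix: GenotypeMatrix, members: Sequence[int]) -> np.ndarray:
    """Per-variant minor-allele carrier matrix (n_samples, k) for the members.

    For rare variants the minor allele is the alternative allele in all but
    pathological cases; when the alternative allele is the major one the
    carrier definition flips accordingly.
    """
    cols = []
    for j in members:
        g = matrix.genotypes[:, j]
        called = g != MISSING
        alt = g[called].sum()
        if 2 * alt <= 2 * called.sum():
            cols.append(g > 0)
        else:  # minor allele is the reference allele
            cols.append((g < 2) & called)
    return np.stack(cols, axis=1)


def _carrier_table(A: np.ndarray, status: np.ndarray) -> tuple[int, int, int, int]:
    carrier = A.astype(bool)
    cc = int((carrier & status).sum())
    nc = int((~carrier & status).sum())
    ccl = int((carrier & ~status).sum())
    ncl = int((~carrier & ~status).sum())
    return cc, nc, ccl, ncl


def _table_chi2(table: tuple[int, int, int, int]) -> float:
    a, b, c, d = (np.array([x], dtype=np.float64) for x in table)
    return float(_chi2_vectorized(a, b, c, d)[0])


def greedy_select(
    window: LocusWindow,
    matrix: GenotypeMatrix,
    status: np.ndarray,
) -> LocusVariant:
    """Forward greedy subset selection maximizing the union-carrier chi-square.

    Starts from C = {} (stat 0); at each step adds the member of S \\ C that
    maximally increases the statistic, accepting only strict improvement;
    ties break to the leftmost position.  Deterministic.
    """
    status = np.asarray(status, dtype=bool)
    carriers = _carrier_minor(matrix, window.members)  # ordered by position
    stats = _greedy_stats(carriers, status[None, :].astype(np.uint8), return_sets=True)
    best_stat, chosen = stats[0][0], stats[1][0]
    C = [window.members[k] for k in range(len(window.members)) if chosen[k]]
    A, n_all_missing = union_carrier(matrix, C)
    table = _carrier_table(A, status)
    return LocusVariant(
        window=window,
        C=C,
        A_C=A,
        carrier_table=table,
        stat=float(best_stat),
        n_all_missing=n_all_missing,
    )


def exhaustive_select(
    window: LocusWindow,
    matrix: GenotypeMatrix,
    status: np.ndarray,
    max_size: int = 20,
) -> LocusVariant:
    """Enumerate all non-empty subsets of S and return the stat-maximal one.

    Oracle for :func:`greedy_select`; refuses windows larger than
    ``max_size`` members.  Ties break to the smallest subset, then to the
    lexicographically leftmost member set.
    """
    k = len(window.members)
    if k > max_size:
        raise ValueError(f"window has {k} members, exhaustive limit is {max_size}")
    status = np.asarray(status, dtype=bool)
    carriers = _carrier_minor(matrix, window.members)
    n = carriers.shape[0]
    words = (n + 63) // 64
    bits = np.zeros((k, words), dtype=np.uint64)
    for j in range(k):
        idx = np.flatnonzero(carriers[:, j])
        np.bitwise_or.at(bits[j], idx // 64, np.uint64(1) << (idx % 64).astype(np.uint64))
    case_bits = np.zeros(words, dtype=np.uint64)
    idx = np.flatnonzero(status)
    np.bitwise_or.at(case_bits, idx // 64, np.uint64(1) << (idx % 64).astype(np.uint64))

    n_sub = 1 << k
    unions = np.zeros((n_sub, words), dtype=np.uint64)
    for s in range(1, n_sub):
        low = s & -s
        unions[s] = unions[s ^ low] | bits[low.bit_length() - 1]
    tot = np.bitwise_count(unions).sum(axis=1).astype(np.float64)
    cas = np.bitwise_count(unions & case_bits[None, :]).sum(axis=1).astype(np.float64)
    n_cases = float(status.sum())
    a = cas
    b = n_cases - cas
    c = tot - cas
    d = (n - n_cases) - c
    chi2 = _chi2_vectorized(a, b, c, d)
    chi2[0] = -np.inf
    best = float(chi2[1:].max())
    cand = np.flatnonzero(chi2 >= best - 1e-12)
    cand = cand[cand > 0]
    sizes = np.array([int(s).bit_count() for s in cand])
    cand = cand[sizes == sizes.min()]
    subset = int(min(cand, key=lambda s: tuple(k_ for k_ in range(k) if s >> k_ & 1)))
    C = [window.members[k_] for k_ in range(k) if subset >> k_ & 1]
    A, n_all_missing = union_carrier(matrix, C)
    table = _carrier_table(A, status)
    return LocusVariant(
        window=window,
        C=C,
        A_C=A,
        carrier_table=table,
        stat=max(best, 0.0),
        n_all_missing=n_all_missing,
    )


def _greedy_stats_directional(
    carriers: np.ndarray,
    case_mat: np.ndarray,
    direction: int,
):
    """Single-direction forward greedy for a batch of label vectors.

    ``direction`` +1 seeks case-enriched unions, -1 control-enriched ones;
    candidate tables leaning the wrong way score negatively and are never
    accepted (strict improvement from 0).  Returns (stats (P,), sets (P, K)).
    """
    P, N = case_mat.shape
    K = carriers.shape[1]
    case_bool = case_mat.astype(bool)
    n_cases = case_bool.sum(axis=1).astype(np.float64)  # (P,)
    U = np.zeros((P, N), dtype=bool)
    best = np.zeros(P, dtype=np.float64)
    in_C = np.zeros((P, K), dtype=bool)
    active = np.ones(P, dtype=bool)
    for _ in range(K):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        cu = U[idx, :, None] | carriers[None, :, :]  # (p, N, K)
        tot = cu.sum(axis=1).astype(np.float64)  # (p, K)
        cas = (cu & case_bool[idx, :, None]).sum(axis=1).astype(np.float64)
        a = cas
        b = n_cases[idx, None] - cas
        c = tot - cas
        d = (N - n_cases[idx, None]) - c
        chi2 = _chi2_vectorized(a, b, c, d)
        enrich = direction * (a * (N - n_cases[idx, None]) - c * n_cases[idx, None])
        score = np.where(enrich >= 0, chi2, -chi2)
        score[in_C[idx]] = -np.inf
        pick = score.argmax(axis=1)  # argmax takes the leftmost tie
        gain = score[np.arange(idx.size), pick]
        improved = gain > best[idx] + 1e-9
        sel = idx[improved]
        if sel.size == 0:
            break
        picked = pick[improved]
        best[sel] = gain[improved]
        in_C[sel, picked] = True
        U[sel] |= carriers[:, picked].T
        active[idx[~improved]] = False
    return best, in_C


def _greedy_stats(
    carriers: np.ndarray,
    case_mat: np.ndarray,
    return_sets: bool = False,
):
    """Greedy union-carrier statistic for a batch of label vectors.

    ``carriers`` is (N, K) boolean, columns ordered by position; ``case_mat``
    is (P, N) with 0/1 entries, one row per label permutation.  Because the
    2x2 chi-square is two-sided, the forward greedy is run once per
    enrichment direction (case-enriched and control-enriched unions) and the
    larger statistic wins; a single start would commit to the direction of
    its first pick.  Vectorized over rows and candidate variants.  Returns
    the (P,) array of final statistics (and the (P, K) chosen-set mask when
    ``return_sets``).
    """
    stat_pos, sets_pos = _greedy_stats_directional(carriers, case_mat, +1)
    stat_neg, sets_neg = _greedy_stats_directional(carriers, case_mat, -1)
    neg_wins = stat_neg > stat_pos + 1e-12
    best = np.where(neg_wins, stat_neg, stat_pos)
    if return_sets:
        sets = np.where(neg_wins[:, None], sets_neg, sets_pos)
        return best, sets
    return best


def _label_permutations(n: int, n_cases: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    perm = np.zeros((n_perm, n), dtype=np.uint8)
    for i in range(n_perm):
        perm[i, rng.permutation(n)[:n_cases]] = 1
    return perm


def locus_permutation_p(
    window: LocusWindow,
    matrix: GenotypeMatrix,
    status: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    batch_size: int = 2048,
) -> float:
    """Locus permutation P for a window, re-optimizing C in every permutation.

    ``p = (1 + #{perm stat >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    status = np.asarray(status, dtype=bool)
    observed = greedy_select(window, matrix, status).stat
    carriers = _carrier_minor(matrix, window.members)
    rng = np.random.default_rng(seed)
    n_cases = int(status.sum())
    exceed = 0
    done = 0
    while done < n_perm:
        p = min(batch_size, n_perm - done)
        perm = _label_permutations(matrix.n_samples, n_cases, p, rng)
        stats = _greedy_stats(carriers, perm)
        exceed += int((stats >= observed - 1e-12).sum())
        done += p
    return (1 + exceed) / (n_perm + 1)


def gene_wide_adjust(
    windows: Sequence[LocusWindow],
    matrix: GenotypeMatrix,
    status: np.ndarray,
    n_perm_gene: int = 1_000_000,
    seed: int = 0,
    batch_size: int = 2048,
) -> np.ndarray:
    """Gene-wide adjusted P per window via max-over-windows permutations.

    The same label permutations are applied to every window of the gene; each
    permutation contributes the maximum re-optimized statistic over windows.
    """
    if n_perm_gene < 1:
        raise ValueError("n_perm_gene must be >= 1")
    status = np.asarray(status, dtype=bool)
    observed = np.array([greedy_select(w, matrix, status).stat for w in windows])
    carrier_sets = [_carrier_minor(matrix, w.members) for w in windows]
    rng = np.random.default_rng(seed)
    n_cases = int(status.sum())
    exceed = np.zeros(len(windows), dtype=np.int64)
    done = 0
    while done < n_perm_gene:
        p = min(batch_size, n_perm_gene - done)
        perm = _label_permutations(matrix.n_samples, n_cases, p, rng)
        gene_max = np.full(p, -np.inf)
        for carriers in carrier_sets:
            np.maximum(gene_max, _greedy_stats(carriers, perm), out=gene_max)
        exceed += (gene_max[:, None] >= observed[None, :] - 1e-12).sum(axis=0)
        done += p
    return (1 + exceed) / (n_perm_gene + 1)


def rarecover_scan(
    matrix: GenotypeMatrix,
    status: np.ndarray,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    window_size: int = DEFAULT_WINDOW_SIZE,
    n_perm: int = 10_000,
    n_perm_gene: Optional[int] = None,
    gene: str = "gene",
    seed: int = 0,
) -> list[LocusVariant]:
    """Full collapsing scan: windows, greedy selection, locus (and gene-wide) P."""
    windows = enumerate_windows(matrix, maf_threshold, window_size, gene=gene)
    results = []
    for i, w in enumerate(windows):
        lv = greedy_select(w, matrix, status)
        lv.p_locus = locus_permutation_p(w, matrix, status, n_perm=n_perm, seed=seed + i)
        results.append(lv)
    if n_perm_gene and windows:
        p_gene = gene_wide_adjust(windows, matrix, status, n_perm_gene, seed=seed + 7919)
        for lv, pg in zip(results, p_gene):
            lv.p_genewide = float(pg)
    return results
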