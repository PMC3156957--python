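"""Genotype concordance QC: blind replicates and cross-platform comparison.

Replicate pairs are classified into the five-status error taxonomy
(1 concordant; 2 het vs hom-alt; 3 het vs hom-ref with residual alternative
allele evidence, the "near-pass" error; 4 het vs hom-ref without evidence;
5 disagreement at a low-covered position).  Sequencing-versus-array
comparisons are tallied per site as matches, under-calls, over-calls and
missing (N/N), with per-platform HWE statistics and a nearby-known-variant
("hidden variant") flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import MISSING, GenotypeMatrix
from .variant_qc import hwe_test

LOW_COVERAGE = 20
HIDDEN_VARIANT_DISTANCE = 50  # bp


@dataclass(frozen=True)
class GenotypePair:
    """One sample's genotype at one site in two replicates."""

    sample_id: str
    site_id: str
    g1: int
    g2: int
    depth1: int
    depth2: int
    alt_evidence2: bool = False  # alternative allele second-most-likely in the hom-ref call


@dataclass
class ConcordanceSummary:
    counts: dict[int, int]
    n_pairs: int
    n_missing_excluded: int
    concordance: float
    under_call_fraction: float  # statuses 3 + 2 (allele under-calling)
    random_miscall_fraction: float  # statuses 4 + 5 (random sampling errors)


@dataclass
class PlatformComparison:
    site_id: str
    n_match: int
    n_under_call: int
    n_over_call: int
    n_nn: int
    hwe_seq: float
    hwe_array: float
    hidden_variant: Optional[tuple[int, str]] = None  # (distance bp, class)

    @property
    def n_compared(self) -> int:
        return self.n_match + self.n_under_call + self.n_over_call + self.n_nn


@dataclass
class PlatformTotals:
    n_comparisons: int
    n_match: int
    n_under_call: int
    n_over_call: int
    n_nn: int

    @property
    def n_discordant(self) -> int:
        return self.n_under_call + self.n_over_call + self.n_nn

    @property
    def discordance_fraction(self) -> float:
        return self.n_discordant / self.n_comparisons if self.n_comparisons else float("nan")


def classify_pair(pair: GenotypePair, low_cov_threshold: int = LOW_COVERAGE) -> int:
    """Assign the matching status (1-5) to one replicate genotype pair.

    Missing genotypes are not classified here (raise); callers exclude them
    first.  Low coverage (status 5) pre-empts statuses 2-4 because it
    explains the disagreement.  Symmetric in the two replicates; hom-ref vs
    hom-alt disagreements are grouped with status 2.
    """
    if MISSING in (pair.g1, pair.g2):
        raise ValueError("missing genotypes are excluded from the status taxonomy")
    if pair.g1 == pair.g2:
        return 1
    if min(pair.depth1, pair.depth2) < low_cov_threshold:
        return 5
    pair_set = {pair.g1, pair.g2}
    if pair_set == {1, 0}:  # het vs hom-ref
        return 3 if pair.alt_evidence2 else 4
    return 2  # het vs hom-alt, or the taxonomy-silent hom-ref vs hom-alt


def summarize_replicates(pairs: Iterable[GenotypePair]) -> ConcordanceSummary:
    """Tally the status taxonomy over replicate pairs.

    Pairs where either genotype is missing are excluded from the taxonomy
    and counted separately.  Two disagreement groupings are reported
    explicitly: allele under-calling (statuses 3 + 2) and random miscalls
    (statuses 4 + 5).
    """
    counts = {s: 0 for s in (1, 2, 3, 4, 5)}
    n_missing = 0
    for pair in pairs:
        if MISSING in (pair.g1, pair.g2):
            n_missing += 1
            continue
        counts[classify_pair(pair)] += 1
    n = sum(counts.values())
    return ConcordanceSummary(
        counts=counts,
        n_pairs=n,
        n_missing_excluded=n_missing,
        concordance=counts[1] / n if n else float("nan"),
        under_call_fraction=(counts[3] + counts[2]) / n if n else float("nan"),
        random_miscall_fraction=(counts[4] + counts[5]) / n if n else float("nan"),
    )


def pairs_from_matrices(m1: GenotypeMatrix, m2: GenotypeMatrix) -> list[GenotypePair]:
    """Build replicate genotype pairs from two matrices over the same grid."""
    if m1.sample_ids != m2.sample_ids or [s.id for s in m1.sites] != [s.id for s in m2.sites]:
        raise ValueError("replicate matrices must share samples and sites")
    evidence = m2.alt_evidence if m2.alt_evidence is not None else np.zeros(m2.genotypes.shape, bool)
    pairs = []
    for i, sid in enumerate(m1.sample_ids):
        for j, site in enumerate(m1.sites):
            pairs.append(
                GenotypePair(
                    sample_id=sid,
                    site_id=site.id,
                    g1=int(m1.genotypes[i, j]),
                    g2=int(m2.genotypes[i, j]),
                    depth1=int(m1.depth[i, j]),
                    depth2=int(m2.depth[i, j]),
                    alt_evidence2=bool(evidence[i, j]),
                )
            )
    return pairs


def _genotype_counts(g: np.ndarray) -> tuple[int, int, int]:
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def compare_platforms(
    seq_matrix: GenotypeMatrix,
    array_matrix: GenotypeMatrix,
    known_sites_nearby: Sequence[tuple[str, int, str]] = (),
    flag_distance: int = HIDDEN_VARIANT_DISTANCE,
) -> tuple[list[PlatformComparison], PlatformTotals]:
    """Compare sequence-derived genotypes with an orthogonal platform per site.

    Under-call: sequencing shows fewer alternative alleles than the array;
    over-call: more; N/N: sequencing genotype missing while the array has a
    call.  A known variant (chrom, pos, class) within ``flag_distance`` bp of
    the assayed site is reported as a potential hidden variant.
    """
    shared = [s for s in seq_matrix.sample_ids if s in set(array_matrix.sample_ids)]
    seq_rows = seq_matrix.sample_indices(shared)
    arr_rows = array_matrix.sample_indices(shared)
    arr_site_ids = {s.id: j for j, s in enumerate(array_matrix.sites)}

    results: list[PlatformComparison] = []
    tot = dict(match=0, under=0, over=0, nn=0, n=0)
    for j, site in enumerate(seq_matrix.sites):
        if site.id not in arr_site_ids:
            continue
        ja = arr_site_ids[site.id]
        gs = seq_matrix.genotypes[seq_rows, j]
        ga = array_matrix.genotypes[arr_rows, ja]
        both = ga != MISSING
        nn = int(((gs == MISSING) & both).sum())
        called = both & (gs != MISSING)
        under = int((gs[called] < ga[called]).sum())
        over = int((gs[called] > ga[called]).sum())
        match = int((gs[called] == ga[called]).sum())
        hwe_seq = hwe_test(*_genotype_counts(gs))[0] if (gs != MISSING).any() else 0.0
        hwe_arr = hwe_test(*_genotype_counts(ga))[0] if both.any() else 0.0
        hidden = None
        for chrom, pos, var_class in known_sites_nearby:
            if chrom == site.chrom and 0 < abs(pos - site.pos) <= flag_distance:
                dist = abs(pos - site.pos)
                if hidden is None or dist < hidden[0]:
                    hidden = (dist, var_class)
        results.append(
            PlatformComparison(
                site_id=site.id,
                n_match=match,
                n_under_call=under,
                n_over_call=over,
                n_nn=nn,
                hwe_seq=hwe_seq,
                hwe_array=hwe_arr,
                hidden_variant=hidden,
            )
        )
        tot["match"] += match
        tot["under"] += under
        tot["over"] += over
        tot["nn"] += nn
        tot["n"] += match + under + over + nn
    totals = PlatformTotals(
        n_comparisons=tot["n"],
        n_match=tot["match"],
        n_under_call=tot["under"],
        n_over_call=tot["over"],
        n_nn=tot["nn"],
    )
    return results, totals
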