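"""Indel genotyping and filtering from per-sample read support.

Candidates from multiple samples are clustered (left-normalization plus
merging within homopolymer / di-nucleotide runs, where a local reference
sequence is available), each sample is genotyped from the proportion of
indel-supporting reads (het inside the inclusive 0.2-0.8 band), sites must
show adequate read support in at least one sample (stricter for rare
indels), and finally sites are tested for HWE in the controls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import MISSING
from .variant_qc import HWE_P_THRESHOLD, hwe_test

logger = logging.getLogger(__name__)

HET_BAND = (0.2, 0.8)  # inclusive proportion band for heterozygotes
COMMON_SUPPORT = (8, 3)  # (min coverage, min indel reads), MAF >= 0.01
RARE_SUPPORT = (10, 5)  # stricter rule for MAF < 0.01
RARE_MAF = 0.01


@dataclass(frozen=True)
class IndelCandidate:
    """One per-sample candidate: position, signed length, allele sequence."""

    sample_id: str
    chrom: str
    pos: int
    length: int  # negative = deletion
    seq: str

    def __post_init__(self) -> None:
        if self.length == 0:
            raise ValueError("indel length must be non-zero")
        if len(self.seq) != abs(self.length):
            raise ValueError("seq length must match |length|")


@dataclass
class IndelObservation:
    sample_id: str
    site_id: str
    reads_total: int
    reads_indel: int

    def __post_init__(self) -> None:
        if not 0 <= self.reads_indel <= self.reads_total:
            raise ValueError("need 0 <= reads_indel <= reads_total")


@dataclass
class IndelSite:
    """A clustered indel site with its genotype calls and filter flags."""

    chrom: str
    pos: int  # leftmost member position after normalization
    length: int
    seq: str
    cluster_members: list[int] = field(default_factory=list)  # original positions
    genotypes: dict[str, int] = field(default_factory=dict)  # sample -> code
    maf: float = float("nan")
    support_pass: bool = False
    hwe_pass: bool = False

    @property
    def site_id(self) -> str:
        return f"{self.chrom}_{self.pos}_{'ins' if self.length > 0 else 'del'}{abs(self.length)}"


@dataclass
class IndelLedger:
    n_candidates: int = 0
    n_support_pass: int = 0
    n_hwe_pass: int = 0

    @property
    def hwe_pass_pct(self) -> float:
        """Percent of candidate sites passing the HWE filter."""
        return 100.0 * self.n_hwe_pass / self.n_candidates if self.n_candidates else float("nan")


def left_normalize(pos: int, length: int, seq: str, reference: str) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent placement on ``reference``.

    ``reference`` is the full chromosome (or interval) sequence, 1-based
    addressed via ``pos``.  For a deletion, ``seq`` is the deleted bases
    starting at ``pos``; for an insertion, the bases inserted before ``pos``.
    """
    seq = seq.upper()
    p = pos
    while p > 1 and reference[p - 2].upper() == seq[-1]:
        seq = reference[p - 2].upper() + seq[:-1]
        p -= 1
    return p, seq


def _run_extent(reference: str, pos: int) -> tuple[int, int]:
    """Extent [start, end] (1-based, inclusive) of the homopolymer or
    di-nucleotide run covering ``pos``; degenerate runs return (pos, pos)."""
    n = len(reference)
    best = (pos, pos)
    for unit in (1, 2):
        if pos + unit - 1 > n:
            continue
        motif = reference[pos - 1 : pos - 1 + unit].upper()
        start = pos
        while start - unit >= 1 and reference[start - unit - 1 : start - 1].upper() == motif:
            start -= unit
        end = pos
        while end + 2 * unit - 1 <= n and reference[end + unit - 1 : end + 2 * unit - 1].upper() == motif:
            end += unit
        if end + unit - 1 - start > best[1] - best[0]:
            best = (start, end + unit - 1)
    return best


def cluster_candidates(
    candidates: Iterable[IndelCandidate],
    reference: Optional[str] = None,
) -> list[IndelSite]:
    """Merge equivalent per-sample indel candidates into population sites.

    With a reference, candidates are left-normalized first and candidates of
    identical (length, sequence) whose normalized positions fall inside the
    same repeat run also merge.  Without a reference only candidates agreeing
    exactly in (position, length, sequence) merge.  Distinct allele strings
    at one position are kept as distinct sites (a warning is logged).
    Idempotent and independent of input order.
    """
    normalized: dict[tuple[str, int, int, str], IndelSite] = {}
    originals: dict[tuple[str, int, int, str], set[int]] = {}
    for cand in sorted(candidates, key=lambda c: (c.chrom, c.pos, c.length, c.seq, c.sample_id)):
        pos, seq = cand.pos, cand.seq
        if reference is not None:
            pos, seq = left_normalize(cand.pos, cand.length, cand.seq, reference)
        key = (cand.chrom, pos, cand.length, seq)
        if key not in normalized:
            normalized[key] = IndelSite(chrom=cand.chrom, pos=pos, length=cand.length, seq=seq)
            originals[key] = set()
        originals[key].add(cand.pos)

    sites = list(normalized.values())
    keys = list(normalized.keys())
    if reference is not None:
        # second pass: merge same-allele sites sharing a repeat run
        merged: list[IndelSite] = []
        used = [False] * len(sites)
        order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
        for oi, i in enumerate(order):
            if used[i]:
                continue
            anchor = sites[i]
            run = _run_extent(reference, anchor.pos)
            members = originals[keys[i]].copy()
            for j in order[oi + 1 :]:
                if used[j]:
                    continue
                other = sites[j]
                if (
                    other.chrom == anchor.chrom
                    and other.length == anchor.length
                    and other.seq == anchor.seq
                    and run[0] <= other.pos <= run[1]
                ):
                    used[j] = True
                    members |= originals[keys[j]]
            used[i] = True
            anchor.cluster_members = sorted(members)
            merged.append(anchor)
        sites = merged
    else:
        for site, key in zip(sites, keys):
            site.cluster_members = sorted(originals[key])

    by_pos: dict[tuple[str, int], list[IndelSite]] = {}
    for s in sites:
        by_pos.setdefault((s.chrom, s.pos), []).append(s)
    for (chrom, pos), group in by_pos.items():
        if len(group) > 1:
            logger.warning(
                "distinct indel alleles at %s:%d kept as %d separate sites", chrom, pos, len(group)
            )
    return sorted(sites, key=lambda s: (s.chrom, s.pos, s.length, s.seq))


def genotype_from_proportion(obs: IndelObservation) -> int:
    """Genotype from the proportion of indel-supporting reads.

    het if 0.2 <= p <= 0.8 (inclusive band), hom-ref below, hom-alt above,
    missing when there are no reads.  Monotone in ``reads_indel`` at fixed
    coverage.
    """
    if obs.reads_total == 0:
        return MISSING
    p = obs.reads_indel / obs.reads_total
    if p < HET_BAND[0]:
        return 0
    if p > HET_BAND[1]:
        return 2
    return 1


def site_support_filter(observations: Sequence[IndelObservation], maf: float) -> bool:
    """Read-support rule: at least one sample must clear the coverage/support bar.

    Common indels (MAF >= 0.01): >= 8 reads covering with >= 3 carrying the
    indel.  Rare indels (MAF < 0.01): >= 10 covering with >= 5 carrying.
    Boundaries inclusive.
    """
    min_cov, min_indel = RARE_SUPPORT if maf < RARE_MAF else COMMON_SUPPORT
    return any(o.reads_total >= min_cov and o.reads_indel >= min_indel for o in observations)


def _site_maf(genotypes: dict[str, int]) -> float:
    codes = np.array([g for g in genotypes.values() if g != MISSING])
    if codes.size == 0:
        return float("nan")
    f = codes.sum() / (2 * codes.size)
    return min(f, 1 - f)


def call_indels(
    observations: pd.DataFrame,
    control_ids: Sequence[str],
    reference: Optional[str] = None,
) -> tuple[list[IndelSite], IndelLedger]:
    """Full indel pipeline: cluster, genotype, support filter, HWE filter.

    ``observations`` columns: sample_id, chrom, pos, length, seq,
    reads_total, reads_indel.  Each row is both a candidate (where
    reads_indel > 0) and a read-support observation.  Returns all clustered
    sites (flags set) and the stage ledger; the HWE filter applies
    :func:`extremeseq.variant_qc.hwe_test` on control genotypes at
    P >= 0.001.
    """
    ledger = IndelLedger()
    if len(observations) == 0:
        return [], ledger
    control_set = set(control_ids)

    candidates = [
        IndelCandidate(r.sample_id, r.chrom, int(r.pos), int(r.length), r.seq)
        for r in observations.itertuples()
        if r.reads_indel > 0
    ]
    sites = cluster_candidates(candidates, reference=reference)
    ledger.n_candidates = len(sites)

    obs_by_key: dict[tuple[str, int], dict[str, tuple[int, int]]] = {}
    for r in observations.itertuples():
        key = (r.chrom, int(r.pos))
        per_sample = obs_by_key.setdefault(key, {})
        prev = per_sample.get(r.sample_id)
        if prev is None or r.reads_total > prev[0]:
            per_sample[r.sample_id] = (int(r.reads_total), int(r.reads_indel))

    for site in sites:
        per_sample: dict[str, tuple[int, int]] = {}
        for pos in site.cluster_members or [site.pos]:
            for sid, (tot, ind) in obs_by_key.get((site.chrom, pos), {}).items():
                prev = per_sample.get(sid)
                if prev is None or tot > prev[0]:
                    per_sample[sid] = (tot, ind)
        obs_list = [
            IndelObservation(sid, site.site_id, tot, ind) for sid, (tot, ind) in sorted(per_sample.items())
        ]
        site.genotypes = {
            o.sample_id: genotype_from_proportion(o) for o in obs_list if o.reads_total > 0
        }
        site.maf = _site_maf(site.genotypes)
        site.support_pass = site_support_filter(obs_list, site.maf)
        if site.support_pass:
            ctrl = [g for sid, g in site.genotypes.items() if sid in control_set and g != MISSING]
            counts = (ctrl.count(0), ctrl.count(1), ctrl.count(2))
            if sum(counts) == 0:
                site.hwe_pass = True
            else:
                _, p, _ = hwe_test(*counts)
                site.hwe_pass = p >= HWE_P_THRESHOLD

    ledger.n_support_pass = sum(s.support_pass for s in sites)
    ledger.n_hwe_pass = sum(s.hwe_pass for s in sites)
    return sites, ledger
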