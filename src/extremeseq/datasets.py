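"""Bundled worked-example count tables for the pipeline's QC summaries.

These are the published headline numbers of a targeted re-sequencing
case/control study of BMI extremes (289 samples, two candidate-gene
intervals): the cross-platform genotype comparison for 19 assayed SNPs, the
five-status tally of 1,697 blind-replicate genotype pairs, the SNV and indel
filter-cascade counts, and the carrier-group metabolite summaries.  They
serve as fixed inputs for exercising the concordance, ledger and contrast
operations on realistic numbers; helpers below materialize them as the
package's own data structures so the actual pipeline code runs on them.
"""

from __future__ import annotations

import numpy as np

from .concordance import GenotypePair
from .core import MISSING, GenotypeMatrix, VariantSite
from .indels import IndelLedger
from .metabolites import GroupSummary
from .variant_qc import QCLedger, SiteQCReport

#: per-SNP cross-platform comparison: matches, under-calls, over-calls, N/N,
#: HWE statistic on each platform, and any known variant near the assay site
PLATFORM_COMPARISON = [
    # (snp_id, match, under, over, nn, hwe_seq, hwe_array, hidden (bp, class) or None)
    ("rs594323", 253, 1, 33, 2, 1.2, 4.2, (22, "SNP")),
    ("rs9759081", 272, 15, 2, 0, 0.0, 8.6, (19, "SNP")),
    ("rs9852837", 276, 0, 13, 0, 0.2, 0.01, (38, "indel")),
    ("rs4141964", 287, 1, 0, 1, 1.6, 1.2, None),
    ("rs324419", 287, 2, 0, 0, 0.7, 0.9, None),
    ("rs17203666", 289, 0, 0, 0, 0.6, 0.6, None),
    ("rs11715363", 286, 3, 0, 0, 0.1, 0.0, None),
    ("rs17203659", 288, 1, 0, 0, 0.2, 0.0, None),
    ("rs6778770", 287, 0, 1, 0, 0.2, 0.3, None),
    ("rs17282181", 283, 4, 2, 0, 0.0, 0.2, None),
    ("rs497897", 287, 1, 1, 0, 1.2, 0.2, None),
    ("rs567384", 283, 4, 2, 0, 2.3, 0.6, None),
    ("rs3773155", 286, 3, 0, 0, 0.0, 0.0, None),
    ("rs3773159", 286, 1, 2, 0, 2.3, 2.1, None),
    ("rs13076593", 288, 1, 0, 0, 0.8, 0.1, None),
    ("rs936839", 288, 1, 0, 0, 1.1, 1.2, None),
    ("rs13066225", 289, 0, 0, 0, 0.1, 0.1, None),
    ("rs324420", 289, 0, 0, 0, 0.0, 0.0, None),
    ("rs7652615", 289, 0, 0, 0, 0.4, 0.4, None),
]

#: blind-replicate matching statuses over 1,697 compared genotype pairs
REPLICATE_STATUS_COUNTS = {1: 1612, 2: 5, 3: 31, 4: 34, 5: 15}

#: SNV filter cascade: raw calls, biallelic, HWE-passing (controls, P >= 1e-3),
#: final confidently-called set, and composition of the final set
SNV_FILTER_COUNTS = dict(
    raw=1448, biallelic=1433, hwe_pass=1403, final=1393,
    known=433, singletons=512, maf_below_1pct=762,
)

#: indel filter cascade: clustered candidates and HWE-passing sites
INDEL_FILTER_COUNTS = dict(candidates=240, hwe_pass=143)

#: carrier-group metabolite summaries: for each associated locus-variant and
#: metabolite, the carrier-case and non-carrier-control groups (n, mean, sd
#: in pmol/ml) and the published pooled two-sided t-test P
METABOLITE_CONTRASTS = [
    # (locus, metabolite, carrier-case, noncarrier-control, published P)
    ("faah_promoter", "aea", (14, 17.11, 5.79), (48, 13.76, 5.51), 0.05),
    ("faah_promoter", "2ag", (14, 10.55, 10.67), (35, 6.98, 4.15), 0.10),
    ("mgll_intron3", "aea", (5, 15.60, 6.35), (48, 13.76, 5.52), 0.49),
    ("mgll_intron3", "2ag", (4, 6.43, 2.08), (35, 6.99, 4.16), 0.80),
    ("mgll_promoter", "aea", (26, 15.09, 5.60), (45, 13.80, 5.58), 0.36),
    ("mgll_promoter", "2ag", (24, 6.31, 3.06), (32, 7.22, 4.11), 0.37),
]


def replicate_pairs_fixture() -> list[GenotypePair]:
    """Materialize the replicate status tally as concrete genotype pairs."""
    pairs: list[GenotypePair] = []
    templates = {
        1: dict(g1=1, g2=1, depth1=40, depth2=40, alt_evidence2=False),
        2: dict(g1=1, g2=2, depth1=40, depth2=40, alt_evidence2=False),
        3: dict(g1=1, g2=0, depth1=40, depth2=40, alt_evidence2=True),
        4: dict(g1=1, g2=0, depth1=40, depth2=40, alt_evidence2=False),
        5: dict(g1=1, g2=0, depth1=40, depth2=12, alt_evidence2=False),
    }
    k = 0
    for status, count in REPLICATE_STATUS_COUNTS.items():
        for _ in range(count):
            pairs.append(GenotypePair(sample_id=f"P{k}", site_id=f"site{k}", **templates[status]))
            k += 1
    return pairs


def platform_matrices_fixture() -> tuple[GenotypeMatrix, GenotypeMatrix, list[tuple[str, int, str]]]:
    """Materialize the per-SNP platform comparison as two genotype matrices.

    Each site's samples are laid out to reproduce the published match /
    under-call / over-call / N-N counts; returns (sequencing matrix, array
    matrix, known-variants-nearby list) ready for ``compare_platforms``.
    """
    n = max(m + u + o + nn for _, m, u, o, nn, *_ in PLATFORM_COMPARISON)
    n_sites = len(PLATFORM_COMPARISON)
    sites = []
    known: list[tuple[str, int, str]] = []
    g_seq = np.zeros((n, n_sites), dtype=np.int8)
    g_arr = np.zeros((n, n_sites), dtype=np.int8)
    for j, (snp_id, match, under, over, nn, _hs, _ha, hidden) in enumerate(PLATFORM_COMPARISON):
        pos = 10_000 * (j + 1)
        sites.append(VariantSite("chr3", pos, "A", ("G",), site_id=snp_id))
        if hidden is not None:
            known.append(("chr3", pos + hidden[0], hidden[1]))
        i = 0
        for _ in range(match):
            g_seq[i, j] = g_arr[i, j] = 1
            i += 1
        for _ in range(under):  # sequencing shows fewer alternative alleles
            g_seq[i, j], g_arr[i, j] = 0, 1
            i += 1
        for _ in range(over):
            g_seq[i, j], g_arr[i, j] = 1, 0
            i += 1
        for _ in range(nn):
            g_seq[i, j], g_arr[i, j] = MISSING, 1
            i += 1
        while i < n:  # pad samples not compared at this assay: array missing
            g_seq[i, j], g_arr[i, j] = 0, MISSING
            i += 1
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    depth = np.full((n, n_sites), 40, dtype=np.int32)
    qual = np.full((n, n_sites), 60, dtype=np.int16)
    seq_m = GenotypeMatrix(sample_ids, sites, g_seq, depth, qual)
    arr_m = GenotypeMatrix(list(sample_ids), list(sites), g_arr, depth.copy(), qual.copy())
    return seq_m, arr_m, known


def snv_ledger_fixture() -> QCLedger:
    """The SNV filter cascade as a QC ledger."""
    c = SNV_FILTER_COUNTS
    return QCLedger(
        n_input=c["raw"],
        n_biallelic=c["biallelic"],
        n_hwe_pass=c["hwe_pass"],
        n_call_rate_pass=c["final"],
        n_multiallelic=c["raw"] - c["biallelic"],
    )


def indel_ledger_fixture() -> IndelLedger:
    c = INDEL_FILTER_COUNTS
    return IndelLedger(
        n_candidates=c["candidates"], n_support_pass=c["candidates"], n_hwe_pass=c["hwe_pass"]
    )


def snv_reports_fixture() -> tuple[list[SiteQCReport], set[str]]:
    """Minimal passing-site reports matching the final SNV set's composition."""
    c = SNV_FILTER_COUNTS
    reports = []
    known_ids: set[str] = set()
    for i in range(c["final"]):
        site = VariantSite("chr3", i + 1, "A", ("G",), site_id=f"v{i}")
        singleton = i < c["singletons"]
        rare = i < c["maf_below_1pct"]
        maf = 1 / 578 if singleton else (0.005 if rare else 0.2)
        reports.append(
            SiteQCReport(
                site=site,
                genotype_counts_controls=(147, 0, 0),
                hwe_stat=0.0,
                hwe_p=1.0,
                het_direction="none",
                call_rate=1.0,
                maf=maf,
                minor_allele_count=1 if singleton else (3 if rare else 120),
                is_singleton=singleton,
            )
        )
        if i >= c["final"] - c["known"]:
            known_ids.add(f"v{i}")
    return reports, known_ids


def metabolite_group_summaries() -> list[tuple[str, str, GroupSummary, GroupSummary, float]]:
    out = []
    for locus, metab, g1, g2, p in METABOLITE_CONTRASTS:
        out.append(
            (
                locus,
                metab,
                GroupSummary("carrier-case", *g1),
                GroupSummary("noncarrier-control", *g2),
                p,
            )
        )
    return out
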