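"""Reading and writing the pipeline's on-disk formats.

Genotype matrices travel as VCF v4.2 with FORMAT fields GT, DP, GQ and
missing genotypes encoded "./."; sample tables, truth records, QC reports
and association results as TSV.  VCF writing goes through pysam and reading
through cyvcf2.  No timestamps or environment details are written, so
outputs are byte-identical across reruns with the same seed.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .core import MISSING, GenotypeMatrix, VariantSite
from .variant_qc import SiteQCReport


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a genotype matrix as VCF v4.2 (GT/DP/GQ, "./." for missing)."""
    header = pysam.VariantHeader()
    contigs = sorted({s.chrom for s in matrix.sites})
    max_pos = {c: max(s.pos for s in matrix.sites if s.chrom == c) for c in contigs}
    for c in contigs:
        header.contigs.add(c, length=max_pos[c] + 10_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Phred-scaled consensus genotype quality")
    header.info.add("VC", 1, "String", "Variant class (SNV or indel)")
    for s in matrix.sample_ids:
        header.add_sample(s)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(path, "w", header=header) as out:
        order = sorted(range(matrix.n_sites), key=lambda j: (matrix.sites[j].chrom, matrix.sites[j].pos))
        for j in order:
            site = matrix.sites[j]
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref_allele),
                alleles=(site.ref_allele, *site.alt_alleles),
                id=site.site_id,
            )
            rec.info["VC"] = site.var_class
            for i, sample in enumerate(matrix.sample_ids):
                rec.samples[sample]["GT"] = gt_map[int(matrix.genotypes[i, j])]
                rec.samples[sample]["DP"] = int(matrix.depth[i, j])
                rec.samples[sample]["GQ"] = int(matrix.quality[i, j])
            out.write(rec)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a genotype matrix (alt-allele dosage coding)."""
    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    sites: list[VariantSite] = []
    genotypes, depths, quals = [], [], []
    for var in vcf:
        sites.append(
            VariantSite(
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_alleles=tuple(var.ALT),
                var_class=(var.INFO.get("VC") or ("indel" if var.is_indel else "SNV")),
                site_id=var.ID,
            )
        )
        # cyvcf2 genotypes: [allele1, allele2, phased]
        g = np.array(
            [
                (gt[0] + gt[1]) if gt[0] >= 0 and gt[1] >= 0 else MISSING
                for gt in var.genotypes
            ],
            dtype=np.int8,
        )
        genotypes.append(g)
        dp = var.format("DP")
        depths.append(np.where(dp is None, 0, dp).reshape(-1) if dp is not None else np.zeros(len(sample_ids)))
        gq = var.format("GQ")
        quals.append(np.where(gq is None, 0, gq).reshape(-1) if gq is not None else np.zeros(len(sample_ids)))
    vcf.close()
    n = len(sample_ids)
    if not sites:
        empty = np.zeros((n, 0))
        return GenotypeMatrix(sample_ids, [], empty, empty, empty)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        sites=sites,
        genotypes=np.stack(genotypes, axis=1),
        depth=np.clip(np.stack(depths, axis=1), 0, None),
        quality=np.clip(np.stack(quals, axis=1), 0, None),
    )


def write_samples(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def case_status(samples: pd.DataFrame, matrix: GenotypeMatrix) -> np.ndarray:
    """Boolean case flags aligned to the matrix sample order."""
    groups = samples.set_index("sample_id")["group"]
    return np.array([groups[s] == "case" for s in matrix.sample_ids], dtype=bool)


def write_truth(truth, sample_ids: Sequence[str], path: str) -> None:
    pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "carrier": np.asarray(truth.carrier, dtype=int),
            "liability_bmi": np.round(truth.liability_bmi, 4),
        }
    ).to_csv(path, sep="\t", index=False)
    with open(os.path.splitext(path)[0] + "_sites.tsv", "w") as fh:
        fh.write("causal_position\n")
        for p in truth.causal_variant_positions:
            fh.write(f"{p}\n")


def read_known_sites(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_qc_reports(reports: Iterable[SiteQCReport], path: str) -> None:
    rows = []
    for r in reports:
        rows.append(
            {
                "site_id": r.site.id,
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "n_homref_controls": r.genotype_counts_controls[0],
                "n_het_controls": r.genotype_counts_controls[1],
                "n_homalt_controls": r.genotype_counts_controls[2],
                "hwe_stat": round(r.hwe_stat, 6),
                "hwe_p": r.hwe_p,
                "het_direction": r.het_direction,
                "call_rate": round(r.call_rate, 6),
                "maf": round(r.maf, 6) if r.maf == r.maf else "",
                "minor_allele_count": r.minor_allele_count,
                "is_singleton": int(r.is_singleton),
                "is_known": int(r.is_known),
                "verdict": r.verdict,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
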