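"""Core containers shared by every stage of the pipeline.

Genotypes are stored as small integers counting alternative alleles
(0 = hom-ref, 1 = het, 2 = hom-alt, ``MISSING`` = no call), with per-genotype
read depth and phred-scaled consensus quality alongside, because every
downstream filter (masking, call rate, HWE, association) operates on exactly
this triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: sentinel for a missing / masked genotype call
MISSING: int = -1

GENOTYPE_LABELS = {0: "homref", 1: "het", 2: "homalt", MISSING: "missing"}


@dataclass(frozen=True)
class VariantSite:
    """One variant site: position, alleles and class.

    ``pos`` is 1-based.  ``site_id`` defaults to the ``chrom_pos`` convention
    used for novel variants (e.g. ``Chr3_128957192``).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    var_class: str = "SNV"  # "SNV" | "indel"
    site_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.alt_alleles:
            raise ValueError("alt_alleles must be non-empty")
        if self.ref_allele in self.alt_alleles:
            raise ValueError("alt alleles must differ from the reference allele")
        if len(set(self.alt_alleles)) != len(self.alt_alleles):
            raise ValueError("alt alleles must be distinct")
        if self.var_class not in ("SNV", "indel"):
            raise ValueError(f"unknown var_class {self.var_class!r}")

    @property
    def id(self) -> str:
        return self.site_id if self.site_id is not None else f"{self.chrom}_{self.pos}"

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1


@dataclass
class GenotypeMatrix:
    """Samples x sites genotype matrix with per-genotype depth and quality.

    ``genotypes`` counts alternative alleles per (sample, site); ``MISSING``
    marks no-calls.  ``alt_evidence`` optionally records, per genotype, whether
    the alternative allele appeared as the second most likely raw consensus
    call (used by the replicate-concordance taxonomy).
    """

    sample_ids: list[str]
    sites: list[VariantSite]
    genotypes: np.ndarray  # (n_samples, n_sites) int8
    depth: np.ndarray  # (n_samples, n_sites) int32
    quality: np.ndarray  # (n_samples, n_sites) int16, phred scale
    alt_evidence: Optional[np.ndarray] = None  # (n_samples, n_sites) bool

    def __post_init__(self) -> None:
        shape = (len(self.sample_ids), len(self.sites))
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        self.quality = np.asarray(self.quality, dtype=np.int16)
        for name in ("genotypes", "depth", "quality"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if self.alt_evidence is not None:
            self.alt_evidence = np.asarray(self.alt_evidence, dtype=bool)
            if self.alt_evidence.shape != shape:
                raise ValueError("alt_evidence shape mismatch")
        bad = (self.genotypes < MISSING) | (self.genotypes > 2)
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self, site_id: str) -> int:
        for i, s in enumerate(self.sites):
            if s.id == site_id:
                return i
        raise KeyError(site_id)

    def sample_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from exc

    def called(self) -> np.ndarray:
        """Boolean mask of called (non-missing) genotypes."""
        return self.genotypes != MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=list(self.sites),
            genotypes=self.genotypes.copy(),
            depth=self.depth.copy(),
            quality=self.quality.copy(),
            alt_evidence=None if self.alt_evidence is None else self.alt_evidence.copy(),
        )

    def subset_sites(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=[self.sites[i] for i in idx],
            genotypes=self.genotypes[:, idx],
            depth=self.depth[:, idx],
            quality=self.quality[:, idx],
            alt_evidence=None if self.alt_evidence is None else self.alt_evidence[:, idx],
        )
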