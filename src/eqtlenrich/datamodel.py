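"""Core in-memory containers shared by every pipeline stage.

Coordinate convention: everything internal is 0-based, half-open (BED
semantics). VCF positions (1-based) are converted at the I/O boundary;
:class:`SnpMeta` stores the 1-based position as read and exposes the
internal coordinate via :attr:`SnpMeta.pos0`.

Missing dosages are encoded as ``numpy.nan`` in the float dosage matrix,
which is distinct from every valid dosage in [0, 2]. Imputation happens at
analysis time, never at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SnpMeta",
    "GenotypeMatrix",
    "GeneRecord",
    "MolecularProfiles",
    "GwasSnp",
    "DeRecord",
    "GeneSet",
]


@dataclass(frozen=True)
class SnpMeta:
    """Metadata for one variant. ``pos`` is 1-based (VCF convention)."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in [0, 0.5], got {self.maf}")

    @property
    def pos0(self) -> int:
        """Internal 0-based position."""
        return self.pos - 1


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alt-allele dosage matrix with per-SNP metadata.

    ``dosages`` is float with values in [0, 2]; hard calls are {0, 1, 2};
    missing cells are NaN.
    """

    snps: list[SnpMeta]
    sample_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snps):
            raise ValueError(
                f"dosage matrix is {self.dosages.shape}, expected "
                f"({len(self.sample_ids)}, {len(self.snps)})"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in genotype panel")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")
        self._index = {sid: j for j, sid in enumerate(ids)}

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"snp_id {snp_id!r} not in panel") from None

    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(snp_id)]

    def snp_meta(self, snp_id: str) -> SnpMeta:
        return self.snps[self.index_of(snp_id)]


@dataclass(frozen=True)
class GeneRecord:
    """One gene body in internal (= BED) coordinates: 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class MolecularProfiles:
    """Aligned samples x genes matrices: expression, copy number, methylation.

    Expression is log-scale abundance, copy number a relative per-gene
    summary, methylation a beta value in [0, 1]. All three share one sample
    and one gene ordering.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    expression: np.ndarray
    copy_number: np.ndarray
    methylation: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.sample_ids), len(self.gene_ids))
        for name in ("expression", "copy_number", "methylation"):
            mat = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, mat)
            if mat.shape != shape:
                raise ValueError(f"{name} matrix is {mat.shape}, expected {shape}")
        meth = self.methylation[np.isfinite(self.methylation)]
        if meth.size and (meth.min() < 0 or meth.max() > 1):
            raise ValueError("methylation beta values must lie in [0, 1]")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_id in profiles")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class GwasSnp:
    """One GWAS summary record: variant metadata plus association p-value."""

    meta: SnpMeta
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"{self.meta.snp_id}: p_value must be in (0, 1], got {self.p_value}"
            )


@dataclass(frozen=True)
class DeRecord:
    """Differential-expression record: signed linear fold change and q-value."""

    gene_id: str
    fold_change: float
    fdr: float

    def __post_init__(self) -> None:
        if self.fold_change == 0:
            raise ValueError(f"{self.gene_id}: fold_change must be nonzero")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"{self.gene_id}: fdr must be in [0, 1], got {self.fdr}")


@dataclass
class GeneSet:
    name: str
    gene_ids: set = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.gene_ids)
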