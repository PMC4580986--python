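import numpy as np
import pytest

from eqtlenrich.datamodel import GeneRecord, GenotypeMatrix, GwasSnp, SnpMeta


def make_genotypes(dosages, positions=None, chrom="chr1", mafs=None, sample_prefix="S"):
    """Build a GenotypeMatrix from a raw samples x SNPs array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    positions = positions or [(j + 1) * 1000 for j in range(m)]
    mafs = mafs or [0.3] * m
    snps = [
        SnpMeta(f"snp{j + 1}", chrom, positions[j], "A", "G", mafs[j]) for j in range(m)
    ]
    return GenotypeMatrix(
        snps=snps,
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n)],
        dosages=dosages,
    )


def make_gwas(pvalues, positions=None, chrom="chr1", maf=0.3):
    positions = positions or [(j + 1) * 1000 for j in range(len(pvalues))]
    return [
        GwasSnp(SnpMeta(f"g{j + 1}", chrom, positions[j], "A", "G", maf), float(p))
        for j, p in enumerate(pvalues)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_genes():
    return [
        GeneRecord("GA", "chr1", 100_000, 105_000, "+"),
        GeneRecord("GB", "chr1", 300_000, 320_000, "-"),
        GeneRecord("GC", "chr2", 100_000, 105_000, "+"),
    ]
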