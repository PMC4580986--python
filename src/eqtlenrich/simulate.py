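"""Synthetic input generation for the full pipeline.

The generators emulate the statistical structure the downstream analysis
assumes about its real-world inputs:

* a tumor cohort of 339 samples whose per-gene expression is a linear
  combination of a somatic copy-number track (~14% of variance), a CpG
  methylation track (~4.1%), an optional cis germline genotype (~0.25%) and
  Gaussian noise;
* genotypes with block LD (Gaussian-copula haplotypes thresholded at the
  per-SNP MAF) so that high-r-squared proxies of an index SNP exist;
* GWAS summary p-values that are Uniform(0, 1) away from designated target
  genes and inflated (|Z|, Z ~ Normal(noncentrality, 1)) inside target-gene
  windows;
* differential-expression tables with an exactly known set of genes passing
  the FDR / fold-change selection filter.

Every generator is a pure function of its configuration and seed: the same
:class:`SimConfig` always yields byte-identical data. Per-stage randomness is
derived from the global seed through fixed stage tags, so regenerating one
input never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .datamodel import DeRecord, GeneRecord, GenotypeMatrix, GwasSnp, MolecularProfiles, SnpMeta
from . import io as eio

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_genotypes",
    "simulate_genes",
    "simulate_profiles",
    "simulate_gwas",
    "simulate_de_table",
    "write_bundle",
]

# fixed stage tags: each generator draws from default_rng([seed, tag])
_TAG_GENO, _TAG_GENES, _TAG_PROFILES, _TAG_GWAS, _TAG_DE = 11, 12, 13, 14, 15

_P_FLOOR = 1e-300


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the analysis setting the pipeline was designed for:
    339 tumor samples; copy number, methylation and cis genotype explaining
    14%, 4.1% and 0.25% of expression variance respectively; LD blocks with
    within-block correlation high enough that r^2 > 0.7 proxies exist; and
    GWAS signal inflation concentrated near target genes.
    """

    seed: int = 0
    n_samples: int = 339
    n_genes: int = 500
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.9
    var_frac_cn: float = 0.14
    var_frac_meth: float = 0.041
    var_frac_eqtl: float = 0.0025
    n_true_eqtls: int | None = None  # None = every gene carries a cis effect
    enrichment_noncentrality: float = 3.0
    n_target_genes: int = 128
    # genome layout
    chrom: str = "chr1"
    snp_spacing: int = 10_000
    gene_length: int = 20000
    cis_window: int = 250_000
    gwas_flank: int = 50_000
    # covariate distributions
    cn_amplitude: float = 1.0
    cn_state_probs: tuple[float, float, float] = (0.25, 0.5, 0.25)
    meth_beta_params: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        fracs = (self.var_frac_cn, self.var_frac_meth, self.var_frac_eqtl)
        if any(f < 0 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("variance fractions must be >= 0 and sum to < 1")
        if not (0.0 <= self.ld_rho <= 1.0):
            raise ValueError(f"ld_rho must be in [0, 1], got {self.ld_rho}")
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within [0.05, 0.5], got {self.maf_range}")


@dataclass
class TruthTable:
    """Ground truth recorded by the generators for recovery tests."""

    eqtls: list[tuple[str, str, float]] = field(default_factory=list)
    target_genes: list[str] = field(default_factory=list)
    realized_frac_cn: float = 0.0
    realized_frac_meth: float = 0.0
    realized_frac_eqtl: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        d["eqtls"] = [tuple(t) for t in d["eqtls"]]
        return cls(**d)


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Hard-call dosages with block LD on a single chromosome.

    Two haplotypes per sample are drawn from a per-block equicorrelated
    Gaussian copula (correlation ``ld_rho``) and thresholded at each SNP's
    MAF quantile; the dosage is their sum, so values are {0, 1, 2} and, at
    ``ld_rho = 1`` with equal MAFs, SNPs within a block are identical.
    """
    if config.n_snps % config.ld_block_size != 0:
        raise ValueError(
            f"n_snps ({config.n_snps}) must be divisible by ld_block_size "
            f"({config.ld_block_size})"
        )
    rng = _rng(config, _TAG_GENO)
    n, m = config.n_samples, config.n_snps
    n_blocks = m // config.ld_block_size
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)
    block_of = np.repeat(np.arange(n_blocks), config.ld_block_size)
    rho = config.ld_rho
    dosages = np.zeros((n, m))
    for _hap in range(2):
        common = rng.standard_normal((n, n_blocks))
        indep = rng.standard_normal((n, m))
        z = np.sqrt(rho) * common[:, block_of] + np.sqrt(1.0 - rho) * indep
        dosages += (z < thresholds[None, :]).astype(float)
    width = len(str(m))
    snps = [
        SnpMeta(
            snp_id=f"snp{j + 1:0{width}d}",
            chrom=config.chrom,
            pos=(j + 1) * config.snp_spacing,
            ref_allele="A",
            alt_allele="G",
            maf=float(mafs[j]),
        )
        for j in range(m)
    ]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(snps=snps, sample_ids=sample_ids, dosages=dosages)


def simulate_genes(config: SimConfig) -> list[GeneRecord]:
    """Tile ``n_genes`` gene bodies across the simulated SNP region."""
    region = config.n_snps * config.snp_spacing
    step = max(region // max(config.n_genes, 1), config.gene_length // 2)
    width = len(str(config.n_genes))
    genes = []
    for i in range(config.n_genes):
        start = i * step
        genes.append(
            GeneRecord(
                gene_id=f"G{i + 1:0{width}d}",
                chrom=config.chrom,
                start=start,
                end=start + config.gene_length,
                strand="+",
            )
        )
    return genes


# ---------------------------------------------------------------------------
# molecular profiles
# ---------------------------------------------------------------------------

def simulate_profiles(
    genotypes: GenotypeMatrix,
    genes: list[GeneRecord],
    config: SimConfig,
) -> tuple[MolecularProfiles, TruthTable]:
    """Expression as a per-gene linear model over CN, methylation, genotype.

    Coefficients are scaled against the *empirical* standard deviation of
    each gene's covariate realization so the per-gene population variance
    fractions hit the configured targets exactly (up to covariate
    cross-correlation); the noise variance absorbs the remainder. The first
    ``n_true_eqtls`` fraction of genes (a seeded random subset; all genes if
    ``None``) receive a cis genotype term from a SNP within ``cis_window``
    of the gene body.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    n_true = len(genes) if config.n_true_eqtls is None else config.n_true_eqtls
    if n_true > len(genes):
        raise ValueError(f"n_true_eqtls ({n_true}) exceeds n_genes ({len(genes)})")
    rng = _rng(config, _TAG_PROFILES)
    n = len(genotypes.sample_ids)
    g = len(genes)

    cn_states = rng.choice(
        np.array([-1.0, 0.0, 1.0]), size=(n, g), p=np.asarray(config.cn_state_probs)
    )
    cn = cn_states * config.cn_amplitude
    a, b = config.meth_beta_params
    meth = rng.beta(a, b, size=(n, g))

    planted = sorted(rng.choice(g, size=n_true, replace=False).tolist())
    planted_set = set(planted)
    snp_pos0 = np.array([s.pos0 for s in genotypes.snps])

    expr = np.zeros((n, g))
    truth = TruthTable()
    fr_cn, fr_me, fr_eq = [], [], []
    for gi, gene in enumerate(genes):
        parts = []
        # copy number layer
        sd = cn[:, gi].std()
        f_cn = config.var_frac_cn if sd > 0 else 0.0
        if f_cn > 0:
            parts.append(np.sqrt(f_cn) / sd * (cn[:, gi] - cn[:, gi].mean()))
        # methylation layer
        sd = meth[:, gi].std()
        f_me = config.var_frac_meth if sd > 0 else 0.0
        if f_me > 0:
            parts.append(np.sqrt(f_me) / sd * (meth[:, gi] - meth[:, gi].mean()))
        # cis genotype layer
        f_eq = 0.0
        if gi in planted_set and config.var_frac_eqtl > 0:
            center = (gene.start + gene.end) // 2
            cand = np.flatnonzero(np.abs(snp_pos0 - center) <= config.cis_window)
            rng.shuffle(cand)
            for j in cand:
                x = genotypes.dosages[:, j]
                sd = x.std()
                if sd > 0:
                    f_eq = config.var_frac_eqtl
                    beta = np.sqrt(f_eq) / sd
                    parts.append(beta * (x - x.mean()))
                    truth.eqtls.append((genotypes.snps[j].snp_id, gene.gene_id, float(beta)))
                    break
        noise_sd = np.sqrt(max(1.0 - f_cn - f_me - f_eq, 0.0))
        y = np.sum(parts, axis=0) if parts else np.zeros(n)
        y = y + rng.normal(0.0, noise_sd, size=n)
        expr[:, gi] = y
        vy = y.var()
        fr_cn.append(f_cn / vy)
        fr_me.append(f_me / vy)
        fr_eq.append(f_eq / vy)

    truth.realized_frac_cn = float(np.mean(fr_cn))
    truth.realized_frac_meth = float(np.mean(fr_me))
    truth.realized_frac_eqtl = float(np.mean(fr_eq))

    profiles = MolecularProfiles(
        sample_ids=list(genotypes.sample_ids),
        gene_ids=[gene.gene_id for gene in genes],
        expression=expr,
        copy_number=cn,
        methylation=meth,
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas(
    snps: list[SnpMeta],
    genes: list[GeneRecord],
    targets: set[str],
    config: SimConfig,
) -> list[GwasSnp]:
    """Uniform p-values, inflated inside target-gene windows.

    SNPs whose internal position falls within a target gene body extended by
    ``gwas_flank`` get ``p = 2 * Phi(-|Z|)`` with ``Z ~ Normal(nc, 1)``
    (uniform when the noncentrality is 0); all other SNPs get
    ``p ~ Uniform(0, 1)``.
    """
    gene_ids = {g.gene_id for g in genes}
    missing = targets - gene_ids
    if missing:
        raise ValueError(f"targets not in annotation: {sorted(missing)[:3]}")
    rng = _rng(config, _TAG_GWAS)
    windows_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.gene_id in targets:
            windows_by_chrom.setdefault(g.chrom, []).append(
                (g.start - config.gwas_flank, g.end + config.gwas_flank)
            )
    # merge windows per chromosome so membership is a single searchsorted
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, wins in windows_by_chrom.items():
        wins.sort()
        los, his = [wins[0][0]], [wins[0][1]]
        for lo, hi in wins[1:]:
            if lo <= his[-1]:
                his[-1] = max(his[-1], hi)
            else:
                los.append(lo)
                his.append(hi)
        merged[chrom] = (np.asarray(los), np.asarray(his))

    n = len(snps)
    in_target = np.zeros(n, dtype=bool)
    for chrom, (los, his) in merged.items():
        idx = np.array([i for i, s in enumerate(snps) if s.chrom == chrom])
        if idx.size == 0:
            continue
        pos0 = np.array([snps[i].pos0 for i in idx])
        j = np.searchsorted(los, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < his[np.clip(j, 0, his.size - 1)])
        in_target[idx[ok]] = True

    p = rng.uniform(size=n)
    n_hit = int(in_target.sum())
    if n_hit:
        z = rng.normal(config.enrichment_noncentrality, 1.0, size=n_hit)
        p[in_target] = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, _P_FLOOR, 1.0)
    out = [GwasSnp(meta=s, p_value=float(p[i])) for i, s in enumerate(snps)]
    out.sort(key=lambda x: (x.meta.chrom, x.meta.pos))
    return out


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------

def simulate_de_table(
    genes: list[GeneRecord],
    n_true: int,
    config: SimConfig,
    fdr_max: float = 0.1,
    fold_min: float = 2.0,
) -> tuple[list[DeRecord], set[str]]:
    """DE table in which exactly ``n_true`` genes pass the selection filter.

    True genes get ``|fold_change| > fold_min`` and ``fdr < fdr_max``; every
    other gene fails at least one criterion (values kept clear of the
    boundaries so float comparison is unambiguous).
    """
    if n_true > len(genes):
        raise ValueError(f"n_true ({n_true}) exceeds n_genes ({len(genes)})")
    rng = _rng(config, _TAG_DE)
    idx = rng.choice(len(genes), size=n_true, replace=False) if n_true else np.array([], int)
    true_set = {genes[i].gene_id for i in idx}
    records: list[DeRecord] = []
    for gene in genes:
        sign = -1.0 if rng.uniform() < 0.5 else 1.0
        if gene.gene_id in true_set:
            fc = sign * (fold_min * 1.05 + rng.exponential(1.5))
            fdr = rng.uniform(0.0, fdr_max * 0.95)
        else:
            mode = rng.integers(3)
            small_fc = sign * rng.uniform(0.05, fold_min * 0.95)
            big_fdr = rng.uniform(fdr_max * 1.05, 1.0)
            if mode == 0:  # fold change fails
                fc, fdr = small_fc, rng.uniform(0.0, 1.0)
            elif mode == 1:  # fdr fails
                fc = sign * (fold_min * 1.05 + rng.exponential(1.5))
                fdr = big_fdr
            else:  # both fail
                fc, fdr = small_fc, big_fdr
        records.append(DeRecord(gene.gene_id, float(fc), float(fdr)))
    return records, true_set


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def write_bundle(outdir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Generate and write every pipeline input into ``outdir``.

    Emits genotypes (VCF), gene annotations (BED), the three profile TSVs,
    a GWAS summary TSV, a DE table TSV and a ground-truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotypes = simulate_genotypes(config)
    genes = simulate_genes(config)
    profiles, truth = simulate_profiles(genotypes, genes, config)
    de_records, de_truth = simulate_de_table(genes, config.n_target_genes, config)
    targets = set(de_truth)
    gwas = simulate_gwas(genotypes.snps, genes, targets, config)
    truth.target_genes = sorted(targets)

    paths: dict[str, Path] = {}
    paths["genotypes"] = outdir / "genotypes.vcf"
    eio.write_genotypes_vcf(genotypes, paths["genotypes"])
    paths["genes"] = outdir / "genes.bed"
    eio.write_gene_annotations(genes, paths["genes"])
    paths.update(write_profiles_aliased(profiles, outdir))
    paths["gwas"] = outdir / "gwas.tsv"
    eio.write_gwas_summary(gwas, paths["gwas"])
    paths["de_table"] = outdir / "de_table.tsv"
    eio.write_de_table(de_records, paths["de_table"])
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths


def write_profiles_aliased(profiles: MolecularProfiles, outdir: Path) -> dict[str, Path]:
    return eio.write_profiles(profiles, outdir)
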