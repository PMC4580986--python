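"""Readers and writers for the formats the pipeline touches.

Supported dialects
------------------
* VCF 4.x (``GT``; ``DS`` preferred when present) via :mod:`cyvcf2`.
  Multi-allelic records are skipped with a warning. VCF's 1-based positions
  are stored in :class:`~eqtlenrich.datamodel.SnpMeta.pos` unchanged; the
  internal 0-based coordinate is ``pos0``.
* Dosage TSV: samples as rows, SNPs as columns, first column ``sample_id``,
  with a ``##SNP`` metadata header line per SNP.
* BED4+ gene annotations (coordinates kept as-is: internal convention is BED).
* Header TSVs for molecular profiles, GWAS summary statistics and
  differential-expression tables.

All writers emit UTF-8, tab-delimited text with ``.`` for missing values, so
every file produced here re-reads to an equal value.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import DeRecord, GeneRecord, GenotypeMatrix, GwasSnp, MolecularProfiles, SnpMeta

log = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "read_gene_annotations",
    "write_gene_annotations",
    "read_gwas_summary",
    "write_gwas_summary",
    "read_profiles",
    "write_profiles",
    "read_de_table",
    "write_de_table",
]

_MISSING = "."


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a genotype panel from a VCF (``.vcf``) or a dosage TSV.

    Dispatch is by extension: anything ending in ``.vcf`` / ``.vcf.gz`` is
    parsed as VCF, everything else as the dosage TSV dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.name.endswith((".vcf", ".vcf.gz")):
        return _read_genotypes_vcf(path)
    return _read_genotypes_tsv(path)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    snps: list[SnpMeta] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            log.warning("skipping multi-allelic record %s at %s:%d", rec.ID, rec.CHROM, rec.POS)
            continue
        snp_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if snp_id in seen:
            raise ValueError(f"duplicate snp_id {snp_id!r} in {path}")
        seen.add(snp_id)
        try:
            ds = rec.format("DS")
        except KeyError:  # DS not declared in the header
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where(np.isfinite(col), col, np.nan)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=unknown
            col = np.asarray(rec.gt_types, dtype=float)
            col[col == 3] = np.nan
        maf = _maf_from_dosage(col, rec.INFO.get("MAF"))
        snps.append(
            SnpMeta(
                snp_id=snp_id,
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                maf=maf,
            )
        )
        columns.append(col)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    )
    return GenotypeMatrix(snps=snps, sample_ids=sample_ids, dosages=dosages)


def _maf_from_dosage(col: np.ndarray, info_maf) -> float:
    if info_maf is not None:
        return float(info_maf)
    finite = col[np.isfinite(col)]
    if finite.size == 0:
        return 0.0
    af = float(finite.mean()) / 2.0
    return min(af, 1.0 - af)


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT (hard calls) and DS (dosage) fields."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        chroms = []
        for s in gm.snps:
            if s.chrom not in chroms:
                chroms.append(s.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        order = sorted(range(len(gm.snps)), key=lambda j: (gm.snps[j].chrom, gm.snps[j].pos))
        for j in order:
            s = gm.snps[j]
            cells = []
            for v in gm.dosages[:, j]:
                if not math.isfinite(v):
                    cells.append("./.:.")
                else:
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(round(v)), "./.")
                    cells.append(f"{gt}:{v:.6g}")
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.snp_id}\t{s.ref_allele}\t{s.alt_allele}\t.\t.\t"
                f"MAF={s.maf:.6g}\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Dosage TSV: ``##SNP`` metadata lines, then samples x SNPs values."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in gm.snps:
            fh.write(
                f"##SNP\t{s.snp_id}\t{s.chrom}\t{s.pos}\t{s.ref_allele}\t"
                f"{s.alt_allele}\t{s.maf:.10g}\n"
            )
        fh.write("sample_id\t" + "\t".join(gm.snp_ids) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            cells = [
                _MISSING if not math.isfinite(v) else f"{v:.10g}" for v in gm.dosages[i]
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    metas: dict[str, SnpMeta] = {}
    header: list[str] | None = None
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##SNP"):
                parts = line.split("\t")
                if len(parts) != 7:
                    raise ValueError(f"{path}:{lineno}: malformed ##SNP line")
                _, snp_id, chrom, pos, ref, alt, maf = parts
                if snp_id in metas:
                    raise ValueError(f"{path}:{lineno}: duplicate snp_id {snp_id!r}")
                metas[snp_id] = SnpMeta(snp_id, chrom, int(pos), ref, alt, float(maf))
            elif header is None:
                header = line.split("\t")
                if header[0] != "sample_id":
                    raise ValueError(f"{path}:{lineno}: first column must be sample_id")
            else:
                parts = line.split("\t")
                if len(parts) != len(header):
                    raise ValueError(f"{path}:{lineno}: expected {len(header)} fields")
                sample_ids.append(parts[0])
                rows.append(
                    [np.nan if c == _MISSING else float(c) for c in parts[1:]]
                )
    if header is None:
        raise ValueError(f"{path}: no header line found")
    snp_ids = header[1:]
    missing_meta = [s for s in snp_ids if s not in metas]
    if missing_meta:
        raise ValueError(f"{path}: missing ##SNP metadata for {missing_meta[:3]}")
    snps = [metas[s] for s in snp_ids]
    dosages = np.array(rows, dtype=float) if rows else np.empty((0, len(snp_ids)))
    return GenotypeMatrix(snps=snps, sample_ids=sample_ids, dosages=dosages)


# ---------------------------------------------------------------------------
# gene annotations (BED)
# ---------------------------------------------------------------------------

def read_gene_annotations(path: str | Path) -> list[GeneRecord]:
    """Read BED4+ gene bodies. BED coordinates are kept unchanged."""
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for idx, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: record {idx}: need >= 4 BED columns")
            chrom, start, end, name = parts[:4]
            start_i, end_i = int(start), int(end)
            if start_i >= end_i:
                raise ValueError(
                    f"{path}: record {idx}: start ({start_i}) >= end ({end_i})"
                )
            if name in seen:
                raise ValueError(f"{path}: record {idx}: duplicate gene_id {name!r}")
            seen.add(name)
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "unknown"
            genes.append(GeneRecord(name, chrom, start_i, end_i, strand))
    return genes


def write_gene_annotations(genes: list[GeneRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for g in genes:
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

_GWAS_COLS = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele", "maf", "p"]


def read_gwas_summary(path: str | Path) -> list[GwasSnp]:
    """Read GWAS summary TSV; rows with p outside (0, 1] are rejected and
    logged. Records come back sorted by (chrom, pos)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("snp_id", "chrom", "pos", "maf", "p"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out: list[GwasSnp] = []
    for row in df.itertuples(index=False):
        p = float(row.p)
        if not (0.0 < p <= 1.0):
            log.warning("rejecting %s: p=%g outside (0, 1]", row.snp_id, p)
            continue
        out.append(
            GwasSnp(
                meta=SnpMeta(
                    snp_id=str(row.snp_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref_allele=str(getattr(row, "ref_allele", "N")),
                    alt_allele=str(getattr(row, "alt_allele", "N")),
                    maf=float(row.maf),
                ),
                p_value=p,
            )
        )
    out.sort(key=lambda s: (s.meta.chrom, s.meta.pos))
    return out


def write_gwas_summary(snps: list[GwasSnp], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_GWAS_COLS) + "\n")
        for s in snps:
            m = s.meta
            fh.write(
                f"{m.snp_id}\t{m.chrom}\t{m.pos}\t{m.ref_allele}\t{m.alt_allele}\t"
                f"{m.maf:.10g}\t{s.p_value:.14g}\n"
            )


# ---------------------------------------------------------------------------
# molecular profiles
# ---------------------------------------------------------------------------

def _read_matrix_tsv(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_MISSING])
    return list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float)


def _write_matrix_tsv(
    sample_ids: list[str], gene_ids: list[str], mat: np.ndarray, path: Path
) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(gene_ids) + "\n")
        for i, sid in enumerate(sample_ids):
            cells = [_MISSING if not math.isfinite(v) else f"{v:.10g}" for v in mat[i]]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_profiles(
    expression_path: str | Path,
    copy_number_path: str | Path,
    methylation_path: str | Path,
) -> MolecularProfiles:
    """Read the three aligned samples x genes TSVs into one container."""
    samples, genes, expr = _read_matrix_tsv(Path(expression_path))
    s2, g2, cn = _read_matrix_tsv(Path(copy_number_path))
    s3, g3, meth = _read_matrix_tsv(Path(methylation_path))
    if s2 != samples or s3 != samples or g2 != genes or g3 != genes:
        raise ValueError("profile matrices disagree on sample or gene ordering")
    return MolecularProfiles(samples, genes, expr, cn, meth)


def write_profiles(profiles: MolecularProfiles, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "copy_number": outdir / "copy_number.tsv",
        "methylation": outdir / "methylation.tsv",
    }
    for key, p in paths.items():
        _write_matrix_tsv(
            profiles.sample_ids, profiles.gene_ids, getattr(profiles, key), p
        )
    return paths


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------

def read_de_table(path: str | Path) -> list[DeRecord]:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "fold_change", "fdr"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return [
        DeRecord(str(r.gene_id), float(r.fold_change), float(r.fdr))
        for r in df.itertuples(index=False)
    ]


def write_de_table(records: list[DeRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene_id\tfold_change\tfdr\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.fold_change:.10g}\t{r.fdr:.10g}\n")
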