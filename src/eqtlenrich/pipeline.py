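"""End-to-end orchestration: simulate -> adjust -> eqtl scan -> enrichment.

A run is driven by one :class:`RunConfig` (YAML-serializable). Every stage
writes plain-text TSV/JSON artifacts into the run directory and the run ends
with a manifest recording parameters, the seed, package version and a SHA-256
hash of every output, so re-running with the same config and seed reproduces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as eio
from .adjust import adjust_expression, variance_decomposition
from .enrichment import enrichment_suite, report_table, select_targets
from .scan import best_per_locus, run_scan
from .simulate import SimConfig, TruthTable, write_bundle

log = logging.getLogger(__name__)

__all__ = ["ScanParams", "EnrichParams", "RunConfig", "run_pipeline"]


@dataclass
class ScanParams:
    window: int = 250_000
    r2_threshold: float = 0.7
    fdr_call_threshold: float = 0.1
    n_loci: int = 47
    loci: list[str] | None = None  # explicit index SNPs; None = derive


@dataclass
class EnrichParams:
    flanks: tuple[int, ...] = (10_000, 25_000, 50_000, 100_000)
    thresholds: tuple[float, ...] = (1e-3, 1e-4, 1e-5)
    n_perm: int = 10_000
    maf_min: float = 0.01
    de_fdr_max: float = 0.1
    de_fold_min: float = 2.0
    exclude: tuple[str, ...] = ()


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    sim: SimConfig | None = field(default_factory=SimConfig)
    inputs: dict[str, str] = field(default_factory=dict)
    scan: ScanParams = field(default_factory=ScanParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = raw.pop("sim", None)
        scan = raw.pop("scan", {})
        enrich = raw.pop("enrich", {})
        if "maf_range" in (sim or {}):
            sim["maf_range"] = tuple(sim["maf_range"])
        for key in ("flanks", "thresholds", "exclude"):
            if key in enrich:
                enrich[key] = tuple(enrich[key])
        cfg = cls(
            sim=SimConfig(**sim) if sim is not None else None,
            scan=ScanParams(**scan),
            enrich=EnrichParams(**enrich),
            **raw,
        )
        if cfg.sim is not None:
            cfg.sim.seed = cfg.seed
        return cfg

    def validate(self) -> None:
        """Fail fast: every referenced input must resolve before any compute."""
        if self.sim is None:
            required = (
                "genotypes",
                "genes",
                "expression",
                "copy_number",
                "methylation",
                "gwas",
                "de_table",
            )
            for key in required:
                if key not in self.inputs:
                    raise ValueError(f"config: inputs.{key} is required when not simulating")
                if not Path(self.inputs[key]).exists():
                    raise ValueError(f"config: inputs.{key} does not exist: {self.inputs[key]}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_loci(truth: TruthTable | None, snp_ids: list[str], n_loci: int) -> list[str]:
    """Planted eQTL SNPs first, then evenly spaced fill-in index SNPs."""
    loci: list[str] = []
    if truth is not None:
        loci.extend(sorted({snp for snp, _, _ in truth.eqtls}))
    loci = loci[:n_loci]
    if len(loci) < n_loci:
        step = max(len(snp_ids) // max(n_loci - len(loci), 1), 1)
        taken = set(loci)
        for snp_id in snp_ids[step // 2 :: step]:
            if snp_id not in taken:
                loci.append(snp_id)
                taken.add(snp_id)
            if len(loci) == n_loci:
                break
    return loci


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages, returning the run directory.

    Artifacts: ``inputs/`` (when simulating), ``residuals.tsv``,
    ``gene_fits.tsv``, ``decomposition.json``, ``eqtl.tsv``,
    ``eqtl_best.tsv``, ``enrichment.tsv``, ``enrichment.json`` and
    ``manifest.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # ---- stage: inputs ----------------------------------------------------
    truth: TruthTable | None = None
    if config.sim is not None:
        log.info("stage simulate: writing synthetic bundle")
        bundle = write_bundle(outdir / "inputs", config.sim)
        inputs = {k: str(v) for k, v in bundle.items()}
        truth = TruthTable.from_json(bundle["truth"])
    else:
        inputs = dict(config.inputs)
    genotypes = eio.read_genotypes(inputs["genotypes"])
    genes = eio.read_gene_annotations(inputs["genes"])
    profiles = eio.read_profiles(
        inputs["expression"], inputs["copy_number"], inputs["methylation"]
    )
    gwas = eio.read_gwas_summary(inputs["gwas"])
    de_records = eio.read_de_table(inputs["de_table"])

    # ---- stage: adjust ----------------------------------------------------
    log.info("stage adjust: %d genes, %d samples", len(profiles.gene_ids), profiles.n_samples)
    adjusted = adjust_expression(profiles)
    res_path = outdir / "residuals.tsv"
    eio._write_matrix_tsv(adjusted.sample_ids, adjusted.gene_ids, adjusted.residuals, res_path)
    outputs["residuals"] = res_path
    fits_path = outdir / "gene_fits.tsv"
    adjusted.fit_summaries.to_csv(fits_path, sep="\t", index=False, float_format="%.10g")
    outputs["gene_fits"] = fits_path

    pairs = [(snp, gene) for snp, gene, _ in truth.eqtls] if truth else []
    decomp = variance_decomposition(profiles, genotypes, pairs)
    decomp_path = outdir / "decomposition.json"
    decomp_path.write_text(
        json.dumps(dataclasses.asdict(decomp), indent=1, sort_keys=True), encoding="utf-8"
    )
    outputs["decomposition"] = decomp_path

    # ---- stage: eqtl scan -------------------------------------------------
    loci = config.scan.loci or _derive_loci(truth, genotypes.snp_ids, config.scan.n_loci)
    log.info("stage eqtl: scanning %d loci", len(loci))
    results = run_scan(
        adjusted,
        genotypes,
        genes,
        loci,
        r2_threshold=config.scan.r2_threshold,
        window=config.scan.window,
        fdr_call_threshold=config.scan.fdr_call_threshold,
    )
    outputs["eqtl"] = _write_eqtl_tsv(results, outdir / "eqtl.tsv")
    outputs["eqtl_best"] = _write_eqtl_tsv(best_per_locus(results), outdir / "eqtl_best.tsv")

    # ---- stage: enrichment ------------------------------------------------
    targets = select_targets(
        de_records,
        fdr_max=config.enrich.de_fdr_max,
        fold_min=config.enrich.de_fold_min,
        exclude=set(config.enrich.exclude),
    )
    log.info("stage enrich: %d target genes", len(targets))
    reports = enrichment_suite(
        gwas,
        genes,
        targets,
        flanks=config.enrich.flanks,
        thresholds=config.enrich.thresholds,
        n_perm=config.enrich.n_perm,
        seed=config.seed,
        maf_min=config.enrich.maf_min,
    )
    table = report_table(reports)
    enr_path = outdir / "enrichment.tsv"
    table.to_csv(enr_path, sep="\t", index=False, float_format="%.10g")
    outputs["enrichment"] = enr_path
    enr_json = outdir / "enrichment.json"
    enr_json.write_text(
        json.dumps(
            [
                {
                    "flank": r.flank,
                    "ks_statistic": r.ks_statistic,
                    "ks_p": r.ks_p,
                    "fisher": [dataclasses.asdict(f) for f in r.fisher],
                    "gsea": dataclasses.asdict(r.gsea) if r.gsea else None,
                }
                for r in reports
            ],
            indent=1,
            sort_keys=True,
        ),
        encoding="utf-8",
    )
    outputs["enrichment_json"] = enr_json

    # ---- manifest ---------------------------------------------------------
    if config.sim is not None:
        for key, p in sorted(inputs.items()):
            outputs[f"inputs/{key}"] = Path(p)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "scan": dataclasses.asdict(config.scan),
            "enrich": dataclasses.asdict(config.enrich),
            "sim": dataclasses.asdict(config.sim) if config.sim else None,
        },
        "loci": loci,
        "n_significant": int(sum(r.significant for r in results)),
        "hashes": {k: _sha256(p) for k, p in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return outdir


def _write_eqtl_tsv(results, path: Path) -> Path:
    cols = "locus\tsnp_id\tgene_id\tbeta\tstat\tp\tfdr\tn\tsignificant\n"
    with path.open("w", encoding="utf-8") as fh:
        fh.write(cols)
        for r in sorted(results, key=lambda r: (r.p_value, r.snp_id, r.gene_id)):
            fh.write(
                f"{r.locus}\t{r.snp_id}\t{r.gene_id}\t{r.beta:.10g}\t{r.t_stat:.10g}\t"
                f"{r.p_value:.10g}\t{r.q_value:.10g}\t{r.n_used}\t{int(r.significant)}\n"
            )
    return path
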