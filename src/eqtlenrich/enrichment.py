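"""GWAS-signal enrichment over window-based SNP-to-gene assignments.

Given genome-wide association summary statistics and a target-gene set
(here: genes differentially expressed after perturbing a candidate
regulator), three complementary statistics ask whether association signal
concentrates in and around the targets:

* a two-sample Kolmogorov-Smirnov test comparing the p-value distribution of
  SNPs assigned to target genes against SNPs assigned to any other gene;
* two-tailed Fisher's exact tests on the proportion of SNPs below fixed
  p-value thresholds (1e-3, 1e-4, 1e-5) in targets versus all other genes;
* a preranked, weighted GSEA on genes ranked by the -log10 p of their most
  significant assigned SNP, with a gene-label permutation null.

SNPs are assigned to a gene when they fall inside the gene body extended by
a flank (10/25/50/100 kb variants); a SNP may map to several genes. SNPs
assigned to both a target and a non-target gene count as target by default
(``overlap_policy="drop-shared"`` removes them from both samples instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .datamodel import DeRecord, GeneRecord, GeneSet, GwasSnp

log = logging.getLogger(__name__)

__all__ = [
    "SnpAssignment",
    "FisherResult",
    "GseaResult",
    "RankedGenes",
    "EnrichmentReport",
    "select_targets",
    "map_snps_to_genes",
    "ks_enrichment",
    "fisher_threshold_enrichment",
    "rank_genes",
    "gsea_preranked",
    "enrichment_suite",
    "report_table",
]

_P_FLOOR = float(np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# target selection
# ---------------------------------------------------------------------------

def select_targets(
    de: list[DeRecord],
    fdr_max: float = 0.1,
    fold_min: float = 2.0,
    exclude: set[str] = frozenset(),
    name: str = "targets",
) -> GeneSet:
    """Genes with fdr < fdr_max and |fold_change| > fold_min, minus exclusions.

    Both cutoffs are strict, and the fold-change rule is sign-symmetric
    (2.5-fold up and 2.5-fold down both qualify). An empty result is allowed
    (with a warning) so callers can distinguish "nothing passed" from error.
    """
    if not de:
        raise ValueError("differential-expression table is empty")
    ids = {
        r.gene_id
        for r in de
        if r.fdr < fdr_max and abs(r.fold_change) > fold_min and r.gene_id not in exclude
    }
    if not ids:
        log.warning("select_targets: no gene passed fdr<%g, |fc|>%g", fdr_max, fold_min)
    return GeneSet(name=name, gene_ids=ids)


# ---------------------------------------------------------------------------
# SNP-to-gene assignment
# ---------------------------------------------------------------------------

@dataclass
class SnpAssignment:
    """Bidirectional SNP <-> gene window assignment at one flank size."""

    flank: int
    snp_to_genes: dict[str, set[str]]
    gene_to_snps: dict[str, set[str]]
    snp_pvalues: dict[str, float]

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


def map_snps_to_genes(
    snps: list[GwasSnp],
    genes: list[GeneRecord],
    flank: int,
    maf_min: float = 0.01,
) -> SnpAssignment:
    """Assign each SNP to every gene whose flanked body contains it.

    SNPs with maf <= maf_min are dropped first. A SNP at internal position
    pos0 maps to a gene iff pos0 in [start - flank, end + flank), half-open,
    via an interval tree so results do not depend on input order.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - flank, g.end + flank, g.gene_id
        )
    snp_to_genes: dict[str, set[str]] = {}
    gene_to_snps: dict[str, set[str]] = {}
    snp_pvalues: dict[str, float] = {}
    for s in snps:
        if s.meta.maf <= maf_min:
            continue
        tree = trees.get(s.meta.chrom)
        if tree is None:
            continue
        hits = {iv.data for iv in tree.at(s.meta.pos0)}
        if not hits:
            continue
        snp_to_genes[s.meta.snp_id] = hits
        snp_pvalues[s.meta.snp_id] = s.p_value
        for gid in hits:
            gene_to_snps.setdefault(gid, set()).add(s.meta.snp_id)
    return SnpAssignment(
        flank=flank,
        snp_to_genes=snp_to_genes,
        gene_to_snps=gene_to_snps,
        snp_pvalues=snp_pvalues,
    )


def _split_samples(
    assignment: SnpAssignment, targets: GeneSet, overlap_policy: str
) -> tuple[np.ndarray, np.ndarray]:
    """P-values of target-assigned vs background-assigned SNPs."""
    if overlap_policy not in ("target-priority", "drop-shared"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    tset = targets.gene_ids
    a, b = [], []
    for snp_id, gids in assignment.snp_to_genes.items():
        in_t = bool(gids & tset)
        in_b = bool(gids - tset)
        p = assignment.snp_pvalues[snp_id]
        if in_t and in_b and overlap_policy == "drop-shared":
            continue
        if in_t:
            a.append(p)
        else:
            b.append(p)
    return np.asarray(a), np.asarray(b)


# ---------------------------------------------------------------------------
# K-S enrichment
# ---------------------------------------------------------------------------

def ks_enrichment(
    assignment: SnpAssignment,
    targets: GeneSet,
    overlap_policy: str = "target-priority",
) -> tuple[float, float]:
    """Two-sample K-S test of target-SNP p-values against background.

    Unassigned SNPs never enter either sample. Returns (D, asymptotic p).
    """
    a, b = _split_samples(assignment, targets, overlap_policy)
    if a.size == 0:
        raise ValueError("K-S enrichment: target SNP sample is empty")
    if b.size == 0:
        raise ValueError("K-S enrichment: background SNP sample is empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(max(res.pvalue, _P_FLOOR))


# ---------------------------------------------------------------------------
# Fisher threshold enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FisherResult:
    threshold: float
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    no_snps: bool


def fisher_threshold_enrichment(
    assignment: SnpAssignment,
    targets: GeneSet,
    thresholds: tuple[float, ...] = (1e-3, 1e-4, 1e-5),
    overlap_policy: str = "target-priority",
) -> list[FisherResult]:
    """Two-tailed Fisher's exact test per p-value threshold.

    The 2x2 table is [target, background] x [p < t, p >= t]; two-tailed p by
    hypergeometric probability-mass summation (the scipy convention). The
    odds ratio uses the Haldane 0.5 correction when any cell is zero. A
    threshold with no qualifying SNP in either group is reported with p = 1
    and ``no_snps=True``.
    """
    a, b = _split_samples(assignment, targets, overlap_policy)
    if a.size == 0:
        raise ValueError("Fisher enrichment: target SNP sample is empty")
    if b.size == 0:
        raise ValueError("Fisher enrichment: background SNP sample is empty")
    out = []
    for t in thresholds:
        k_t = int((a < t).sum())
        k_b = int((b < t).sum())
        table = ((k_t, a.size - k_t), (k_b, b.size - k_b))
        if k_t + k_b == 0:
            out.append(FisherResult(t, table, float("nan"), 1.0, True))
            continue
        _, p = stats.fisher_exact(table, alternative="two-sided")
        (x11, x12), (x21, x22) = table
        if min(x11, x12, x21, x22) == 0:
            oratio = ((x11 + 0.5) * (x22 + 0.5)) / ((x12 + 0.5) * (x21 + 0.5))
        else:
            oratio = (x11 * x22) / (x12 * x21)
        out.append(FisherResult(t, table, float(oratio), float(max(p, _P_FLOOR)), False))
    return out


# ---------------------------------------------------------------------------
# gene ranking and preranked GSEA
# ---------------------------------------------------------------------------

@dataclass
class RankedGenes:
    """Genes in descending score order; score = -log10(min assigned SNP p)."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != self.scores.size:
            raise ValueError("gene_ids and scores length mismatch")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")


def rank_genes(assignment: SnpAssignment) -> RankedGenes:
    """Rank covered genes by the -log10 p of their best assigned SNP.

    Genes without any assigned SNP are excluded, not scored zero. Ties are
    broken lexicographically by gene_id.
    """
    scored = []
    for gid, snp_ids in assignment.gene_to_snps.items():
        pmin = min(assignment.snp_pvalues[s] for s in snp_ids)
        scored.append((-np.log10(pmin), gid))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return RankedGenes(
        gene_ids=[gid for _, gid in scored],
        scores=np.array([sc for sc, _ in scored]),
    )


@dataclass(frozen=True)
class GseaResult:
    es: float
    p_value: float
    n_perm: int
    n_hits: int


def _running_sum_extremum(
    hit_idx: np.ndarray, weights: np.ndarray, n_genes: int
) -> float:
    """Signed extremum of the GSEA running sum from sorted hit positions.

    Between hits the running sum falls linearly by 1/(N - k) per miss, so its
    extrema occur immediately after a hit or immediately before one; only
    those 2k candidate values are evaluated.
    """
    k = hit_idx.size
    if k == n_genes:
        return 1.0
    delta = 1.0 / (n_genes - k)
    total = weights.sum()
    if total <= 0:
        weights = np.ones(k)
        total = float(k)
    cum = np.cumsum(weights) / total
    i = np.arange(k)
    after_hit = cum - (hit_idx - i) * delta
    before_hit = np.concatenate(([0.0], cum[:-1])) - (hit_idx - i) * delta
    hi = float(after_hit.max())
    lo = float(min(before_hit.min(), 0.0))
    return hi if hi >= -lo else lo


def gsea_preranked(
    ranked: RankedGenes,
    targets: GeneSet,
    n_perm: int = 10_000,
    weight_exponent: float = 1.0,
    seed: int = 0,
    alternative: str = "enrichment",
) -> GseaResult:
    """Preranked GSEA with a gene-label permutation null.

    Hits advance the running sum by |score|^weight_exponent normalized to the
    in-set total; misses retreat it by 1/(N - |S|); the enrichment score is
    the signed extremum. The null permutes gene labels: uniformly random sets
    of the same size. The permutation p carries the +1 correction, so it can
    never be 0.

    With ``alternative="enrichment"`` (default) the p is the right tail of
    the permutation ES distribution: the hypothesis is that the set sits
    near the top of the ranking, and an anti-enriched set simply gets a
    large p. ``alternative="mirrored"`` instead takes the tail on the side
    of the observed ES sign; note that choosing the tail from the data
    doubles the type-I error of the nominal level and is offered only for
    exploratory symmetric use.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("enrichment", "mirrored"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = len(ranked.gene_ids)
    index = {g: i for i, g in enumerate(ranked.gene_ids)}
    hit_idx = np.sort([index[g] for g in targets.gene_ids if g in index])
    if hit_idx.size == 0:
        raise ValueError("target set does not intersect the ranked genes")
    w_all = np.abs(ranked.scores) ** weight_exponent
    es = _running_sum_extremum(hit_idx, w_all[hit_idx], n)
    rng = np.random.default_rng(seed)
    k = hit_idx.size
    null_es = np.empty(n_perm)
    for i in range(n_perm):
        idx = np.sort(rng.choice(n, size=k, replace=False))
        null_es[i] = _running_sum_extremum(idx, w_all[idx], n)
    if alternative == "enrichment" or es >= 0:
        p = (1 + int((null_es >= es).sum())) / (n_perm + 1)
    else:
        p = (1 + int((null_es <= es).sum())) / (n_perm + 1)
    return GseaResult(es=float(es), p_value=float(p), n_perm=n_perm, n_hits=k)


# ---------------------------------------------------------------------------
# the full battery
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentReport:
    flank: int
    ks_statistic: float
    ks_p: float
    fisher: list[FisherResult] = field(default_factory=list)
    gsea: GseaResult | None = None


def enrichment_suite(
    snps: list[GwasSnp],
    genes: list[GeneRecord],
    targets: GeneSet,
    flanks: tuple[int, ...] = (10_000, 25_000, 50_000, 100_000),
    thresholds: tuple[float, ...] = (1e-3, 1e-4, 1e-5),
    n_perm: int = 10_000,
    seed: int = 0,
    maf_min: float = 0.01,
    gsea_flank: int = 50_000,
    weight_exponent: float = 1.0,
    overlap_policy: str = "target-priority",
) -> list[EnrichmentReport]:
    """K-S and Fisher at every flank; GSEA at the 50-kb flank only."""
    reports = []
    for flank in flanks:
        assignment = map_snps_to_genes(snps, genes, flank, maf_min=maf_min)
        d, ks_p = ks_enrichment(assignment, targets, overlap_policy)
        fisher = fisher_threshold_enrichment(assignment, targets, thresholds, overlap_policy)
        gsea = None
        if flank == gsea_flank:
            ranked = rank_genes(assignment)
            gsea = gsea_preranked(ranked, targets, n_perm, weight_exponent, seed)
        reports.append(
            EnrichmentReport(flank=flank, ks_statistic=d, ks_p=ks_p, fisher=fisher, gsea=gsea)
        )
    return reports


def report_table(reports: list[EnrichmentReport]) -> pd.DataFrame:
    """One row per flank: K-S, per-threshold Fisher, GSEA columns."""
    rows = []
    for r in reports:
        row: dict[str, object] = {
            "flank_kb": r.flank / 1000,
            "ks_D": r.ks_statistic,
            "ks_p": r.ks_p,
        }
        for f in r.fisher:
            tag = f"{f.threshold:.0e}"
            row[f"fisher_p_{tag}"] = "No SNPs" if f.no_snps else f.p_value
            row[f"fisher_or_{tag}"] = f.odds_ratio
        row["gsea_es"] = r.gsea.es if r.gsea else np.nan
        row["gsea_p"] = r.gsea.p_value if r.gsea else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
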