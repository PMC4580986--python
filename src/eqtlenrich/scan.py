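"""Cis-eQTL association scan on covariate-adjusted expression.

For each index SNP (risk locus), the scan expands to LD proxies (squared
Pearson correlation of dosages above a threshold, 0.7 by default), pairs
every proxy with every gene whose body overlaps a +/- 250 kb window around
the variant, Wald-tests each pair by simple linear regression of residual
expression on alt-allele dosage, and controls the false discovery rate with
Benjamini-Hochberg across all tested pairs pooled over loci. Per locus the
best pair by p-value is reported alongside the full table.

The proxy panel may differ from the eQTL cohort (e.g., a reference haplotype
panel for LD, tumor genotypes for the scan); ``run_scan`` accepts both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .adjust import AdjustedExpression
from .datamodel import GeneRecord, GenotypeMatrix, SnpMeta

log = logging.getLogger(__name__)

__all__ = [
    "ProxySet",
    "EqtlResult",
    "AssociationTest",
    "ConstantDosageError",
    "find_proxies",
    "cis_genes",
    "test_association",
    "bh_fdr",
    "run_scan",
    "best_per_locus",
]

MIN_PAIRS = 10
_P_FLOOR = float(np.finfo(float).tiny)


class ConstantDosageError(ValueError):
    """Dosage vector has no variation; the Wald test is undefined."""


@dataclass
class ProxySet:
    """Index SNP plus its LD proxies, sorted by descending r-squared."""

    index_snp: str
    members: list[tuple[str, float]]

    @property
    def snp_ids(self) -> list[str]:
        return [s for s, _ in self.members]


@dataclass(frozen=True)
class AssociationTest:
    beta: float
    t_stat: float
    p_value: float
    n_used: int


@dataclass
class EqtlResult:
    """One SNP-gene association row: effect, Wald statistic, p, BH q."""

    locus: str
    snp_id: str
    gene_id: str
    beta: float
    t_stat: float
    p_value: float
    q_value: float
    n_used: int
    significant: bool


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    mask = np.isfinite(x) & np.isfinite(y)
    xm, ym = x[mask], y[mask]
    if xm.size < 2 or np.ptp(xm) == 0 or np.ptp(ym) == 0:
        return np.nan
    r = np.corrcoef(xm, ym)[0, 1]
    return float(r * r)


def find_proxies(
    panel: GenotypeMatrix, index_snp: str, r2_threshold: float = 0.7
) -> ProxySet:
    """All panel SNPs with dosage r^2 above ``r2_threshold`` to the index.

    r^2 is the squared Pearson correlation over samples non-missing in both
    vectors. The index SNP is always a member with r^2 = 1; a monomorphic
    index is an error (its correlation is undefined).
    """
    x = panel.dosage_of(index_snp)
    xf = x[np.isfinite(x)]
    if xf.size == 0 or np.ptp(xf) == 0:
        raise ConstantDosageError(f"index SNP {index_snp!r} is monomorphic in panel")
    members: list[tuple[str, float]] = [(index_snp, 1.0)]
    snp_ids = panel.snp_ids
    if np.isfinite(panel.dosages).all() and np.isfinite(x).all():
        # complete panel: one matrix product gives every correlation
        xc = x - x.mean()
        Y = panel.dosages - panel.dosages.mean(axis=0)
        ss = (Y * Y).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2_all = (xc @ Y) ** 2 / ((xc @ xc) * ss)
        for j, snp_id in enumerate(snp_ids):
            if snp_id == index_snp:
                continue
            r2 = r2_all[j]
            if np.isfinite(r2) and r2 > r2_threshold:
                members.append((snp_id, float(r2)))
    else:
        for snp_id in snp_ids:
            if snp_id == index_snp:
                continue
            r2 = _pairwise_r2(x, panel.dosage_of(snp_id))
            if np.isfinite(r2) and r2 > r2_threshold:
                members.append((snp_id, r2))
    members.sort(key=lambda m: (-m[1], m[0]))
    return ProxySet(index_snp=index_snp, members=members)


def cis_genes(
    snp: SnpMeta, genes: list[GeneRecord], window: int = 250_000
) -> list[GeneRecord]:
    """Genes whose body overlaps [pos0 - window, pos0 + window + 1).

    The window is symmetric around the variant; the gene body (not its TSS)
    defines cis membership and strand is ignored.
    """
    lo = snp.pos0 - window
    hi = snp.pos0 + window + 1
    return [
        g for g in genes if g.chrom == snp.chrom and g.start < hi and g.end > lo
    ]


def test_association(dosage: np.ndarray, residual_expr: np.ndarray) -> AssociationTest:
    """Wald test of the slope in OLS of residual expression on dosage.

    Complete-case over the two vectors; two-sided p from Student's t with
    ``n_used - 2`` degrees of freedom. Raises :class:`ConstantDosageError`
    when the dosage does not vary, and ``ValueError`` with fewer than
    ``MIN_PAIRS`` complete pairs.
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(residual_expr, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} complete pairs, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ConstantDosageError("constant dosage: association untestable")
    beta = float(xc @ yc) / sxx
    ss_res = float(yc @ yc) - beta * beta * sxx
    df = n - 2
    sigma2 = max(ss_res, 0.0) / df
    if sigma2 == 0.0:
        t = math.inf if beta > 0 else (-math.inf if beta < 0 else 0.0)
    else:
        t = beta / math.sqrt(sigma2 / sxx)
    p = 2.0 * stats.t.sf(abs(t), df) if math.isfinite(t) else 0.0
    return AssociationTest(
        beta=beta, t_stat=t, p_value=float(max(p, _P_FLOOR)), n_used=n
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _impute_dosage(x: np.ndarray) -> tuple[np.ndarray, int]:
    miss = ~np.isfinite(x)
    if not miss.any():
        return x, 0
    out = x.copy()
    out[miss] = np.nanmean(x)
    return out, int(miss.sum())


def run_scan(
    adjusted: AdjustedExpression,
    genotypes: GenotypeMatrix,
    genes: list[GeneRecord],
    loci: list[str],
    proxy_panel: GenotypeMatrix | None = None,
    r2_threshold: float = 0.7,
    window: int = 250_000,
    fdr_call_threshold: float = 0.1,
    pool_fdr: bool = True,
) -> list[EqtlResult]:
    """Scan every locus: proxies x cis genes, Wald tests, BH correction.

    BH is applied across all tested pairs jointly (``pool_fdr=False``
    corrects within each locus instead); a pair tested under several loci
    enters the FDR family once. Missing dosages are mean-imputed per SNP
    here, with the imputation count logged. Untestable pairs (constant
    dosage) are excluded from the family. Raises if no pair is testable.
    """
    panel = proxy_panel if proxy_panel is not None else genotypes
    gene_index = {g: i for i, g in enumerate(adjusted.gene_ids)}
    cohort_snps = set(genotypes.snp_ids)

    tested: dict[tuple[str, str], tuple[str, AssociationTest]] = {}
    n_imputed = 0
    n_untestable = 0
    for locus in loci:
        proxies = find_proxies(panel, locus, r2_threshold)
        for snp_id in proxies.snp_ids:
            if snp_id not in cohort_snps:
                continue
            meta = genotypes.snp_meta(snp_id)
            x, n_miss = _impute_dosage(genotypes.dosage_of(snp_id))
            n_imputed += n_miss
            for gene in cis_genes(meta, genes, window):
                gi = gene_index.get(gene.gene_id)
                if gi is None or (snp_id, gene.gene_id) in tested:
                    continue
                try:
                    res = test_association(x, adjusted.residuals[:, gi])
                except ConstantDosageError:
                    n_untestable += 1
                    continue
                tested[(snp_id, gene.gene_id)] = (locus, res)
    if n_imputed:
        log.info("mean-imputed %d missing dosage cells", n_imputed)
    if n_untestable:
        log.info("excluded %d untestable (constant-dosage) pairs", n_untestable)
    if not tested:
        raise ValueError("no testable SNP-gene pair at any locus")

    keys = list(tested.keys())
    pvals = np.array([tested[k][1].p_value for k in keys])
    if pool_fdr:
        qvals = bh_fdr(pvals)
    else:
        qvals = np.empty_like(pvals)
        locus_of = np.array([tested[k][0] for k in keys])
        for locus in np.unique(locus_of):
            idx = np.flatnonzero(locus_of == locus)
            qvals[idx] = bh_fdr(pvals[idx])

    results = []
    for (snp_id, gene_id), q in zip(keys, qvals):
        locus, res = tested[(snp_id, gene_id)]
        results.append(
            EqtlResult(
                locus=locus,
                snp_id=snp_id,
                gene_id=gene_id,
                beta=res.beta,
                t_stat=res.t_stat,
                p_value=res.p_value,
                q_value=float(q),
                n_used=res.n_used,
                significant=bool(q <= fdr_call_threshold) and fdr_call_threshold > 0,
            )
        )
    return results


def best_per_locus(results: list[EqtlResult]) -> list[EqtlResult]:
    """The best pair per locus: smallest p, then largest |t|, then snp_id."""
    best: dict[str, EqtlResult] = {}
    for r in results:
        cur = best.get(r.locus)
        key = (r.p_value, -abs(r.t_stat), r.snp_id, r.gene_id)
        if cur is None or key < (cur.p_value, -abs(cur.t_stat), cur.snp_id, cur.gene_id):
            best[r.locus] = r
    return [best[locus] for locus in sorted(best)]
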