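# eqtlenrich

Cis-eQTL scanning in tumors with molecular-covariate adjustment, plus a
battery of GWAS-signal enrichment tests over target-gene sets.

## The problem

GWAS risk variants for cancers such as high-grade serous ovarian carcinoma
mostly fall in non-coding DNA, so the gene each locus acts on is unknown.
Two complementary analyses help nominate and corroborate candidate
susceptibility genes:

1. **Tumor cis-eQTL mapping.** In tumors, somatic copy number and CpG
   methylation dominate expression variance, so a germline signal is only
   visible after removing them. Per gene *g*, expression is first adjusted by
   ordinary least squares,

       e_g = α + β_cn · CN_g + β_me · M_g + ε_g ,

   and the residuals are the trait. For each risk locus, LD proxies of the
   index SNP (dosage r² > 0.7) are paired with every gene within ±250 kb,
   the slope of `residual ~ dosage` is Wald-tested (t = β̂/SE, df = n−2), and
   Benjamini–Hochberg FDR is controlled across all tested pairs; calls are
   made at q ≤ 0.1. An incremental-R² decomposition (copy number →
   methylation → cis genotype) attributes expression variance to each layer.

2. **GWAS-signal enrichment in target-gene sets.** Given genome-wide summary
   statistics and a set of target genes (e.g., genes differentially expressed
   after perturbing a candidate regulator, selected at FDR < 0.1 and |fold
   change| > 2), SNPs with MAF > 0.01 are assigned to genes within the gene
   body ± a flank (10/25/50/100 kb) and three statistics test whether
   association signal concentrates in targets: a two-sample
   Kolmogorov–Smirnov test on SNP p-values, two-tailed Fisher's exact tests
   on the proportion of SNPs below p < 10⁻³/10⁻⁴/10⁻⁵, and preranked GSEA
   (genes ranked by −log₁₀ of the best assigned SNP p, permutation null,
   10,000 permutations).

A synthetic-data module generates genotypes with block LD, tumor molecular
profiles with configurable per-layer variance fractions (defaults: copy
number 14%, methylation 4.1%, cis genotype 0.25% at n = 339 samples), GWAS
p-values with signal planted near target genes, and differential-expression
tables with known truth — so the whole pipeline is testable end to end
without any external download.

## Worked example

Generate a synthetic cohort and run the variance decomposition:

```python
from eqtlenrich.simulate import SimConfig, simulate_genotypes, simulate_genes, simulate_profiles
from eqtlenrich.adjust import adjust_expression, variance_decomposition

cfg = SimConfig(seed=7)                      # 339 samples, 500 genes, 5,000 SNPs
genotypes = simulate_genotypes(cfg)
genes = simulate_genes(cfg)
profiles, truth = simulate_profiles(genotypes, genes, cfg)
adjusted = adjust_expression(profiles)       # residuals used by the eQTL scan
decomp = variance_decomposition(profiles, genotypes,
                                [(s, g) for s, g, _ in truth.eqtls])
print(f"copy number : {decomp.frac_cn:.4f}")
print(f"methylation : {decomp.frac_meth:.4f}")
print(f"cis genotype: {decomp.frac_eqtl:.5f}")
```

prints

```
copy number : 0.1418
methylation : 0.0406
cis genotype: 0.00264
```

— the recovered fractions of expression variance per molecular layer,
matching the generator's planted 0.14 / 0.041 / 0.0025.

The same works from the shell. Write a full input bundle and run the
enrichment battery on it (the bundle plants GWAS signal near the true
differential-expression targets):

```bash
eqtlenrich simulate --out demo --seed 7
eqtlenrich enrich --gwas demo/gwas.tsv --genes demo/genes.bed \
    --de-table demo/de_table.tsv --nperm 10000 --seed 7 --out demo/enr
```

which prints one row per flank size:

```
 flank_kb     ks_D          ks_p  fisher_p_1e-03  fisher_or_1e-03  ...  gsea_es  gsea_p
     10.0 0.843064 1.546012e-305   4.625158e-123       299.281087  ...      NaN     NaN
     25.0 0.838371 2.225074e-308   2.621121e-221       404.605072  ...      NaN     NaN
     50.0 0.826788 2.225074e-308   2.225074e-308       427.259016  ... 0.778374  0.0001
    100.0 0.518493 2.225074e-308   6.381937e-189       200.845815  ...      NaN     NaN
```

`ks_D`/`ks_p` compare the p-value distribution of target-assigned SNPs
against all other gene-assigned SNPs; `fisher_p_*`/`fisher_or_*` give the
two-tailed Fisher p and odds ratio for the excess of sub-threshold SNPs in
targets; GSEA (computed at the 50-kb flank) reports the weighted enrichment
score and its permutation p (never smaller than 1/(n_perm+1)). Here the
planted signal is strong, so every statistic rejects decisively.

Other subcommands: `eqtlenrich adjust` (covariate adjustment + decomposition),
`eqtlenrich eqtl` (the cis-eQTL scan; `--window 250000 --r2 0.7 --fdr 0.1`),
and `eqtlenrich run --config run.yaml` for the whole pipeline with a manifest
of output hashes (re-runs with the same seed are byte-identical).

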