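# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical/design decisions that were genuinely open.

## Covariate adjustment and variance decomposition

Tumor expression is modeled per gene as a linear combination of somatic copy
number, CpG methylation and (optionally) a cis germline dosage. Adjustment
fits `expression ~ intercept + CN + methylation` by OLS per gene,
complete-case, and returns residuals; a constant covariate is dropped with a
warning and genes with fewer than 10 complete samples are dropped and logged.
Residuals are exactly orthogonal to the gene's covariates and the operation
is idempotent (both are asserted in the test suite against QR / normal
equations oracles).

Variance is attributed to layers by **sequential incremental R²** in the
fixed order copy number → methylation → cis genotype. The order reflects the
reading of the genotype layer as explaining variance *beyond* the somatic
layers; it is a keyword argument (`order=`) for sensitivity checks. When a
gene has several candidate (SNP, gene) pairs, the pair with the largest
incremental R² at the genotype step is used. Module-level fractions are the
variance-weighted mean of per-gene increments (weights: per-gene expression
variance; `weights="uniform"` for the plain mean); genes lacking a layer
contribute 0 to it.

**Small-effect bias correction.** The raw incremental R² of one added
regressor is inflated by roughly 1/(n − p) even when the regressor is pure
noise. At n = 339 that is ≈ 0.3 percentage points — larger than the 0.25%
cis-genotype layer itself. The decomposition therefore reports increments of
Ezekiel-adjusted R², `1 − (1 − R²)(n − 1)/(n − k − 1)`, by default;
`adjusted=False` restores raw increments (whose per-step non-negativity and
cumulative monotonicity are property-tested). Per-gene adjusted increments
can be slightly negative; only the aggregated fractions are clipped to [0, 1].

## The cis-eQTL scan

* **Proxies:** squared Pearson correlation of dosage vectors over samples
  non-missing in both; members with r² > 0.7 (configurable), sorted
  descending; the index SNP is always a member with r² = 1. A monomorphic
  index is an error. The proxy panel may be a different cohort from the
  scanned genotypes (e.g., a reference haplotype panel).
* **Cis membership:** a gene is cis to a variant when its body (0-based,
  half-open) overlaps the variant position ± 250 kb. Gene-body overlap (not
  TSS distance) is used and strand is ignored; the flanks are symmetric.
* **Association:** OLS of residual expression on [intercept, dosage];
  Wald t = β̂/SE with n − 2 degrees of freedom, two-sided p. At least 10
  complete pairs are required; constant dosages are flagged untestable and
  excluded from the FDR family. Missing dosages are mean-imputed per SNP at
  analysis time (count logged); raw data are never modified at read time.
* **Multiplicity:** Benjamini–Hochberg across all tested pairs pooled over
  loci (one FDR family, matching a single reported FDR column across loci);
  `pool_fdr=False` corrects per locus instead. A pair reachable from two loci
  enters the family once. Calls at q ≤ 0.1.
* **Reporting:** all pairs, plus a best-pair-per-locus table (ties: smallest
  p, then largest |t|, then lexicographic snp_id) mirroring the
  one-row-per-association layout of published eQTL tables.

Internally all coordinates are 0-based half-open (BED semantics); VCF's
1-based positions are converted at the I/O boundary. This makes window
arithmetic overlap-safe and BED reading an identity.

## GWAS-signal enrichment

SNPs with MAF > 0.01 are assigned to every gene whose body ± flank contains
them (interval tree; results independent of input order; a SNP may map to
several genes). SNPs assigned to both a target and a non-target gene count
as **target**, and the background excludes them (`overlap_policy=
"drop-shared"` removes them from both sides) — the single largest ambiguity
in the procedure, hence exposed as a flag.

* **K–S:** two-sample test of target-SNP p-values vs background-SNP
  p-values, asymptotic null. Run on raw p-values; the statistic is invariant
  to monotone transforms, so −log p would give the same D.
* **Fisher:** per threshold t ∈ {10⁻³, 10⁻⁴, 10⁻⁵}, a 2×2 table
  [target/background] × [p < t / p ≥ t]; two-tailed p by hypergeometric
  probability-mass summation (the mainstream-software convention); odds
  ratio with Haldane 0.5 correction when a cell is zero. A threshold with no
  qualifying SNP anywhere reports p = 1 with a "No SNPs" flag.
* **Preranked GSEA:** genes covered by ≥ 1 SNP are ranked by −log₁₀ of
  their best assigned p (ties lexicographic; uncovered genes are excluded,
  not scored 0). The running sum increments at hits by |score|¹ normalized to
  the in-set total and decrements at misses by 1/(N − |S|); ES is the signed
  extremum. The null permutes gene labels (uniform random sets of the same
  size) — the only permutation available for summary statistics. The p-value
  is the right tail of the permutation distribution with the +1 correction
  (never 0, minimum 1/(n_perm + 1)): the hypothesis is *enrichment* near the
  top of the ranking. A sign-mirrored alternative is available
  (`alternative="mirrored"`), but selecting the tail from the observed ES
  sign doubles the nominal type-I error (measured ≈ 0.125 at α = 0.05 under
  the null), so it is not the default. The weighted (exponent 1) form is the
  default; exponent 0 gives the classic form, invariant to monotone score
  transforms.
* No correction across flanks/thresholds: each cell of the report is a raw p.

GSEA runs at the 50-kb flank only; K–S and Fisher at every flank in
{10, 25, 50, 100} kb.

## Synthetic data: what it emulates, what it does not

* **Genotypes:** two haplotypes per sample from a per-block equicorrelated
  Gaussian copula thresholded at each SNP's MAF quantile (MAF ~ U(0.05, 0.5));
  dosage = sum, so hard calls {0, 1, 2}. Within-block latent correlation
  `ld_rho = 0.9` makes r² > 0.7 proxies exist, which is all the scan needs;
  there is no coalescent realism, no population structure, no relatedness,
  no imputation uncertainty.
* **Profiles:** per gene, copy number is an i.i.d. 3-state {−1, 0, +1} track
  and methylation a Beta(2, 5) track, independent of each other (their joint
  distribution in real tumors is unknown; a correlation knob is deliberately
  not defaulted on). Coefficients are scaled against the empirical SD of each
  gene's covariate so the per-gene variance fractions hit the targets
  exactly up to covariate cross-correlation; noise absorbs the remainder
  (total variance ≈ 1). Defaults: 339 samples; 14% copy number, 4.1%
  methylation, 0.25% cis genotype. Planted cis SNPs sit within 250 kb of the
  gene.
* **GWAS:** p ~ U(0, 1) outside target windows; inside a target gene
  ± 50 kb, p = 2Φ(−|Z|), Z ~ N(noncentrality, 1) (uniform again at
  noncentrality 0). No LD between the GWAS panel and the signal — enrichment
  here has no LD-clumping confound, so passing tests say nothing about
  LD-driven false enrichment in real summary statistics.
* **DE tables:** exactly `n_true` genes pass FDR < 0.1 and |fold change| > 2,
  with values kept clear of the boundaries; every other gene fails at least
  one criterion.
* **Genome layout:** one chromosome; SNPs every 10 kb, 20-kb gene bodies
  tiled so gene spacing is ~100 kb (human-like order of magnitude). Every
  generator is a pure function of (config, seed); per-stage seeds derive from
  the global seed through fixed tags.

Because covariate tracks are i.i.d. across samples and layers are
independent, passing recovery tests demonstrates correctness of the
estimators under the model's own assumptions — not robustness to somatic
heterogeneity, probe-level methylation structure, or hidden expression
factors (PEER-like correction is out of scope).

## Validation experiments and problem sizes

`eqtlenrich.experiments` fixes the standard scenarios (the test suite and
`scripts/acceptance.py` both run them):

* **Scan FDR calibration:** 20 replicates of a null cohort (339 × 500 genes,
  300 SNPs, every SNP an index locus → ≈ 15,000 pairs per replicate). The
  mean false-call proportion at q ≤ 0.1 is compared with 0.1 + 3 binomial
  SEs. Under the global null the proportion is 1 whenever anything is called,
  so this measures the probability of any BH rejection (≈ 0.15 observed).
* **eQTL recovery:** 47 loci, 5 of them carrying a cis effect at 10% of
  expression variance, 10 replicates. The effect size comes from a power
  calculation: the Wald statistic at fraction f is ≈ √(f/(1−f)·337) ± 1 and
  the pooled-BH calling threshold sits near t = 3.2, so f = 0.10 keeps the
  per-gene miss probability below 0.1% while f at the 1% floor (t ≈ 1.8)
  is unrecoverable under any multiplicity correction. Note that with five
  true calls the q ≤ 0.1 rule itself implies ≈ 0.5 expected false genes per
  replicate (E[null rejections] ≈ q·R·m₀/m), so occasional spurious genes
  are the *correct* behavior of an FDR-calibrated scan, not a defect.
* **Decomposition recovery:** 10 replicates × 2,000 genes at the generator
  defaults; recovered fractions agree with 14% / 4.1% / 0.25% to well within
  15% / 15% / 50% relative error.
* **Enrichment calibration/power:** a fixed layout of 500 genes (100-kb
  spacing) and 50,000 SNPs (1-kb spacing). Null: 200 replicates with fresh
  uniform p-values and a fresh random 100-gene target set (with correlated
  neighbor-gene scores, conditioning on a single target draw would bias the
  measured rate); each statistic must reject at α = 0.05 in 5% ± 3% of
  replicates (GSEA at 1,000 permutations). Power: noncentrality 3,
  10 replicates; K–S and Fisher (10⁻³) at α = 0.01 at every flank.

Sizes were set so each experiment finishes in minutes on one CPU while
keeping Monte-Carlo error small relative to the tolerance being checked.

## Known limitations

* The scan tests intercept + dosage only on pre-adjusted residuals; no
  ancestry PCs or other covariates enter the association model itself.
* No trans-eQTLs, conditional analyses, or permutation-based gene-level
  eQTL p-values.
* Enrichment is not LD-aware (no clumping, no LD-score regression); the
  Fisher tests treat SNPs as independent observations, which real LD
  violates.
* The container model is normalization-agnostic: expression, copy-number and
  methylation matrices must arrive pre-summarized to one value per gene per
  sample.
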