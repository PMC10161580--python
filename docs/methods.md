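# Methods

`countqtl` maps expression quantitative trait loci (eQTLs) in RNA-seq
count data two ways and compares the outcomes:

1. **Linear framework** (the GTEx-style pipeline): counts are
   TMM-normalized to counts per million, each gene is inverse-normal
   transformed across samples, and every gene × variant pair is tested
   with ordinary least squares — an additive model (allele count 0/1/2,
   t-test on the slope) and an ANOVA model (genotype as a 3-level
   factor, 2-df F-test).
2. **Differential-expression (DGE) framework**: raw counts are modeled
   per pair with a negative binomial GLM (log link, log effective
   library-size offsets, collection-site covariate) and nested models
   are compared with a quasi-likelihood F-test.  A two-tier procedure
   (genotype-as-factor, then pseudo-coded dominance contrasts) together
   with a numeric-genotype additive model classifies significant eQTLs
   into dominance vs additive allelic modes.

Both frameworks use the genome-wide nominal threshold p < 5 × 10⁻⁸
(−log₁₀ = 7.3) and test all pairs exhaustively (trans included); a cis
window (default 1 Mb, inclusive boundaries) is available for labeling
only.

## Genotype QC

Input is a multi-sample VCF.  Records are restricted to biallelic SNPs;
half-calls and `./.` are missing.  The cascade retains sites with

* site depth ≥ 20 (INFO `DP`, else the sum of per-sample `DP`),
* genotypes called in ≥ 20 samples,
* ≥ 5 samples in each genotype class (AA, AB, BB),
* minor-allele frequency > 0.15 (computed from called genotypes only),
* no Hardy–Weinberg violation at FDR 0.05: two-sided Levene–Haldane
  exact test (probability-ordering definition of "as or more extreme",
  no mid-p), Benjamini–Hochberg adjusted across all tested variants.

The exact-test p-value is computed from the conditional distribution of
the heterozygote count given the sample and minor-allele counts, with
log-gamma arithmetic; it agrees with full rational-arithmetic
enumeration to 10⁻¹² for every configuration up to 50 individuals.

## Expression QC and representations

Samples with fewer than 10⁶ reads mapped to the annotation are dropped;
protein-coding genes with CPM > 2 (raw library sizes, strict) in ≥ 5
samples are retained.  TPM uses exonic (union-exon) lengths and
rescales to 10⁶ per sample.  TMM factors follow the published
trimmed-mean-of-M-values defaults: reference sample by 75th-percentile
CPM closest to the mean (ties to lowest index), genes with zeros or
mean log₂ abundance ≤ −10¹⁰ excluded, double trim of 30% (M) and 5%
(A) per side, inverse asymptotic-variance weights, factors rescaled to
geometric mean one.  The implementation agrees with the reference
R implementation to ~10⁻¹⁰ on random matrices.

The inverse normal transform maps each gene row to
Φ⁻¹((rank − k)/(n − 2k + 1)) with Blom offset k = 3/8 and average ranks
for ties; constant rows become zeros with a warning.

For the DGE framework only, genes with an extreme single-sample spike
are removed first: any sample with |log₂(TMM-CPM + 1) − median| >
5 × MAD (scaled) flags the gene; zero-MAD rows are never flagged.  This
rule is a heuristic interpretation — no canonical definition exists for
this filtering step — and its false-positive rate under pure NB noise
grows with dispersion (≈1.4% at φ = 0.05, ≈3% at φ = 0.2 at the 5-MAD
cutoff); rule and cutoff are recorded in output provenance and
configurable.

## Negative binomial fitting

The NB model uses Var(y) = μ + φμ² (φ = 0 is Poisson).  Fitting is
IRLS with log link and offsets: working weights μ/(1 + φμ), at most 50
iterations, relative deviance-change tolerance 10⁻⁸, step-halving on
deviance increases.  Thousands of small gene × variant fits are solved
with stacked (batched) linear algebra.  Aliased design columns are
dropped with a warning in the single-fit path; scan designs are checked
for rank per variant and skipped if aliased.

Dispersion is estimated once per gene under the covariates-only design
(intercept + site) and reused across that gene's variant models: the
Cox–Reid adjusted profile likelihood (log-likelihood minus half the log
determinant of the Fisher information) is evaluated on a 25-point
log-spaced grid over φ ∈ [10⁻⁶, 10], combined with the all-gene mean
curve as a residual-df-weighted average (individual weight = residual
df, common weight = prior df, default 10), and maximized with parabolic
refinement on the log scale.  This approximates, but does not
replicate, the empirical-Bayes squeezing of the reference DGE
implementation.

## Quasi-likelihood F-test

For nested designs, F = ((dev_reduced − dev_full)/df₁)/s² referred to
F(df₁, df₂) with df₂ = the full model's raw residual df.  The
quasi-dispersion s² defaults to the generalized Pearson estimate
X²/df₂ = Σ(y − μ̂)²/(μ̂ + φμ̂²)/df₂.  The deviance-based
s² = dev_full/df₂ is available (`ql_method="deviance"`) but is
measurably conservative at n = 41: under matched null simulations its
p-value ECDF deviates from uniformity by up to ≈0.018 even at the true
dispersion, while the Pearson form stays within ≈0.007 and holds the
α = 0.05 type-I error within Monte-Carlo error.  Neither form applies
the reference implementation's moderated ("squeezed") residual df.

## Two-tier scan and mode classification

Tier 1 tests genotype as a 3-level factor (2 df) against
intercept + site.  For tier-1-significant pairs, tier 2 fits the two
pseudo-coded contrasts — AA vs {AB, BB} (0/1/1) and {AA, AB} vs BB
(0/0/1) — each a 1-df QL F-test with the same covariates and offsets.
Independently, the additive scan tests genotype as a numeric 0/1/2
regressor; its effect is the per-allele natural-log fold change (also
reported in log₂).

Every pair significant in tier 1 is reported once from the ANOVA tier;
pairs significant only in the additive scan are additive eQTLs
(overlap-reporting rule: no pair appears twice).  The allelic mode of a
tier-1 pair is decided by goodness of fit, not by contrast significance
alone: among the three 1-df reductions of the factor model (two
contrasts and the numeric additive model — all of equal complexity),
the one with the smallest NB deviance wins.  A winning AA vs {AB, BB}
contrast means the alternate allele is dominant; a winning
{AA, AB} vs BB contrast means the reference allele is dominant; a
winning numeric model means additive.  The gate: at least one of the
three submodels must itself reach the significance threshold, otherwise
the pair is flagged `unresolved` rather than silently assigned.

The design rationale: under the QL F-test, significance of a single
contrast does not identify dominance — a strong additive effect often
leaves exactly one contrast significant while the contrast's
group-mean misfit inflates its quasi-dispersion.  In mixed simulations
(10 complete-dominance + 10 additive effects among 500 null pairs,
n = 41, φ = 0.2) the significance-only rule recovered ~69% of detected
true modes, while the best-fitting-submodel rule recovers 96–98% with
zero false mode calls.

Missing genotypes drop samples per pair; the covariates-only model is
refit on the same samples so deviances are comparable; a pair is
skipped (with a reason code) if a genotype class used by the model
empties or the design becomes aliased.

## Synthetic data

The generator emulates the study conditions both frameworks assume:
41 samples; Hardy–Weinberg genotypes at MAF 0.3; NB counts at baseline
mean 100 with dispersion φ = 0.2; per-sample library-size factors
uniform on the log scale in [0.5, 2]; two collection sites (log-scale
shift per level, 0 by default); 200 genes × 50 SNPs by default — small
enough that every scan runs in seconds on one CPU while keeping the
per-test sample size of the study design.  Planted effects act on the
log-mean scale: `additive` adds β per alternate allele,
`dominance_alt` adds β once any alternate allele is present,
`dominance_ref` adds β only to alternate homozygotes.  SNP columns are
redrawn until every genotype class has ≥ 5 samples, i.e. genotypes are
conditioned on passing the per-class QC rule — the state in which any
scan would actually run.  Gene g spans [10000g + 1, 10000g + 5000] on
one chromosome and SNP s sits at 10000s + 2500, so SNP i is cis to
gene i and distant from the rest.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, gene–gene expression correlation, cell-type-mixture confounding,
GC/length bias, and allele-specific expression.  Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under the stated model, not robustness to those features of
real data.

For calibration studies, two canned drivers exist: a full-pipeline
grid runner (type-I error and power per framework/model/α, with
truth-scored confusion counts) and a matched-pairs null study in which
each of 1,000 pairs is an independent count vector with its own
genotype column — used for distribution-level uniformity checks, since
the default scenario's 10,000 pairwise p-values share genes and SNPs
and are therefore dependent.

## Numerical and reporting choices

* P-value underflow is floored at the smallest positive normal double
  and flagged (`p_floored`).
* Significance is strict: p < threshold.
* Results are sorted by p with deterministic (gene, variant) tie order;
  reruns with the same configuration are byte-identical.
* Every output TSV starts with a provenance header: package version, a
  12-hex configuration hash, and every threshold/parameter used.
* BH adjustment is applied within each scan's full result list.
* Site covariates use full-rank dummy coding, levels ordered
  lexicographically, first level as reference.
* Coordinates are 1-based inclusive everywhere (VCF and GFF3 agree);
  the proximity annotation window is gene span ± 1,000 nt, distance 0
  inside the gene model.

## Known limitations

* Dispersion estimation approximates the reference empirical-Bayes
  machinery; on real data the two frameworks' gene sets can differ
  after outlier filtering, and `compare_frameworks` requires explicit
  alignment of the tested universes.
* The QL F-test's residual df is not moderated; p-values at very small
  counts (μ ≲ 5) have not been characterized here.
* The outlier-gene rule is an interpretation, not a reproduction of any
  published rule; real-data gene counts will not match studies that
  used a different (unstated) rule.
* No population-structure correction, kinship, or G×site interaction
  terms; variant calling upstream of the VCF is out of scope.
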