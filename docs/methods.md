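# Methods

## Count model and the likelihood-ratio ladder

Read counts for gene *i* in sample (fly) *k* are modeled as negative
binomial, `x_ik ~ NB(μ_ik, σ²_ik)` with `σ²_ik = μ_ik + φ_i μ_ik²`; the
gene-specific dispersion `φ_i ≥ 0` measures how far the variance exceeds
the Poisson mean–variance line, and `φ = 0` degenerates exactly to
Poisson sampling. Means follow a log-link GLM with the log size factor as
offset: `log μ_ik = log s_k + X_k β`.

Each design term is tested by a deviance comparison of nested fits:

| term | full model | reduced model |
|---|---|---|
| S, G, R | β₀+S+G+R | the same minus the tested main effect |
| G×R | β₀+S+G+R+G×R | β₀+S+G+R |
| G×S | …+G×R+G×S | …+G×R |
| R×S | …+G×S+R×S | …+G×S |
| G×R×S | full three-way model | all two-way interactions |

The statistic is `max(0, D_reduced − D_full)` where the deviance `D` is
`2[ℓ(saturated) − ℓ(fitted)]` at fixed φ; differences of deviances
between nested fits sharing one φ are likelihood-ratio statistics,
referred to χ² with df equal to the parameter-count difference. Negative
differences below 1e-8 (convergence noise) are clamped to zero.
Benjamini–Hochberg FDR is applied separately per term across genes,
because the natural summary of such a study is a per-term count of
significant genes.

**Fitting.** GLMs are fitted by iteratively reweighted least squares
(working weights `μ/(1+φμ)`, step-halving on the deviance, relative
deviance tolerance 1e-8, 100-iteration cap; non-convergence flags the fit
instead of raising). Design matrices are treatment-coded via patsy;
aliased columns are dropped with a warning so df always counts effective
parameters. On the balanced default design the full three-way model is
the cell-means model, which is fitted by a vectorized per-cell Newton
solve — the same MLE at a fraction of the cost. The statsmodels GLM
reproduces these fits to 1e-6 and serves as the independent cross-check
in the test suite.

**Dispersion.** One φ per gene, estimated under the full three-way model
and held fixed across the ladder (sharing φ is what makes the deviance
differences valid LRTs). The estimator maximizes the Cox–Reid adjusted
profile likelihood `ℓ(φ) − ½ log det(XᵀWX)`; without the adjustment,
estimating 96 cell means from 8 flies each biases φ down by roughly the
factor 1−1/n and visibly inflates every test's type-I error. The search
runs on log φ (bounded, tolerance 1e-4), is initialized from a
method-of-moments estimate pooled over design cells,
`max(0, (s²−m̄)/m̄²)`, and returns exactly 0 for under-dispersed genes.
No information is shared across genes: this is a deliberately transparent
per-gene MLE, not an empirical-Bayes shrinkage estimator, so dispersion
estimates for individual genes are noisier than shrinkage tools would
give, while remaining unbiased enough for calibrated ladder tests at the
default design size (verified by simulation).

## CV_E and heterogeneity of variance

Microenvironmental plasticity of a gene is the coefficient of
environmental variation of its normalized counts within one
genotype×sex×replicate cell, `CV_E = 100·sd/mean` (n−1 denominator).
Cells with n < 2 or non-positive mean are flagged undefined and excluded
rather than imputed — CV_E is numerically unstable at near-zero means.
CV_E is then analyzed per gene as a trait with the fixed-effects ANOVA
`Y = μ + S + G + G×S + ε`, using the replicate-level CV_E values
(3 per genotype×sex) as the error stratum; this choice makes the G×S term
estimable. The design is balanced, so type I/II/III sums of squares
coincide; the implementation computes the closed-form balanced SS
vectorized across genes and is oracle-checked against statsmodels
`anova_lm`. When a term's between-cell signal is exactly zero the test
reports F = 0, p = 1 (even at zero residual), and signal with zero
residual reports p = 0.

Variance heterogeneity across cells is screened with Levene's test
(absolute deviations from the cell mean) and the Brown–Forsythe variant
(deviations from the median), i.e. a one-way ANOVA F on
`Z = |y − center|` with df (k−1, N−k). The default grouping is the finest
design cell; with 8 flies per cell these tests have modest but usable
power, and grouping granularity is a parameter.

## Variance components and broad-sense heritability

Components come from the expected mean squares of the balanced
random-effects ANOVA with genotype and all genotype interactions random
(unrestricted mixed-model convention):

```
σ_GRS = (MS_GRS − MSE)/n          σ_GS = (MS_GS − MS_GRS)/(n·b)
σ_GR  = (MS_GR − MS_GRS)/(n·c)    σ_G  = (MS_G − MS_GR − MS_GS + MS_GRS)/(n·b·c)
```

(n flies/cell, b replicate levels, c sexes; factors with one level drop
out of the system, so the same code covers one-way toys). Negative
method-of-moments solutions are truncated at zero before forming

* expression scale: `H² = (σ_G+σ_GR+σ_GS+σ_GRS)/(σ_G+σ_GR+σ_GS+σ_GRS+σ_ε)`
* CV_E scale: `H² = (σ_G+σ_GS)/(σ_G+σ_GS+σ_ε)` with random G and G×S and
  replicate-within-(G×S) residual,

so `H² ∈ [0,1]` by construction and `0/0 := 0`. Expression-scale
components are computed on `log2(normalized + 1)` per fly: raw NB counts
conflate mean and variance, and log stabilization is the standard
quantitative-genetics scale — a documented divergence risk if compared
against raw-scale estimates. Method-of-moments was chosen over REML
because it is closed-form and exactly testable on balanced toys; truly
unbalanced inputs fall back to an unweighted-means solution with
harmonic-mean cell size, flagged via `balanced=False` and a warning.
Truncation makes H² estimates slightly biased upward near H² = 0 (about
+0.01 at H² = 0.1 at the default design size, measured by simulation);
this is inherent to non-negative component estimation.

## Coexpression modules and enrichment

The gene–gene correlation matrix (Pearson by default, Spearman optional;
constant genes dropped) is sharpened into a weighted adjacency
`A = |cor|^β` with the exponent selected on a 24-point grid over
[0.5, 12] to maximize the achieved weighted modularity

`Q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j)` ,

partitions coming from deterministic greedy (CNM) agglomerative
modularity maximization with lexicographic tie-breaking. Exact
modularity maximization is NP-hard; the greedy partition recovers planted
block structure reliably at the module sizes this analysis produces
(adjusted Rand ≥ 0.9 on 3-module plants). Q is recomputed from adjacency
and labels by an independent function and must agree with the clusterer's
report to 1e-10. Modules are reported ordered by mean within-module edge
weight, descending, so module 1 is always the tightest. An all-zero
adjacency returns the single-module degenerate result with Q = 0.

Enrichment of a module in user-supplied gene sets (GMT) is the
hypergeometric upper tail of the observed overlap against a stated
universe (sets intersected with the universe first), Bonferroni-corrected
over the number of sets. The sex-bias contingency test reports the sample
odds ratio ad/bc and a two-sided Fisher p computed by summing, over the
margin-conditioned hypergeometric support, all tables at most as probable
as the observed one (relative tolerance 1e-10 on the probability
comparison, matching the convention of standard implementations).

## Covariate screens

The infection screen fits `log μ = β₀ + I` per gene (I = line-level
infection status) against the intercept-only model, LRT with df 1, with φ
profiled under the two-group model. The model deliberately contains no
genotype term: infection is a property of the line, so genotype structure
in expression makes the screen anti-conservative — this documented
limitation is asserted by a test showing p-value inflation when line
effects exist. The heterozygosity/rRNA screens compute the per-line SD of
normalized expression (all flies of a genotype pooled; singleton lines
flagged NaN) and Spearman-correlate it with the per-line covariate: exact
permutation p-values when ≤ 8 tie-free lines (the null distribution is
enumerated once per n and cached), t-approximation otherwise.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical skeleton of a single-fly
factorial RNA-seq study: a balanced G×R×S×n layout (default 16×3×2×8 =
768 flies; the infected flag is constant within genotype, default 9/16
lines), NB counts with gene-specific φ drawn uniformly from a
configurable range (default 0.05–0.5), per-sample size factors drawn
log-uniformly (default 0.7–1.4) and rescaled to geometric mean 1 to match
the identifiability convention of median-of-ratios, and baseline
log-means uniform on log(20)–log(2000). Planted effects per design term
are i.i.d. normal on the log scale, centered to sum to zero over every
factor axis so the intercept stays the grand log-mean and recovery tests
are clean. CV_E differences are planted by multiplying φ per
(genotype, sex) with factors ≥ 1, which perturbs within-cell variance
while leaving every mean-model term untouched — mean-effect and
variance-effect tests stay separable by construction. An optional random
dropout rate mimics post-QC sample loss (real studies keep ~95% of
flies); dropout never empties a design cell.

Not emulated: read-level artifacts (mapping, duplication, GC), spike-ins,
batch/plate/pool structure, mean–dispersion trends across genes,
correlated genes under the null, and annotation. Passing tests therefore
demonstrate correctness of the estimators under the assumed NB factorial
model, not robustness to those real-data violations; the limma-voom-style
quality weighting and plate covariate variants used to probe such
violations are intentionally out of scope.

## Numerical choices

* Fitted means floored at 1e-10; linear predictors clipped at ±30 inside
  IRLS; `y log y := 0` at `y = 0` in deviances.
* Threshold derivation: Gaussian KDE (Silverman bandwidth) of
  `log(mean normalized count + 1e-8)`, 512-point grid spanning both
  samples ± 1; the threshold is the smallest grid point above the
  intergenic mode where the genic density exceeds the intergenic density.
  Identical or never-crossing densities raise a descriptive error. With
  no intergenic table the shipped default 3.486 is used.
* BH-FDR: step-up with stable mergesort ordering, outputs clamped to 1.
* LRT statistics below 1e-8 are treated as exact zeros (p = 1 at df 0).
* All generators flow from numpy `default_rng` seeds; the pipeline
  derives stage seeds from the single configured seed, and the run
  summary is byte-identical across reruns of one configuration (the
  config hash covers analysis-relevant fields only, not the output path).

## Problem sizes used in validation

The validation suite simulates 2000 null genes on the full 768-fly design
for ladder calibration (each term's rejection rate at α = 0.05 must stay
in the binomial 99% band), 500 genes for dispersion/effect recovery at
φ ∈ {0.1, 0.5, 1.0} with 1.5-fold planted genotype effects, 500 genes per
planted H² level {0.1, 0.3, 0.5}, 200 + 200 genes for CV_E-ANOVA
power/specificity under a 2× dispersion inflation, and 20 seeds of a
30-gene 3-module plant for clustering recovery. These sizes give tight
Monte-Carlo error while keeping the whole suite inside a few minutes on
one CPU.

## Known limitations

* Per-gene dispersion MLE (even Cox–Reid-adjusted) is noisy for very low
  counts; no mean–dispersion trend or shrinkage is applied.
* The CV_E ANOVA treats CV_E values as homoscedastic Gaussian responses;
  CV_E of NB counts is neither, so its F-tests are mildly anti-
  conservative (measured ~0.05–0.06 at nominal 0.05 on the default
  design) — acceptable for screening, not for sharp inference.
* Heritability standard errors are not provided (method-of-moments, no
  REML information matrix).
* The infection screen inherits the stated model's confounding with
  genotype, by design.
* Greedy modularity can merge weakly separated modules; the β grid
  mitigates but does not eliminate resolution limits.
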