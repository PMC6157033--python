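# Methods

This package tests sets of neighboring CpG sites ("blocks") against a
quantitative trait — canonically, the pre-to-post-treatment change in a
blood lipid — and compares the region-level view with per-CpG testing, for
both unrelated samples and family cohorts. This note documents the models,
the numerical choices, what the synthetic cohort generator does and does not
emulate, and known limitations.

## Data model

Let `Y` (n × p) be the methylation values of one block, `x` (n) the trait,
and `C` (n × r) covariates including an intercept. Methylation is analyzed
on the beta scale (proportions in [0, 1]) by default; an M-value/logit
option (`log(b/(1−b))`, b clipped to `[1e-6, 1 − 1e-6]`) is available
because beta values are heteroscedastic near the boundaries. Neither scale
is privileged by the methods; the configuration chooses.

Traits are lipid changes: triglycerides as `log(post) − log(pre)` (TG is
right-skewed, so changes are modeled multiplicatively) and HDL as
`post − pre` by default.

## Region construction

CpGs (1-based positions) are assigned to genes (0-based half-open BED
intervals) extended by a symmetric 20 kb flank: a CpG at position `pos`
belongs to gene `[s, e)` iff `s − 20000 < pos ≤ e + 20000` on the same
chromosome. Strand is ignored; a CpG may belong to several overlapping gene
windows; unannotated CpGs are dropped. Gene sets larger than 130 CpGs are
split into `ceil(p/130)` contiguous position-ordered chunks of near-equal
size (first `p mod k` chunks one CpG larger), suffixed `_1..k`. Count-based
equal splitting is a declared convention: it preserves local correlation,
is deterministic, and keeps every block well below the sample size.

## PCEV

The principal component of explained variation seeks `w` maximizing
`h²(w)`, the fraction of the variance of `Yw` explained by `x` after
adjusting both `Y` and `x` for `C`. With `V_G` the covariance of the
x-fitted values of residualized `Y` and `V_R` the residual covariance, `w`
is the leading eigenvector of `V_R⁻¹V_G` and `h² = d/(1+d)` for its leading
eigenvalue `d`. Testing `corr(Yw, x) = 0` after optimizing `w` would use
the data twice; testing `h²(w) = 0` instead uses it once. For a single
trait the hypothesis matrix has rank one, so the largest-root statistic has
an exact null distribution under Gaussian residuals:

    F = d (n − r − p) / p  ~  F(p, n − r − p).

This exact single-root form is the package's analytic null; it is validated
in-repo against the permutation test (residualized `x` permuted, h²
recomputed, `p = (1 + #{h²* ≥ h²}) / (B + 1)`), which is the recommended
fallback when normality is in doubt. The eigenproblem is solved through a
Cholesky factor of `V_R` (symmetric reformulation), with an escalating
jitter starting at `1e-10 · tr(V_R)/p` when `V_R` is numerically singular
(e.g. duplicated CpG columns). Blocks require `p ≤ n − r − 2`; larger
blocks must be split first. PCEV is defined here for unrelated samples
only.

## Variance-component (SKAT-type) score test

The reverse model treats `x` as the response and lets the block act on its
variance: with kernel `K = ZZ'` (`Z` the column-centered block, optionally
unit-scaled, columns weighted by `√w_j`, default weights 1 — methylation
predictors are common-scale, so no rare-variant weighting),

    Q = x' P₀ K P₀ x,
    P₀ = V⁻¹ − V⁻¹C (C'V⁻¹C)⁻¹ C'V⁻¹.

Unrelated samples: `V = σ_e² I` with `σ_e² = RSS/(n − r)` from OLS.
Families: `V = σ_g² · 2Φ + σ_e² I` with `Φ` the pedigree kinship matrix;
variance components are estimated by REML (standard small-sample choice),
profiling over `δ = σ_g²/σ_e²` on a 41-point log₁₀ grid over `[1e-5, 1e5]`
refined by bounded scalar minimization, after rotating into the eigenbasis
of `2Φ` (computed once and cached on the kinship object). A boundary flag
marks optima at the grid edge; `δ` indistinguishable from the lower edge is
reported as `σ_g² = 0`.

Under the null `Q ~ Σ λ_j χ²₁` with `λ_j` the eigenvalues of
`P₀^{1/2} K P₀^{1/2}`, computed as the eigenvalues of the p × p matrix
`Z'P₀Z` (identical nonzero spectrum, no n × n factorization), clipped at 0
and thresholded at `1e-10 · λ_max`.

### Mixture-of-chi-square tails

`davies_pvalue(q, λ)` inverts the characteristic function numerically via
Imhof's integral with adaptive quadrature (absolute tolerance ~1e-10).
Numerical choices:

* the spectrum is normalized by `λ_max` first (the law is scale
  equivariant);
* a single eigenvalue, or an exactly equal spectrum, is a scaled
  chi-square and is inverted in closed form — this makes the single-CpG
  case agree with the textbook score test to machine precision;
* if the quadrature fails, returns a value outside `(0, 1]`, or its error
  estimate is not small relative to the value, the Liu–Tang–Zhang
  moment-matching approximation (first three cumulants matched to a scaled
  noncentral chi-square) is used instead and recorded in `method_used`.
  This is the usual regime for extreme tails (oscillatory integrand), where
  moment matching is adequate for ranking and thresholding;
* p-values are clamped below at 1e-300 so they remain strictly positive.

## Per-CpG tests

Unrelated: OLS of `x` on `[C, y_cpg]`, two-sided t test on the CpG
coefficient. Families: the same fixed effects in a kinship LMM with Wald
test on the CpG coefficient, variance components re-estimated under the
alternative for each CpG (`fast_approx` reuses the covariate-only null
components, trading exactness for an order-of-magnitude speedup). The Wald
statistic is referred to a t distribution with residual degrees of freedom
rather than a normal: this is exact in the `2Φ = I` collapse (where the
LMM must reproduce OLS) and a standard small-sample refinement otherwise.
A constant CpG yields p = 1 with a warning rather than an error.

## Confounder principal components

Cell-composition and batch effects leave genome-wide signatures. 2000
probes are sampled uniformly without replacement (restricted to autosomes
when chromosome annotation is supplied), the probe submatrix is
column-centered, and the top 4 left singular vectors scaled by their
singular values are used as additional covariates. Signs are fixed by the
largest-magnitude loading. Defaults (2000 probes, 4 PCs) match the scale
at which broad latent structure is recoverable while leaving block-level
signal untouched; both are configurable, including `n_probes = all`.

## Kinship and unrelated-subset selection

Pedigree kinship uses the standard recursion in parents-first order
(founders `φ_ii = 0.5`, `φ_ij = 0`; otherwise
`φ_ii = 0.5 + 0.5 φ_fm`, `φ_ij = (φ_fj + φ_mj)/2`). The greedy unrelated
selection builds a graph on pairs with `φ ≥ 0.0221` (≈ 2^-5.5, below the
half-first-cousin level, so any pair sharing a pedigree ancestor is
connected) and repeatedly deletes the highest-degree vertex, breaking ties
by lexicographically smallest sample id for cross-platform determinism.
Survivors are returned in input order; the result is an independent set
and maximal. Greedy max-degree deletion attains the maximum independent
set on the package's family structures (verified exhaustively in tests)
but is not guaranteed optimal on arbitrary graphs.

## Synthetic cohorts

The generator exists to exercise the pipeline under a known truth. Per
block, latent (logit-scale) methylation decomposes into: a familial
component `a ~ N(0, meth_h2 · 2Φ)` shared across the block; an exchangeable
block factor with correlation `block_rho`; latent confounders `F`
(standard normal, shared between methylation and both traits) with per-CpG
loadings of geometrically decaying scale `latent_sd · 0.7^(k-1)` (a
dominant batch axis plus weaker cell-composition axes; decay keeps the
factors identifiable from PCs, which equal-strength factors — recoverable
only up to rotation — would not be); and independent noise absorbing the
rest of a unit marginal variance (loadings capped at 80% of the residual
budget so the noise variance stays positive). Beta values are
`expit(μ_c + latent)` with `μ_c ~ U(−2, 2)`. Phenotype changes add causal
CpG contributions (standardized logit scale), `γ'F`, a polygenic term
`N(0, pheno_h2 · 2Φ)`, and noise; TG changes act on the log scale, HDL
changes additively at 5 mg/dL per unit score. Causal CpGs are the first
`ceil(fraction · p)` of the block in position order; with
`effect_sign_pattern = "alternating"` every second causal CpG's effect is
flipped, producing distributed effects with heterogeneous direction.

Defaults (60 nuclear families of 4, 20 genes × 20 CpGs, `block_rho = 0.3`,
`meth_h2 = 0.2`, three latent factors at `latent_sd = 0.6`,
`pheno_h2 = 0.3`) describe a moderately confounded, moderately heritable
cohort. Everything is driven by `numpy.random.default_rng([seed, stream])`
with a documented draw order, so equal seeds give byte-identical output
files.

What the generator does **not** emulate: realistic 450K probe spacing and
beta distributions, SNP genotypes, cell-type mixtures with reference
profiles, shared household environment, or methylation heritability beyond
the pedigree kinship model. Consequently, calibration results here show
that the family tests are correct *when the fitted variance structure
matches the generative one*; they cannot show how the tests behave when
real methylation is more heritable than the pedigree kinship accounts for,
a regime in which family-based region tests are known to inflate.

## Multiplicity and diagnostics

FWER is controlled by Bonferroni at `α = 0.10` by default, with `m` the
number of tests actually performed per method in the run. Genomic
inflation `λ` is the median of `χ²₁`-quantile-transformed p-values divided
by 0.4549364; Q-Q tables pair sorted observed `−log10 p` with expected
`(i − 0.5)/m` quantiles. The pipeline writes per-method results TSVs,
top-5 tables (ties broken by unit id), thresholds, `λ`, Q-Q tables, and a
run manifest with the config hash and seed.

## Problem sizes used in the checks

The statistical test-suite checks run at: type-I calibration with 2000
null replicates per test (n = 200–300); confounding diagnosis on ten
replicate cohorts of 300 samples × 2000 CpGs; heritability recovery with
200 REML fits at n = 602; power comparison with 200 replicates of a
20-CpG block at n = 400, with a 0.10-SD same-sign effect on half the CpGs
and weak within-block correlation (rho = 0.1). That regime was chosen by
power analysis so the comparison is informative: stronger effects drive
every method to power 1, strongly correlated same-sign effects let
per-CpG min-p pool the signal through inflated marginal correlations
(matching PCEV), and sign-alternating effects hide the signal from the
centered kernel's dominant eigen-direction (defeating the VC test). With
weak correlation, marginal tests cannot aggregate a distributed signal and
both region tests show their advantage. The acceptance script re-runs the
same quantities at moderately reduced replicate counts.

## Known limitations

* PCEV assumes Gaussian homoscedastic residuals; beta-scale methylation
  violates this near the boundaries. Use the logit scale or the
  permutation p-value when this matters.
* The family VC test corrects only pedigree-kinship correlation (see the
  generator caveat above).
* Missing methylation values are a hard error; no imputation is provided.
* The LMM Wald test re-estimates variance components per CpG; for very
  large CpG counts use `fast_approx` or the unrelated subset.
* Bonferroni with the run's own `m` is conservative under correlated
  blocks; no FDR alternative is provided.
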