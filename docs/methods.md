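# Methods

## The testing problem

Given `n` unrelated subjects with an ordered categorical phenotype
`y_i ∈ {0, …, J−1}`, covariates `x_i ∈ R^K` and a set of `M` SNP dosages
`g_i ∈ {0,1,2}^M`, we test whether the SNP set is associated with the
phenotype while adjusting for the covariates.  The phenotype model is the
proportional odds (cumulative logit) model

    logit P(y_i ≤ j | x_i, g_i) = ζ_j − x_i'γ − g_i'β ,
    ζ_0 < ζ_1 < … < ζ_{J−2},

so a positive coefficient shifts mass toward higher categories.  Testing
`H0: β = 0` coefficient-by-coefficient loses power when `M` is large; the
variance-component formulation instead treats `β` as random with mean zero
and variance `D(θ)` and tests the single parameter `H0: θ = 0`.

## Score statistic

The quasi-likelihood score for `θ` at the null reduces (up to a term not
involving the phenotype) to the weighted quadratic form

    T = ½ (y − μ̂)' G̃ W G̃' (y − μ̂),

where

- `μ̂_i` is the fitted null mean of the integer-scored response,
  `μ̂_i = Σ_{j=0}^{J−2} P(y_i > j)` under the covariates-only fit;
- `G̃` is the dosage matrix residualized column-wise on `[1, X]` by least
  squares (centering is required even without covariates, otherwise `T` is
  not a proper score statistic);
- `W = diag(w_m)` with `w_m = BetaDensity(f_m; ½, ½)²` evaluated at the
  sample minor-allele frequency `f_m` folded to ≤ ½.  The Beta(½,½)
  density `1/(π√(f(1−f)))` gives rarer SNPs larger weights; multiplying
  all weights by a constant rescales `T` and the null spectrum identically
  and leaves the p-value unchanged (tested to 1e−10).

Under `H0`, `T` is asymptotically a mixture `Σ_m λ_m χ²_1` with `λ` the
eigenvalues of `½ V^{1/2} G̃ W G̃' V^{1/2}`, `V = diag(Var(y_i))` under the
null fit with

    Var(y_i) = μ̂_i − μ̂_i² + 2 Σ_{j=1}^{J−2} j · P(y_i > j).

Both exceedance sums run to `j = J−2`: the model has only `J−1` cutpoints,
and the `J=2` reduction must give `E(y) = P(y=1)` and the Bernoulli
variance, which pins the upper limits.  Both formulas are verified in the
tests against the definitional `Σ j P(y=j)` and `Σ j² P(y=j) − μ²` to
1e−12.

The spectrum is computed from the `M×M` symmetric matrix
`½ W^{1/2} G̃' V G̃ W^{1/2}`, which shares all nonzero eigenvalues with the
`n×n` form (asserted against a brute-force `n×n` eigendecomposition on
small fixtures).  Eigenvalues below `1e−10 · λ_max` are treated as
numerical rank deficiency and dropped.

## Pearson Type III p-value

With moments `E(T) = Σλ`, `Var(T) = 2Σλ²`, `E[(T−ET)³] = 8Σλ³` and
skewness `ξ = 8Σλ³ / (2Σλ²)^{3/2}`, the standardized statistic
`T* = (T − E T)/√Var T` is referred to the Pearson Type III (shifted
gamma) distribution with mean 0, variance 1 and skewness ξ:

    X = c + a · Gamma(shape b, scale 1),
    a = ξ/2 (scale),  b = 4/ξ² (shape),  c = −2/ξ (location),

and `p = P(X > T*) = Q(b, (T* − c)/a)` with `Q` the upper regularized
gamma function.  For a single eigenvalue this is exactly the scaled-χ²₁
tail (ξ = 2√2, tested to 1e−9); as ξ → 0 it tends to the standard normal.

### Accuracy

The three-moment match is very accurate in the rejection region: against
10⁶-draw Monte-Carlo simulations of the mixture, errors are below 0.005
for tail probabilities in [0.01, 0.5] for flat spectra, and below ~0.003
for p ≤ 0.1 for every spectrum shape we examined.  Its one known weakness
is the **middle of the distribution under strongly skewed spectra**: when
one eigenvalue dominates (ξ ≳ 2, e.g. few SNPs in strong AR(1) LD), the
approximation can under-state p by 0.02–0.03 near p ≈ 0.5.  This does not
affect decisions at conventional levels but is visible when comparing to
re-sampling p-values on small fixtures; see Limitations.

## Permutation oracle

`permutation_pvalue` re-fits the covariates-only null for every permuted
phenotype vector and re-evaluates `T`, returning the add-one estimate
`(1 + #{T_perm ≥ T_obs})/(H+1)`.  Permuting the raw phenotype is an exact
null reference **only under exchangeability**, i.e. when the phenotype is
independent of the covariates; when covariate effects are present the
permutation destroys the phenotype–covariate coupling and targets a
different (wider) null.  Covariate-preserving permutation schemes are out
of scope, so the oracle-agreement tests use exchangeable fixtures
(covariates present in the model, no covariate effect in the generator).
Permuted refits are warm-started at the observed optimum.

## Comparators

- **PCA-LRT** – PCA on the dosage correlation matrix; the smallest `L`
  leading components reaching 80% cumulative eigenvalue share enter the
  proportional odds model and are tested jointly by LRT against χ²_L.
- **MinP** – per-SNP marginal fits; the smallest Wald p-value is referred
  to its permutation distribution (phenotype-only shuffles, add-one
  estimate).  The per-SNP reference is the standard normal: proportional
  odds Wald statistics are asymptotically normal, and at the sample sizes
  used any Student-t correction is negligible.
- **Bonferroni (BC)** – `min(1, M · min_m p_m)`.
- **QT** – the classical joint test of all `M` SNP coefficients.  No
  canonical construction exists for it beyond its χ²_M reference; we use
  the likelihood-ratio statistic (score or Wald variants would be drop-in
  replacements).  It refuses to run when `n ≤ M + K + J` and its
  calibration is expected to degrade as `M` grows — that failure mode is
  the point of including it.

## Null-model fitting

The cumulative-logit MLE runs on the unconstrained parameterization
`(ζ_0, log successive gaps, γ)`, which enforces the cutpoint ordering by
construction, using BFGS with the analytic gradient.  Convergence demands
a mean per-subject gradient max-norm below 1e−5 (target 1e−8·n on the raw
gradient), with at most 200 iterations; failures raise with diagnostics
rather than returning a flagged object.  Starting values are the
intercept-only closed form (cutpoints at marginal cumulative logits).
Wald standard errors come from central finite differences of the analytic
gradient; the coefficient block of the inverse information is invariant to
the cutpoint reparameterization, so it is read off directly.  The fit is
cross-checked in the tests against statsmodels' `OrderedModel`
(coefficients, log-likelihood and standard errors) and, for `J=2`,
against plain logistic regression to 1e−8.

## Synthetic data generator

The generator reproduces the statistical structure of the study design:

- **Genotypes**: a latent `N(0, Σ)` row with `Σ_{jk} = ρ^{|j−k|}`
  (exact AR(1) recursion), thresholded per SNP at the standard-normal
  quantiles of `(1−f)²` and `1−f²`.  Marginals follow Hardy–Weinberg
  proportions; ρ controls LD decay.  Default MAFs are `M` equally spaced
  values in [0.1, 0.45].
- **Covariates**: i.i.d. bivariate normal, unit variances, covariance 0.5.
- **Phenotype**: latent trait `x'γ + g'β (+ φ·g₁g₂) + ε` with standard
  logistic errors (so the induced categorical model is exactly
  proportional-odds), cut at the **empirical quantiles** (linear
  interpolation between order statistics) of the realized latent trait at
  probabilities `D`.  This fixes the category proportions exactly per
  replicate, at the cost of a weak negative coupling between subjects
  that is invisible at the study sample sizes.  The interaction product
  `g₁·g₂` is deliberately uncentered.
- **Seeding**: replicate `r` of master seed `s` draws from the stream
  `SeedSequence(s, spawn_key=(r,))`; everything is bit-reproducible.

What the generator does **not** emulate: the empirical LD patterns of
real gene regions (AR(1) with ρ=0.5 is the documented stand-in),
genotyping error, missingness, population stratification, or relatedness.  Power numbers under synthetic
LD are therefore comparable only in their qualitative trends (monotone in
the causal count B, decreasing in the set size M, and the aggregate
method ordering), not cell-by-cell with results obtained on real LD.

## Study problem sizes

- Type I error: all 18 scenarios (J=3 n=2000 / J=5 n=3000 × M ∈
  {50,100,200} × ρ ∈ {0.2,0.5,0.8}), 500 replicates each at α=0.05 —
  the full simulation grid.
- Power: a half-scale grid n=1000, M ∈ {15,30}, B ∈ {1,3,6}, β=0.2,
  ρ=0.5, J=3, 500 replicates, methods POM-SKAT/PCA/BC, with QT checked
  for calibration separately at small M.  Larger grids run through
  the same `power_experiment` API.
- Oracle agreement: 20 fixtures with n=300, M=10, H=5000 permutations,
  alternating null and alternative (β=0.25 on two SNPs), exchangeable
  phenotype.

## Known limitations

- The Pearson III mid-distribution bias under strongly skewed spectra
  (above): on the small oracle fixtures, |analytic − permutation| can
  reach ~0.03 for p-values near 0.5 while agreeing to well under 0.01 in
  the tails.  Davies-style exact inversion would remove this but is out
  of scope; re-sampling is retained as the oracle.
- Raw-phenotype permutation is not a valid reference when covariates
  truly affect the phenotype (see Permutation oracle).
- Common-variant weights only; no rare-variant collapsing, alternative
  kernels, adaptive weight mixing, or X-chromosome dosage handling.
- The ordinal phenotype must be coded (or mapped via the level-order
  utility) to consecutive integers 0..J−1; the statistic uses the integer
  scores `y − μ̂`, which is the intended behaviour of the method, not an
  arbitrary choice of scores.
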