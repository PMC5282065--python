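# Methods

## Scientific setting

In bistable perception (here: a rotating structure-from-motion sphere whose
rotation direction flips perceptually), the time between reported reversals
— the percept duration — is a stable individual trait. Several studies have
correlated its per-subject summary (the log geometric-mean duration) with
scalar brain measures: grey-matter volume at superior-parietal coordinates
and occipital GABA+/Cr concentration. This package implements the
statistical machinery of a Bayesian replication of such correlation
findings, and a synthetic-study generator so that every stage can be
exercised end to end without any subject data.

## Exact likelihood for a correlation

All Bayesian machinery rests on the exact sampling density of the Pearson
correlation `r` from `n` bivariate-normal observations with population
correlation `ρ` (Hotelling's hypergeometric form):

    f(r | ρ, n) = (n−2) Γ(n−1) / (√(2π) Γ(n−½))
                  · (1−ρ²)^((n−1)/2) (1−r²)^((n−4)/2) (1−ρr)^(−(n−3/2))
                  · ₂F₁(½, ½; n−½; (1+ρr)/2)

implemented in log space with `scipy.special.hyp2f1` (whose argument is
confined to (0, 1), so the series is convergent and well conditioned).
The log-space form is stable for every sample size we have probed (to
n = 10⁴), so no arbitrary-precision fallback is used. At ρ = 0 the density
collapses to the closed beta form
`(1−r²)^((n−4)/2) / B(½, (n−2)/2)`, used as the H0 marginal likelihood.
`n < 4` is rejected: the `(n−4)/2` exponent degenerates below that.

A seeded Monte-Carlo check (2·10⁵ simulated studies at ρ = .5, n = 20)
confirms the parameterisation: KS distance to the empirical distribution
is ~0.003.

### Degrees-of-freedom convention in the Bayes-factor layer

Replication Bayes factors in this literature were produced with R code
that evaluates the likelihood of `r` at an effective sample size of
`n − 1` (the degrees of freedom of a correlation after centering). The
replication layer therefore defaults to `likelihood="df"`; this choice
reproduces the published Bayes-factor tables to ≲2% while the raw-`n`
convention deviates by up to 12% at large `r`. `likelihood="n"` is
available everywhere. The likelihood kernel itself (`r_density`) always
uses the true sample size — the convention is applied only where the
published analyses applied it.

## Replication tests

For one original study (r₀, N₀) and one replication (r₁, N₁):

* **Uniform-prior BF₁₀** — marginal likelihood of r₁ under a one-sided
  uniform prior on ρ (on (0,1) or (−1,0), matching the expected
  direction), divided by the null density at ρ = 0. When no direction is
  available (no original correlation, e.g. a peak found inside a mask of
  previously significant voxels) the prior is the two-sided uniform on
  (−1,1).
* **Informed-prior BF₁₀** — the prior is the posterior of ρ given the
  original study under a *two-sided* uniform base prior. The base prior is
  deliberately untruncated: published credible intervals of combined
  posteriors span zero for weak effects, which is impossible under a
  one-sided informed prior. By Bayes-rule associativity, the resulting
  combined posterior is identical to analysing both datasets jointly (a
  property asserted to 1e−6 in the tests).
* **Posterior summaries** — MAP by quadratic interpolation around the grid
  argmax; 95% credible interval as equal-tailed 2.5/97.5% quantiles by
  inverse-CDF interpolation (equal-tailed, not HPD, matching the reported
  cut-off definition).
* **Savage–Dickey ratio** — prior/posterior density ratio at ρ = 0 on a
  shared grid, with a one-sided limit (and a flag) when the prior density
  vanishes at the origin. Used as the scalar form of posterior-probability
  mapping; it agrees with marginal-likelihood integration to <1% on smooth
  two-sided priors.
* BF₁₀ is reported throughout, with 1/BF alongside in the report layer;
  verbal categories use the conventional thresholds (1–3 anecdotal, 3–10
  substantial, 10–30 strong, 30–100 very strong, >100 extreme).

All ρ integrals share one grid: 4001 equally spaced nodes on
[−0.9999, 0.9999] with the trapezoid rule. This reproduces published BFs
and posterior summaries to 2–3 significant figures in well under a second;
doubling the grid changes results in the fourth figure.

One caveat discovered while validating: for a single row of the published
table (original r = −.65, N = 52; replication r = −.220, n = 37) the printed
informed BF (.16) cannot be produced by *any* single likelihood in `r`
that also produces the row's printed uniform BF (.83) — the two values
imply different replication correlations. The package computes .112 for
that row, consistent with the exact likelihood family and with every other
printed value; an identity test pins the internal consistency of the two
BFs for this row.

## Power and critical values

Power uses the Fisher-z method with the small-sample bias term
(`z_ρ = atanh ρ + ρ/(2(n−1))`) and a critical r from the central
t quantile at df = n−2 — the convention of R's `pwr` package, which
reproduces the published one-tailed values (.998, .993, .743, .995, .851)
to three decimals; the uncorrected variant (off by up to .03 at n = 15) is
behind a flag for sensitivity checks, and a seeded simulation-based
estimate provides an exact cross-check. The chance bar for mass-univariate
correlation screening comes from
`r_c = t_c/√(t_c² + n − 2)`: at n = 37, 10% of null voxels exceed
|r| = .2746 by chance.

## All-subsets regression and WAIC

Every subset of the candidate covariates (2^k models including
intercept-only) is fitted as a Bayesian linear regression on z-scored
outcome and predictors with N(0, 10) priors on all coefficients — weakly
informative on that scale, and consistent with reported intercepts of
zero. The residual scale gets a half-Cauchy(0, 5) prior, represented
exactly as an inverse-gamma scale mixture so the sampler is a pure Gibbs
scheme with conjugate conditionals (coefficients: Gaussian; scale and its
auxiliary: inverse-gamma). A half-normal(0, 5) alternative (one
slice-sampling step) is provided; tests confirm it leaves WAIC rankings
unchanged. Convergence is monitored by split-chain potential scale
reduction; default runs (2 chains × 600 kept draws after 300 warmup —
at least the 1000 draws WAIC requires) give R-hat < 1.01 on the synthetic
problems shipped here.

WAIC is computed pointwise from the stored draws with log-sum-exp:
`lppd = Σᵢ log meanₛ p(yᵢ|θₛ)`, `p_waic = Σᵢ varₛ log p(yᵢ|θₛ)`,
`WAIC = −2(lppd − p_waic)`; lower is better, ties broken toward fewer
predictors. Separate comparisons per covariate family (exact peaks vs ROI
peaks; large vs small GABA voxel) are run by passing the corresponding
candidate list.

## Synthetic-study generator

The generator emulates the *statistical* structure the analyses assume,
not the experiment's physics:

* **Durations** — a gamma renewal process per run (default shape 2.5,
  typical of bistable alternation timing; scale solved from the geometric
  mean of a gamma variate, `exp(ψ(shape) + log scale)`, for an 11 s
  target). Runs are 60 s, 8 per subject. The final interval of each run is
  truncated at the boundary; fragments shorter than 8 s are discarded.
  That threshold balances two opposing biases (the boundary interval is
  length-biased, so always dropping it shortens the kept sample; keeping
  every fragment drags the log-scale summary down): with only ~4.4
  percepts per run *some* truncation bias is unavoidable — about −5% on
  the geometric mean and −7% on the arithmetic mean at defaults, a known
  limitation of short observation windows rather than of the generator.
* **Between-subject spread** — each subject's gamma scale is multiplied by
  exp(N(0, 0.4)), chosen once so the 95% CI of the grand geometric mean at
  n = 37 has a realistic width (≈ ±1.5 s around ~10.5 s).
* **Covariates** — standard-Gaussian marginals with a user-specified
  correlation to the log geometric-mean duration and optional
  inter-covariate correlations (the completed matrix must be positive
  definite). By default the targets are imposed as the *exact sample*
  correlations (the `MASS::mvrnorm(empirical = TRUE)` convention, via
  QR-orthonormalised noise), so recovery and calibration checks measure
  the inference machinery itself rather than its convolution with
  sampling noise in r̂ — at n = 52 that noise alone has sd ≈ .08, which
  would dominate any ±.1 recovery criterion. Population-level sampling is
  available with `empirical=False`.
* **Default covariate set** — five covariates named for the measures they
  stand in for (three grey-matter peaks, a mask-ROI peak, a GABA ratio),
  two carrying real moderate effects (.39, .48) and three null — the
  composition the replication analyses themselves found.
* "Unclear percept" gaps between reversals are not modelled (no
  quantitative description exists to emulate); covariates are scalar
  peaks — no spatial VBM structure or spectra are simulated. Durations use
  the natural log throughout.

What passing tests on this generator do *not* show: robustness to
non-gamma duration distributions, to non-Gaussian covariates, to missing
data, or to the spatial selection effects (peak picking within ROIs) that
the replication literature worries about.

## Assumption checks

The classical prerequisites of a Pearson correlation are checked
numerically rather than visually: D'Agostino–Pearson normality per margin
(n ≥ 20), a quadratic-term test for linearity, a 4σ standardized-residual
outlier rule, and Breusch–Pagan for homoscedasticity (n ≥ 8). Defaults
(α = .01 per test) give the whole battery a ~95% joint pass rate under
bivariate normality, so flags are informative; they are advisory and never
drop data.

## Problem sizes and seeds

Every stochastic routine takes an explicit integer seed (PCG64; child
streams via `SeedSequence.spawn`, identical across platforms). The shipped
analysis drivers and tests use desk-scale sizes chosen for tight Monte-
Carlo error at interactive runtimes: 2·10⁵ studies for the sampling-
distribution check, 10⁵ for null-exceedance, 200 replicates for
calibration/recovery rates, 100 replicates × 32 models for WAIC model
recovery, 2 × 600 kept draws per regression fit.
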