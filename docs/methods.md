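# Methods

`pathint` decomposes homing errors from a guided-walking
path-integration task into interpretable sources: leaky integration,
velocity-gain bias, additive drift, accumulating internal noise, and
reporting noise. This note records the model, the numerical choices,
what the synthetic-data generator does and does not emulate, and the
known limitations.

## The generative model

A walker's internal estimate **x̂**(t) of their position evolves under a
linear Langevin (Ornstein–Uhlenbeck) equation driven by the true
velocity **v**(t):

    dx̂/dt = −β x̂ + α v + b + σ₀ ξ(t)

* **β** (leak, 1/m or 1/s): exponential forgetting of the integrated
  position. β = 0 is a perfect integrator.
* **α** (velocity gain, dimensionless): systematic over/under-estimation
  of displacement; α = 1 is unbiased.
* **b** (additive bias, m/m or m/s, a 2-vector): a constant drift of the
  estimate in a fixed world direction.
* **σ₀²** (accumulating-noise rate, m²/m or m²/s): unbiased Gaussian
  diffusion of the estimate.

Because the process is linear-Gaussian, its transition over a whole
trajectory segment (between consecutive stopping points, approximated
as a constant-velocity chord) is Gaussian with closed-form mean and
variance; `pathint.ou` evaluates these moments exactly. Two scalings
are supported: *distance* scaling, in which the rescaled parameters
(β̃ = β/|v|, b̃ = b/|v|, σ̃₀² = σ₀²/|v|) are held fixed so error accrues
per meter traveled, and *time* scaling, in which error accrues per
second (noise then also accrues while standing at a stop). A third
noise mode holds the per-stop variance constant (non-accumulating),
which decouples the stops.

At each stopping point the walker reports the homing vector (distance
and direction back to the start). Reports are corrupted by reporting
noise: Weber-like (log-normal in distance — the error magnitude grows
linearly with the reported distance) or constant-magnitude, plus
additive Gaussian angular noise. Eight named variants combine the
noise mode, report mode and bias toggle (`pathint.params.VARIANTS`).

## Likelihood

With reporting noise the reports are nonlinear (log-polar or polar)
observations of the latent Gaussian chain; `pathint.ekf` computes the
marginal likelihood with an extended Kalman filter: exact OU predict,
Jacobian-linearized update, innovation density summed over stops.
Implementation details that matter:

* The belief starts at the true start with zero covariance; the first
  predict injects process noise, so the innovation covariance is
  invertible whenever σ̃₀² > 0. σ̃₀² = 0 with reporting noise enabled is
  unidentifiable and rejected.
* Angle innovations are wrapped to (−π, π] before the update.
* Covariances are symmetrized after each update; trials whose
  predictive mean falls within 1e-6 m of the start (where the polar map
  is singular) receive a fixed −1e6 penalty instead of NaN.
* Missing intermediate reports (the non-stopping trials) use the
  infinite-observation-noise limit: updated = predictive, no likelihood
  term.
* Without reporting noise the internal estimate is reconstructed from
  the reports and the likelihood is the exact product of Gaussian
  transition densities (conditioning collapses the belief at each
  observed stop). Constant-noise variants use the independent-stop
  likelihood with the mean recursion running on predicted means, which
  reduces to uniform least squares over stops.

**Common likelihood scale.** The variants' natural observation spaces
differ (log-polar, polar, Cartesian). All reported log-likelihoods are
converted to the density of the *Cartesian report position* by the
parameter-free change-of-variables terms (−2·log d̂ per stop for
log-polar, −log d̂ for polar). This leaves every maximum-likelihood
estimate unchanged but makes BIC and cross-validation scores directly
comparable across variants; without it, model comparison across report
modes would be systematically distorted.

## Fitting

`PathIntegrationModel.fit()` maximizes the total log-likelihood with
L-BFGS-B over an unconstrained parameterization: log scale for β̃ and
all variances (flooring them at 1e-8), identity for α and b̃. The
default start point is β̃ = 0.05/m, α = 1, b̃ = 0, σ̃₀² = 0.1,
σ_d = σ_φ = 0.2; multi-start perturbs it (sd 1.0 in log-space for
rates/variances, 0.15 for α, 0.05 for bias) with a seeded generator.
The likelihood engine is vectorized across trials with the 2×2 algebra
written out, so a 10,000-trial likelihood evaluation costs ~20 ms and a
full fit seconds. Standard errors come from the numerical Hessian at
the optimum, delta-method-transformed back to the natural scale.

Cross-validation (`pathint.selection`): leave-one-trajectory-out (one
fold per trial, scored as −2·held-out log-likelihood averaged over
folds), leave-one-path-shape-out, and a stop-4 holdout that trains with
final-stop observations masked and scores only final-stop terms. Each
fold is an independent optimization; by default fold fits are
warm-started at the full-dataset optimum (`warm_start=False` restores
cold multi-starts). The warm start is identical across variants, so
variant rankings are unaffected; it cuts the 48-fold cost roughly
four-fold. BIC uses n = number of observed stopping-point reports
(each contributes one bivariate term); a different counting can be
supplied explicitly to `bic()`.

## Synthetic task generator

`pathint.task` and `pathint.simulate` emulate the behavioral study
design so every stage is testable without data downloads:

* 10 curved paths: four legs drawn from {2, 3.5, 5, 6.5} m constrained
  to sum to 17 m (so splined arc lengths land near the ~17.7 m of the
  original paths), turns of {55°, 80°, 105°} left/right, smoothed by a
  natural cubic spline through the turning points (chord-length
  parameterization, arc-length resampling at 0.05 m), rejection-sampled
  to fit a 10×8 m tracking area. Paths 7/8 and 9/10 are mirror pairs
  with single-direction turns; paths 1–6 mix directions. Stops sit at
  the three turning points and the endpoint.
* Sessions: 3 blocks × 16 trials (paths 1–10 with stops, paths 1–6
  repeated without intermediate stops), shuffled with ≥3 other trials
  between repeats of a path; straight standardization paths of 10, 2,
  6 m after the 4th and 12th trial of each block.
* Walking speed is drawn per segment (default 0.5 ± 0.05 m/s, matching
  ~35 s non-stopping traversals); reporting pauses at stops default to
  17.8 ± 4 s so stopping trials take ~88 s, reproducing the
  time-vs-distance dissociation. In time scaling, pauses are extra
  zero-velocity OU transitions.
* A multiplicative verbal distance bias (per distance band: [0,4),
  [4,8), ≥8 m — boundaries assigned upward) corrupts the verbal
  response; the standardization paths carry the same Weber reporting
  noise, so recovered correction factors are noisy but centred
  (geometrically) on the generating factors.
* Cohort defaults (`DEFAULT_GROUP_SPECS`): accumulating noise is the
  dominant error source and larger in the older group
  (σ̃₀² = 0.15 vs 0.30 m²/m), with a modest gain bias (α ≈ 1.10–1.15),
  small leak and additive bias, and stronger verbal under-reporting in
  older adults. Between-participant heterogeneity is log-normal
  (sd 0.2) on rates/variances and Gaussian on gain/bias.

What the generator does **not** emulate: heading-dependent reporting,
within-segment speed profiles (the model's constant-velocity chord
approximation is generative truth here), landmark use, fatigue or
learning across blocks, and non-multiplicative verbal bias. Passing
tests therefore validate the pipeline's internal consistency and its
behavior on model-consistent data, not the adequacy of the model for
any particular empirical dataset.

## Error metrics

Verbal distances are standardized per block half with f_corr =
d_correct/d_response from the matching standardization triplet; the
standardized distance and reported homing direction give the presumed
starting point; the absolute error is its distance from the true start,
and the incremental error its distance from the previously presumed
start (the true start at stop 1), isolating each segment's unique
contribution. The shuffled-response baseline permutes responses across
trials within participant × stop (pooling optional). Trials with
nonpositive reported distances are dropped with a warning; no other
outlier handling is applied.

## Influence decomposition

`pathint.influence` simulates the fitted model forward over the
dataset's trial geometry (default 100 repetitions per trial), scoring
the squared distance between the simulated presumed start and the true
start, averaged over repetitions, then trials, then stops. The
relative influence of a parameter is the percent reduction in this
predicted square error when that parameter alone is set to its ideal
value (β̃ = 0, α = 1, b̃ = 0, variances 0). Full and reduced simulations
share common random numbers, so an already-ideal parameter has exactly
zero influence. Influences can be negative (compensating
miscalibrations) and need not sum to 100%.

## Group statistics

One-sided permutation tests on the difference of group means (default
10,000 shuffles, add-one p-value estimator so p > 0; exact enumeration
available for small samples). The trimmed comparison drops the
best/worst fraction per group (or only the worst of the putatively
worse group) by stable rank before re-testing. The angular-velocity
median split assigns ties to the low group. The caller must state the
alternative explicitly; no default direction is assumed.

## Known limitations

* **EKF bias.** The EKF likelihood is an approximation; its maximum is
  not exactly the true ML estimate. On model-consistent synthetic data
  at the default study conditions the leak rate β̃ is overestimated by
  ~14% and σ_d slightly inflated (~10%), while α, σ̃₀² and σ_φ recover
  within a few percent; the exact-likelihood (no-reporting-noise)
  branch recovers everything to ~1% on matched data, isolating the bias
  to the linearized observation step. Iterated/unscented filters would
  reduce this but are outside this package's scope, which follows the
  plain-EKF formulation.
* The log-polar observation map is singular at the start point;
  near-origin predictive means are penalized rather than modeled.
* Constant-magnitude distance reporting noise can generate nonpositive
  reported distances; such trials are excluded at fitting time rather
  than truncated, which slightly censors extreme draws.
* Problem sizes in the test-suite recovery and model-recovery checks
  (200 virtual sessions for parameter recovery; 96-trial datasets and
  3 seeds per scenario for model recovery) were chosen as the package's
  own balance of statistical resolution against runtime.
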