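# pathint

Decomposition of human path-integration error from triangle-completion
style homing tasks.

People track their position while walking by integrating self-motion
cues, and their homing reports drift with traveled distance. This
package asks *why*: it fits a stochastic leaky-integrator model of the
internal position estimate to homing reports and splits the observed
error into distinct causes — memory leak, velocity-gain bias, additive
drift, accumulating noise, and reporting noise. It is aimed at
researchers analyzing guided-walking or VR path-integration
experiments (and at anyone who wants a tested reference implementation
of the underlying latent-state likelihood machinery).

## The model

The internal position estimate **x̂**(t) follows an Ornstein–Uhlenbeck
(Langevin) process driven by the true walking velocity **v**(t):

    dx̂/dt = −β x̂ + α v + b + σ₀ ξ(t)

with leak β, velocity gain α, additive bias **b**, and accumulating
Gaussian noise of rate σ₀². Over a trajectory segment the transition
is Gaussian with closed-form moments (distance- or time-scaled). At
each stopping point the homing vector (distance d, angle φ back to the
start) is reported with Weber-like noise:

    d̂ = exp(log d + σ_d η),   φ̂ = φ + σ_φ η

The marginal likelihood of a report sequence is computed with an
extended Kalman filter over the log-polar observation map; model
variants (time-scaled noise, constant noise, constant reporting noise,
no reporting noise, no additive bias) are compared with BIC and
cross-validation, and each fitted parameter's *relative influence* is
the percent reduction in model-predicted square error when that
parameter is set to its ideal value (β = 0, α = 1, b = 0,
variances 0).

A synthetic-data module reproduces the task design — 10 four-legged
spline-smoothed curved paths (~17.7 m), 3 blocks × 16 trials with 30
stopping / 18 non-stopping trials, straight 10/2/6 m standardization
paths for verbal-bias correction — so the whole pipeline is testable
end to end with known ground truth.

## Worked example

```python
import numpy as np
from pathint import (GenerativeAgent, IntegratorParams, ReportParams,
                     PathIntegrationModel, make_paths, make_session_design,
                     simulate_participant)

paths = make_paths(seed=1)
design = make_session_design(seed=2)
agent = GenerativeAgent(
    integrator=IntegratorParams(beta=0.05, alpha=1.1, bias=(0.05, -0.03),
                                sigma0_sq=0.2),
    reporter=ReportParams(sigma_d_sq=0.0625, sigma_phi_sq=0.04))
trials, standard = simulate_participant(agent, paths, design, rng=5,
                                        n_sessions=10)

res = PathIntegrationModel(trials, "full").fit(restarts=4, seed=0)
print(res.summary())
```

```
                 Path Integration Error Model
==============================================================
Variant:          full                No. trials:   480
Noise mode:       accumulate_distance No. obs stops:1380
Report mode:      weber               Converged:    True
Log-likelihood:   -5329.234           BIC:          10709.077
--------------------------------------------------------------
parameter           estimate       std err
--------------------------------------------------------------
beta                0.060324       0.00257
alpha                 1.1202        0.0143
bias_x              0.089063          0.01
bias_y             -0.033611       0.00505
sigma0_sq            0.19343        0.0136
sigma_d_sq          0.072554       0.00442
sigma_phi_sq        0.052212        0.0034
==============================================================
```

The fit lands close to the generating values: a leak near 0.05/m, a
~10% velocity-gain overshoot, a small drift, accumulating noise of
~0.2 m² per meter traveled, and Weber reporting noise near σ_d = 0.25
(log units) and σ_φ = 0.2 rad. (The leak and reporting-noise
estimates sit slightly high — a known small bias of EKF-based maximum
likelihood discussed in `docs/methods.md`.) From here,
`res.influence()` decomposes the predicted square error per parameter,
and `pathint.selection.compare(trials, ["full", "time"])` tests whether
error accrues with distance or elapsed time.

A command-line pipeline covers the same flow on a simulated cohort:

```bash
pathint all --seed 7 --out outdir    # simulate -> errors -> fit -> compare -> stats
```

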