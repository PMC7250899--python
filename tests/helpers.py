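"""Independent oracles used by the tests.

These deliberately avoid the package's own propagation/likelihood code
paths: Euler-Maruyama integration of the Langevin dynamics, a bootstrap
particle filter for the marginal likelihood, and central finite
differences for Jacobians.
"""

import numpy as np


def euler_maruyama_distance(x0, delta_x, params, n_steps=2000, n_samples=10_000,
                            rng=None):
    """Fine-step Euler-Maruyama integration of the distance-scaled
    Langevin dynamics over one straight segment; returns endpoint
    samples of shape (n_samples, 2)."""
    rng = np.random.default_rng(rng)
    L = np.linalg.norm(delta_x)
    u = np.asarray(delta_x) / L
    dl = L / n_steps
    x = np.tile(np.asarray(x0, dtype=float), (n_samples, 1))
    b = np.asarray(params.bias, dtype=float)
    for _ in range(n_steps):
        drift = -params.beta * x + params.alpha * u + b
        x = x + drift * dl + np.sqrt(params.sigma0_sq * dl) \
            * rng.standard_normal((n_samples, 2))
    return x


def numerical_jacobian(f, x, h=1e-6):
    """Central-difference Jacobian of a vector map at x."""
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(f(x))
    J = np.zeros((f0.size, x.size))
    for j in range(x.size):
        e = np.zeros_like(x)
        e[j] = h
        J[:, j] = (np.asarray(f(x + e)) - np.asarray(f(x - e))) / (2 * h)
    return J


def particle_filter_loglik(dx_list, observations, params, reporter,
                           n_particles=100_000, rng=None, mode="weber"):
    """Bootstrap particle filter estimate of the marginal log-likelihood
    of a report sequence for the distance-scaled accumulating-noise
    model.

    ``dx_list`` is a list of segment displacement 2-vectors;
    ``observations`` a list of (d_hat, phi_hat) or None for a missing
    report.  The latent transition is the exact Gaussian OU kernel; the
    observation density is evaluated exactly (log-normal distance or
    Gaussian distance, Gaussian wrapped angle), so the only
    approximation is Monte-Carlo.
    """
    from pathint import ou
    from pathint.simulate import wrap_angle

    rng = np.random.default_rng(rng)
    x = np.zeros((n_particles, 2))
    ll = 0.0
    for dx, obs in zip(dx_list, observations):
        mean, var = ou.propagate_distance(x, np.asarray(dx, float), params)
        x = mean + np.sqrt(var) * rng.standard_normal((n_particles, 2))
        if obs is None:
            continue
        d_hat, phi_hat = obs
        d = np.linalg.norm(x, axis=1)
        phi = np.arctan2(x[:, 1], x[:, 0])
        if mode == "weber":
            # density of d_hat | d is log-normal; converted to the
            # Cartesian report scale used by the package: the joint
            # density of the reported position, i.e. /(d_hat^2)
            logw_d = (-0.5 * np.log(2 * np.pi * reporter.sigma_d_sq)
                      - (np.log(d_hat) - np.log(d))**2 / (2 * reporter.sigma_d_sq)
                      - np.log(d_hat)) - np.log(d_hat)
        else:
            logw_d = (-0.5 * np.log(2 * np.pi * reporter.sigma_d_sq)
                      - (d_hat - d)**2 / (2 * reporter.sigma_d_sq)) \
                - np.log(d_hat)
        err = wrap_angle(phi_hat - phi)
        logw_phi = (-0.5 * np.log(2 * np.pi * reporter.sigma_phi_sq)
                    - err**2 / (2 * reporter.sigma_phi_sq))
        logw = logw_d + logw_phi
        m = logw.max()
        w = np.exp(logw - m)
        ll += m + np.log(w.mean())
        # resample
        idx = rng.choice(n_particles, size=n_particles, p=w / w.sum())
        x = x[idx]
    return ll
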