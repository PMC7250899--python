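"""Exact segment-wise moment propagation of the internal position estimate.

Between two stopping points the internal estimate evolves as a 2-D
Ornstein-Uhlenbeck process with leak ``beta``, velocity gain ``alpha``,
additive bias ``b`` and accumulating isotropic noise ``sigma0_sq``.
Because the process is linear-Gaussian, its transition over a whole
segment has closed-form mean and variance; no Euler discretisation is
involved anywhere.

All helpers are vectorised: scalar segment quantities may be arrays,
and position vectors may be ``(..., 2)`` stacks.
"""

from __future__ import annotations

import numpy as np

from .params import IntegratorParams

__all__ = [
    "efold",
    "propagate_distance",
    "propagate_time",
    "propagate_constant_noise",
]


def efold(beta: float, span) -> np.ndarray:
    """Stable evaluation of ``(1 - exp(-beta * span)) / beta``.

    For ``beta == 0`` this is exactly ``span``; otherwise ``expm1``
    keeps the expression accurate down to arbitrarily small ``beta``.
    """
    span = np.asarray(span, dtype=float)
    if beta == 0.0:
        return span.copy()
    return -np.expm1(-beta * span) / beta


def _check_finite(params: IntegratorParams) -> None:
    vals = (params.beta, params.alpha, *params.bias, params.sigma0_sq)
    if not all(np.isfinite(vals)):
        raise ValueError("non-finite integrator parameters")


def propagate_distance(x_prev, delta_x, params: IntegratorParams):
    """Transition moments over a segment, distance scaling.

    ``mu = x_prev e^{-beta L} + (alpha dx/L + b) (1-e^{-beta L})/beta``
    with ``L = |dx|``, and isotropic variance
    ``sigma^2 = sigma0_sq (1-e^{-2 beta L})/(2 beta)``.

    A zero-length segment is the identity transition with no added
    variance (the estimate does not diffuse while stationary).

    Returns ``(mean, var)`` with ``mean`` shaped like ``x_prev`` and
    ``var`` scalar (or broadcast over leading axes).
    """
    _check_finite(params)
    x_prev = np.asarray(x_prev, dtype=float)
    delta_x = np.asarray(delta_x, dtype=float)
    L = np.asarray(np.linalg.norm(delta_x, axis=-1))
    g1 = efold(params.beta, L)          # (1-e^{-bL})/b
    g2 = efold(2.0 * params.beta, L)    # (1-e^{-2bL})/(2b)
    decay = np.exp(-params.beta * L)
    unit = delta_x / np.where(L == 0, 1.0, L)[..., None]
    drift = params.alpha * unit + params.bias_vec
    mean = x_prev * decay[..., None] + drift * g1[..., None]
    # L == 0: identity transition
    mean = np.where(L[..., None] == 0, x_prev, mean)
    var = params.sigma0_sq * np.where(L == 0, 0.0, g2)
    return mean, var


def propagate_time(x_prev, delta_x, delta_t, params: IntegratorParams):
    """Transition moments over a segment, time scaling.

    As :func:`propagate_distance` but with elapsed time ``delta_t`` in
    place of segment length, and mean velocity ``dx/dt`` in place of the
    unit direction:
    ``mu = x_prev e^{-beta dt} + (alpha dx/dt + b)(1-e^{-beta dt})/beta``.
    """
    _check_finite(params)
    x_prev = np.asarray(x_prev, dtype=float)
    delta_x = np.asarray(delta_x, dtype=float)
    delta_t = np.asarray(np.asarray(delta_t, dtype=float))
    if np.any(delta_t <= 0):
        raise ValueError("segment durations must be > 0")
    g1 = efold(params.beta, delta_t)
    g2 = efold(2.0 * params.beta, delta_t)
    decay = np.exp(-params.beta * delta_t)
    vel = delta_x / delta_t[..., None]
    drift = params.alpha * vel + params.bias_vec
    mean = x_prev * decay[..., None] + drift * g1[..., None]
    var = params.sigma0_sq * g2
    return mean, var


def propagate_constant_noise(mu_prev, delta_x, params: IntegratorParams):
    """Mean recursion with constant (non-accumulating) noise.

    The mean follows the distance-scaled recursion evaluated at the
    previous *predicted mean* (not a measured estimate); the variance is
    the fixed ``sigma0_sq`` at every stop, so stop-to-stop estimates are
    conditionally independent.
    """
    mean, _ = propagate_distance(mu_prev, delta_x, params)
    delta_x = np.asarray(delta_x, dtype=float)
    var = np.broadcast_to(
        params.sigma0_sq, np.linalg.norm(delta_x, axis=-1).shape
    ).copy()
    return mean, var
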