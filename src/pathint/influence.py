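"""Forward prediction of homing errors and parameter-influence decomposition.

The fitted model is simulated forward over the dataset's trial
geometry; the predicted square error is the squared distance between
the simulated presumed starting point and the true start, averaged over
repetitions, then trials, then stops.  The relative influence of a
parameter is the percent reduction of that predicted square error when
the parameter is set to its ideal value (beta = 0, alpha = 1, b = 0,
variances = 0) with the others held at their estimates; it can be
negative when two miscalibrations partially cancel.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import ou
from .ekf import TrialArrays
from .params import IntegratorParams, ReportParams, VariantSpec, get_variant

PARAM_IDEALS = {
    "beta": 0.0,
    "alpha": 1.0,
    "bias": (0.0, 0.0),
    "sigma0_sq": 0.0,
    "sigma_d_sq": 0.0,
    "sigma_phi_sq": 0.0,
}

__all__ = [
    "predict_errors",
    "reduced_error",
    "relative_influence",
    "influence_table",
    "error_contribution_by_group",
    "PARAM_IDEALS",
]


def _simulate_square_errors(arrays: TrialArrays, integ: IntegratorParams,
                            reporter: ReportParams | None, variant: VariantSpec,
                            n_reps: int, rng: np.random.Generator):
    """Square homing error per (rep, trial, stop), observed stops only
    marked by ``arrays.obs``; vectorized across reps and trials."""
    n = arrays.n_trials
    x = np.zeros((n_reps, n, 2))
    mu_cn = np.zeros((n, 2))        # deterministic mean chain for constant noise
    sq = np.zeros((n_reps, n, 4))
    stops = np.cumsum(arrays.dx, axis=1)   # (n, 4, 2) true stop positions
    for s in range(4):
        dx = arrays.dx[:, s]
        if variant.noise_mode == "accumulate_time":
            mean, var = ou.propagate_time(x, dx, arrays.dt[:, s], integ)
        elif variant.noise_mode == "constant":
            mu_cn, var = ou.propagate_constant_noise(mu_cn, dx, integ)
            mean = np.broadcast_to(mu_cn, (n_reps, n, 2))
            var = np.broadcast_to(var, (n_reps, n))
        else:
            mean, var = ou.propagate_distance(x, dx, integ)
        x = mean + np.sqrt(np.maximum(var, 0.0))[..., None] \
            * rng.standard_normal((n_reps, n, 2))
        # reports of the homing vector
        d = np.linalg.norm(x, axis=-1)
        phi = np.arctan2(x[..., 1], x[..., 0])
        if reporter is None or variant.report_mode == "none":
            d_hat, phi_hat = d, phi
        elif variant.report_mode == "weber":
            d_safe = np.maximum(d, 1e-12)
            d_hat = np.exp(np.log(d_safe) + np.sqrt(reporter.sigma_d_sq)
                           * rng.standard_normal(d.shape))
            phi_hat = phi + np.sqrt(reporter.sigma_phi_sq) \
                * rng.standard_normal(phi.shape)
        else:  # constant-magnitude reporting noise
            d_hat = d + np.sqrt(reporter.sigma_d_sq) \
                * rng.standard_normal(d.shape)
            phi_hat = phi + np.sqrt(reporter.sigma_phi_sq) \
                * rng.standard_normal(phi.shape)
        # presumed start = stop - d_hat * unit(phi_hat); true start is 0
        pres = stops[None, :, s, :] - np.stack(
            [d_hat * np.cos(phi_hat), d_hat * np.sin(phi_hat)], axis=-1)
        sq[:, :, s] = np.sum(pres**2, axis=-1)
    return sq


def predict_errors(integ: IntegratorParams, reporter: ReportParams | None,
                   variant: str | VariantSpec = "full", design=None,
                   arrays: TrialArrays | None = None, n_reps: int = 100,
                   seed: int = 0, per_stop: bool = False):
    """Model-predicted mean square homing error.

    Simulates ``n_reps`` stochastic repetitions of every trial in
    ``arrays`` (or of the 4-stop trials of a `SessionDesign`-like list
    of paths in ``design``) and averages the squared presumed-start
    error over repetitions, then trials, then stops.  With
    ``per_stop=True`` returns the 4-vector of per-stop means instead of
    the scalar.
    """
    variant = get_variant(variant)
    if arrays is None:
        if design is None:
            raise ValueError("need either arrays or design")
        arrays = _arrays_from_paths(design)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    sq = _simulate_square_errors(arrays, integ, reporter, variant, n_reps, rng)
    rep_mean = sq.mean(axis=0)                        # (n, 4)
    mask = arrays.obs
    with np.errstate(invalid="ignore"):
        per_stop_mean = np.array([
            rep_mean[mask[:, s], s].mean() if mask[:, s].any() else np.nan
            for s in range(4)])
    if per_stop:
        return per_stop_mean
    return float(np.nanmean(per_stop_mean))


def _arrays_from_paths(paths) -> TrialArrays:
    from .task import CurvedPath
    if isinstance(paths, CurvedPath):
        paths = [paths]
    dx = []
    dt = []
    for p in paths:
        stops = p.stop_positions
        d = np.diff(np.vstack([np.zeros(2), stops]), axis=0)
        dx.append(d)
        dt.append(np.linalg.norm(d, axis=1) / 0.5)   # nominal 0.5 m/s walk
    n = len(dx)
    return TrialArrays(np.array(dx), np.array(dt),
                       np.full((n, 4), np.nan), np.full((n, 4), np.nan),
                       np.ones((n, 4), dtype=bool))


def _idealized(integ: IntegratorParams, reporter: ReportParams | None, which: str):
    if which in ("beta", "alpha", "bias", "sigma0_sq"):
        integ = replace(integ, **{which: PARAM_IDEALS[which]})
    elif which in ("sigma_d_sq", "sigma_phi_sq"):
        if reporter is not None:
            reporter = replace(reporter, **{which: 0.0})
    else:
        raise ValueError(f"unknown parameter {which!r}")
    return integ, reporter


def reduced_error(integ: IntegratorParams, reporter: ReportParams | None,
                  which: str, variant: str | VariantSpec = "full",
                  arrays: TrialArrays | None = None, design=None,
                  n_reps: int = 100, seed: int = 0) -> float:
    """Predicted square error with one parameter set to its ideal value.

    The same seed as the full-model prediction gives common random
    numbers, reducing the variance of the influence estimate.
    """
    integ_r, rep_r = _idealized(integ, reporter, which)
    return predict_errors(integ_r, rep_r, variant, design=design,
                          arrays=arrays, n_reps=n_reps, seed=seed)


def relative_influence(full_sq_error: float, reduced_sq_error: float) -> float:
    """Percent reduction of the predicted square error:
    100 (error^2 - error_i^2) / error^2.  May be negative; influences
    need not sum to 100%."""
    if not full_sq_error > 0:
        raise ValueError("relative influence undefined for zero full error")
    return 100.0 * (full_sq_error - reduced_sq_error) / full_sq_error


def influence_table(results, n_reps: int = 100, seed: int = 0,
                    params: tuple[str, ...] = ("beta", "alpha", "bias",
                                               "sigma0_sq", "sigma_d_sq",
                                               "sigma_phi_sq")) -> pd.DataFrame:
    """Per-parameter reduced error, relative influence and absolute
    contribution for one fitted `PathIntegrationResults`."""
    arrays = results.model.data
    integ, rep, variant = results.integrator, results.reporter, results.variant
    full = predict_errors(integ, rep, variant, arrays=arrays,
                          n_reps=n_reps, seed=seed)
    rows = []
    for which in params:
        if which in ("sigma_d_sq", "sigma_phi_sq") and rep is None:
            continue
        red = reduced_error(integ, rep, which, variant, arrays=arrays,
                            n_reps=n_reps, seed=seed)
        rows.append({"parameter": which, "full_sq_error": full,
                     "reduced_sq_error": red,
                     "influence_pct": relative_influence(full, red)
                     if full > 0 else np.nan,
                     "contribution": full - red})
    return pd.DataFrame(rows)


def error_contribution_by_group(fits: dict, n_reps: int = 100,
                                seed: int = 0) -> pd.DataFrame:
    """Per-participant, per-parameter absolute error contributions
    (error^2(ML) - error_i^2), ready for group permutation testing.

    ``fits`` maps participant id to a `PathIntegrationResults`; each is
    simulated over that participant's own trial geometry.
    """
    frames = []
    for i, (pid, res) in enumerate(sorted(fits.items())):
        tab = influence_table(res, n_reps=n_reps, seed=seed + i)
        tab.insert(0, "participant_id", pid)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
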