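"""Marginal log-likelihood of homing reports via extended Kalman filtering.

The internal position estimate is a latent linear-Gaussian chain (the
OU segment transitions); the reports are nonlinear observations of it
(log-polar for Weber reporting noise, polar for constant reporting
noise).  The EKF linearizes the observation map around the predictive
mean and yields the marginal likelihood of the report sequence as a
product of Gaussian innovation densities.  Variants without reporting
noise condition on the internal estimate directly (the observation is
exact), and constant-noise variants drop the stop-to-stop coupling.

Everything is vectorised across trials; beliefs are 2-vectors with 2x2
covariances and all the matrix algebra is written out explicitly.

All log-likelihoods are returned on a common scale: the density of the
*Cartesian* report position.  For log-polar observations this subtracts
``2 log d_hat`` per observed stop, for polar observations ``log d_hat``
(parameter-free change-of-variables terms), which makes values
comparable across variants in BIC and cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ou
from .params import IntegratorParams, ReportParams, VariantSpec, get_variant
from .simulate import wrap_angle

ORIGIN_EPS = 1e-6      # m; predictive means closer to the start than this
ORIGIN_PENALTY = -1e6  # get a large log-likelihood penalty instead of a NaN

LOG2PI = np.log(2.0 * np.pi)

__all__ = [
    "Belief",
    "TrialArrays",
    "observe_logpolar",
    "observe_polar",
    "ekf_step",
    "ekf_step_missing",
    "trial_loglik",
    "trial_logliks",
]


@dataclass
class Belief:
    """Gaussian belief over the internal position estimate."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        if np.max(np.abs(self.cov - self.cov.T)) > 1e-10:
            raise ValueError("belief covariance must be symmetric")
        w = np.linalg.eigvalsh(self.cov)
        if np.min(w) < -1e-10:
            raise ValueError("belief covariance must be positive semidefinite")
        self.cov = 0.5 * (self.cov + self.cov.T)


# ---------------------------------------------------------------------------
# observation maps and Jacobians


def observe_logpolar(mean_xy):
    """Log-polar observation h(x) = (log|x|, atan2(x2, x1)) and Jacobian.

    H = (1/|x|^2) [[x1, x2], [-x2, x1]].  Batched over leading axes.
    """
    x = np.asarray(mean_xy, dtype=float)
    r2 = np.sum(x**2, axis=-1)
    if np.any(r2 < ORIGIN_EPS**2):
        raise FloatingPointError("observation map degenerate: point at the origin")
    h = np.stack([0.5 * np.log(r2), np.arctan2(x[..., 1], x[..., 0])], axis=-1)
    H = np.empty(x.shape[:-1] + (2, 2))
    H[..., 0, 0] = x[..., 0] / r2
    H[..., 0, 1] = x[..., 1] / r2
    H[..., 1, 0] = -x[..., 1] / r2
    H[..., 1, 1] = x[..., 0] / r2
    return h, H


def observe_polar(mean_xy):
    """Polar observation h(x) = (|x|, atan2(x2, x1)) and Jacobian.

    The angle row matches the log-polar Jacobian; the distance row is
    scaled by |x|.
    """
    x = np.asarray(mean_xy, dtype=float)
    r2 = np.sum(x**2, axis=-1)
    if np.any(r2 < ORIGIN_EPS**2):
        raise FloatingPointError("observation map degenerate: point at the origin")
    r = np.sqrt(r2)
    h = np.stack([r, np.arctan2(x[..., 1], x[..., 0])], axis=-1)
    H = np.empty(x.shape[:-1] + (2, 2))
    H[..., 0, 0] = x[..., 0] / r
    H[..., 0, 1] = x[..., 1] / r
    H[..., 1, 0] = -x[..., 1] / r2
    H[..., 1, 1] = x[..., 0] / r2
    return h, H


# ---------------------------------------------------------------------------
# scalar EKF steps (reference API; the fitter uses the batched engine)


def _predict(belief: Belief, segment: dict, params: IntegratorParams,
             variant: VariantSpec) -> Belief:
    dx = np.asarray(segment["dx"], dtype=float)
    if variant.noise_mode == "accumulate_time":
        mean, var = ou.propagate_time(belief.mean, dx, segment["dt"], params)
        span = float(segment["dt"])
    else:
        mean, var = ou.propagate_distance(belief.mean, dx, params)
        span = float(np.linalg.norm(dx))
    F = np.exp(-params.beta * span)
    cov = F**2 * belief.cov + float(var) * np.eye(2)
    return Belief(mean, cov)


def ekf_step(belief: Belief, segment: dict, observation, params: IntegratorParams,
             reporter: ReportParams, variant: VariantSpec | str = "full"):
    """One predict+update EKF step for a single trial.

    ``segment`` is a mapping with ``dx`` (2-vector) and, in time mode,
    ``dt``; ``observation`` is the report pair (d_hat, phi_hat) in
    meters/radians.  Returns ``(updated Belief, log-likelihood
    contribution)`` with the contribution on the observation (z) scale.
    """
    variant = get_variant(variant)
    pred = _predict(belief, segment, params, variant)
    d_hat, phi_hat = observation
    if variant.report_mode == "weber":
        if d_hat <= 0:
            raise ValueError("weber-mode observation needs d_hat > 0")
        z = np.array([np.log(d_hat), phi_hat])
        h, H = observe_logpolar(pred.mean)
    elif variant.report_mode == "constant":
        z = np.array([d_hat, phi_hat])
        h, H = observe_polar(pred.mean)
    else:
        raise ValueError("ekf_step needs a reporting-noise observation model")
    Sz = np.diag([reporter.sigma_d_sq, reporter.sigma_phi_sq])
    S = H @ pred.cov @ H.T + Sz
    det = np.linalg.det(S)
    if det <= 0:
        raise np.linalg.LinAlgError(
            f"singular innovation covariance (det={det:g}); "
            "is the configuration identifiable?")
    y = z - h
    y[1] = wrap_angle(y[1])
    Sinv = np.linalg.inv(S)
    ll = -LOG2PI - 0.5 * np.log(det) - 0.5 * float(y @ Sinv @ y)
    K = pred.cov @ H.T @ Sinv
    mean = pred.mean + K @ y
    cov = (np.eye(2) - K @ H) @ pred.cov
    cov = 0.5 * (cov + cov.T)
    return Belief(mean, cov), ll


def ekf_step_missing(belief: Belief, segment: dict, params: IntegratorParams,
                     variant: VariantSpec | str = "full") -> Belief:
    """Predict-only step for a stop without a report (the infinite
    observation-noise limit: updated = predictive, zero log-likelihood
    contribution)."""
    return _predict(belief, segment, params, get_variant(variant))


# ---------------------------------------------------------------------------
# batched trial arrays


@dataclass
class TrialArrays:
    """Dense per-trial arrays for the likelihood engine.

    Shapes: ``dx`` (n, 4, 2); ``dt``, ``d_hat``, ``phi_hat``, ``obs``
    (n, 4).  ``d_hat`` holds the standardized reported distance in
    meters, ``phi_hat`` the reported homing angle in radians; ``obs``
    flags stops with a report.
    """

    dx: np.ndarray
    dt: np.ndarray
    d_hat: np.ndarray
    phi_hat: np.ndarray
    obs: np.ndarray
    trial_key: pd.DataFrame | None = None   # participant_id/block/trial_index/path_id
    n_excluded: int = 0

    @property
    def n_trials(self) -> int:
        return self.dx.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.obs.sum())

    @property
    def seg_len(self) -> np.ndarray:
        return np.linalg.norm(self.dx, axis=-1)

    def masked_stop4(self) -> "TrialArrays":
        """Copy with the final-stop observations hidden (for holdout CV)."""
        obs = self.obs.copy()
        obs[:, 3] = False
        return TrialArrays(self.dx, self.dt, self.d_hat, self.phi_hat, obs,
                           self.trial_key, self.n_excluded)

    def subset(self, idx) -> "TrialArrays":
        idx = np.asarray(idx)
        key = self.trial_key.iloc[idx].reset_index(drop=True) \
            if self.trial_key is not None else None
        return TrialArrays(self.dx[idx], self.dt[idx], self.d_hat[idx],
                           self.phi_hat[idx], self.obs[idx], key, 0)

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame,
                       distance_col: str | None = None) -> "TrialArrays":
        """Build arrays from the tidy per-stop trial table.

        Uses ``standardized_distance_m`` when present (falling back to
        ``reported_distance_m``).  Trials containing a nonpositive
        reported distance are excluded with a warning.
        """
        if distance_col is None:
            distance_col = ("standardized_distance_m"
                            if "standardized_distance_m" in trials.columns
                            else "reported_distance_m")
        key_cols = ["participant_id", "block", "trial_index"]
        for c in key_cols:
            if c not in trials.columns:
                trials = trials.assign(**{c: 0})
        df = trials.sort_values(key_cols + ["stop_index"])
        dx_l, dt_l, d_l, phi_l, obs_l, keys = [], [], [], [], [], []
        n_excluded = 0
        for key, g in df.groupby(key_cols, sort=False):
            if len(g) != 4:
                raise ValueError(f"trial {key} does not have 4 stops")
            stops = g[["true_x", "true_y"]].to_numpy()
            dx = np.diff(np.vstack([np.zeros(2), stops]), axis=0)
            d = g[distance_col].to_numpy(dtype=float)
            # table stores the homing orientation (stop -> start); the model's
            # observation angle is the polar angle of the position estimate
            phi = wrap_angle(np.deg2rad(g["reported_angle_deg"].to_numpy(dtype=float))
                             + np.pi)
            obs = np.isfinite(d) & np.isfinite(phi)
            if np.any(obs & (d <= 0)):
                warnings.warn(f"trial {key}: nonpositive reported distance; "
                              "trial excluded")
                n_excluded += 1
                continue
            dx_l.append(dx)
            dt_l.append(g["seg_duration_s"].to_numpy(dtype=float))
            d_l.append(np.where(obs, d, np.nan))
            phi_l.append(np.where(obs, phi, np.nan))
            obs_l.append(obs)
            path = g["path_id"].iloc[0] if "path_id" in g.columns else "path"
            keys.append(dict(zip(key_cols, key)) | {"path_id": path})
        if not dx_l:
            raise ValueError("no usable trials")
        return cls(np.array(dx_l), np.array(dt_l), np.array(d_l),
                   np.array(phi_l), np.array(obs_l, dtype=bool),
                   pd.DataFrame(keys), n_excluded)


# ---------------------------------------------------------------------------
# batched likelihood engine


def _iso_logpdf2(resid_sq, var):
    """Log-density of a 2-D isotropic Gaussian at squared radius resid_sq."""
    return -LOG2PI - np.log(var) - 0.5 * resid_sq / var


def _step_moments(arrays: TrialArrays, s: int, integ: IntegratorParams,
                  variant: VariantSpec, mu):
    """Predictive mean/variance and transition decay for segment s."""
    dx = arrays.dx[:, s]
    if variant.noise_mode == "accumulate_time":
        span = arrays.dt[:, s]
        mean, var = ou.propagate_time(mu, dx, span, integ)
    else:
        span = np.linalg.norm(dx, axis=-1)
        if variant.noise_mode == "constant":
            mean, var = ou.propagate_constant_noise(mu, dx, integ)
        else:
            mean, var = ou.propagate_distance(mu, dx, integ)
    decay = np.exp(-integ.beta * span)
    return mean, np.asarray(var, dtype=float), decay


def trial_logliks(arrays: TrialArrays, integ: IntegratorParams,
                  reporter: ReportParams | None,
                  variant: VariantSpec | str = "full",
                  per_stop: bool = False):
    """Log-likelihood per trial (Cartesian report-position scale).

    Returns an (n_trials,) array, or an (n_trials, 4) per-stop matrix
    when ``per_stop`` is True (zeros at unobserved stops).
    """
    variant = get_variant(variant)
    n = arrays.n_trials
    contrib = np.zeros((n, 4))

    if variant.report_mode == "none":
        _loglik_exact_state(arrays, integ, variant, contrib)
    elif variant.noise_mode == "constant":
        _loglik_constant_noise_rn(arrays, integ, reporter, variant, contrib)
    else:
        _loglik_ekf(arrays, integ, reporter, variant, contrib)
    return contrib if per_stop else contrib.sum(axis=1)


def _cartesian_scale(arrays: TrialArrays, variant: VariantSpec) -> np.ndarray:
    """Per-stop change-of-variables term from the observation space to
    Cartesian report coordinates."""
    logd = np.where(arrays.obs, np.log(np.where(arrays.obs, arrays.d_hat, 1.0)), 0.0)
    if variant.report_mode == "weber":
        return -2.0 * logd
    if variant.report_mode == "constant":
        return -logd
    return np.zeros_like(logd)


def _loglik_exact_state(arrays, integ, variant, contrib):
    # Reports determine the internal estimate exactly: chain of Gaussian
    # transition densities (isotropic), conditioning collapses beliefs.
    xhat = np.stack([arrays.d_hat * np.cos(arrays.phi_hat),
                     arrays.d_hat * np.sin(arrays.phi_hat)], axis=-1)  # (n,4,2)
    n = arrays.n_trials
    mu = np.zeros((n, 2))
    p = np.zeros(n)
    for s in range(4):
        mean, var, decay = _step_moments(arrays, s, integ, variant, mu)
        if variant.noise_mode == "constant":
            # independent stops: mean recursion on predicted mean, fixed var
            tot = var
            obs = arrays.obs[:, s]
            resid_sq = np.sum((xhat[:, s] - mean)**2, axis=-1)
            contrib[obs, s] = _iso_logpdf2(resid_sq, np.maximum(tot, 1e-300))[obs]
            mu = mean
        else:
            tot = decay**2 * p + var
            obs = arrays.obs[:, s]
            resid_sq = np.sum((xhat[:, s] - mean)**2, axis=-1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = _iso_logpdf2(resid_sq, np.maximum(tot, 1e-300))
            contrib[obs, s] = ll[obs]
            mu = np.where(obs[:, None], np.where(np.isfinite(xhat[:, s]),
                                                 xhat[:, s], mean), mean)
            p = np.where(obs, 0.0, tot)




def _obs_components(arrays, s, mean, variant):
    """Innovation and Jacobian components at stop s, written out for speed.

    Returns (y1, y2, h11, h12, h21, h22, bad) with ``bad`` flagging
    predictive means at the origin singularity.
    """
    m1, m2 = mean[:, 0], mean[:, 1]
    r2 = m1 * m1 + m2 * m2
    bad = r2 < ORIGIN_EPS**2
    r2s = np.where(bad, ORIGIN_EPS**2, r2)
    m1 = np.where(bad, ORIGIN_EPS, m1)
    m2 = np.where(bad, 0.0, m2)
    phi_pred = np.arctan2(m2, m1)
    obs = arrays.obs[:, s]
    d = np.where(obs, arrays.d_hat[:, s], 1.0)
    phi = np.where(obs, arrays.phi_hat[:, s], 0.0)
    if variant.report_mode == "weber":
        y1 = np.log(d) - 0.5 * np.log(r2s)
        h11 = m1 / r2s
        h12 = m2 / r2s
    else:
        r = np.sqrt(r2s)
        y1 = d - r
        h11 = m1 / r
        h12 = m2 / r
    y2 = wrap_angle(phi - phi_pred)
    h21 = -m2 / r2s
    h22 = m1 / r2s
    return y1, y2, h11, h12, h21, h22, bad


def _gauss2_ll(y1, y2, S11, S12, S22):
    det = np.maximum(S11 * S22 - S12 * S12, 1e-300)
    quad = (S22 * y1 * y1 - 2.0 * S12 * y1 * y2 + S11 * y2 * y2) / det
    return -LOG2PI - 0.5 * np.log(det) - 0.5 * quad, det


def _loglik_constant_noise_rn(arrays, integ, reporter, variant, contrib):
    # stop-to-stop independence: no Kalman update, S = H Sx H' + Sz
    n = arrays.n_trials
    mu = np.zeros((n, 2))
    sd2, sp2 = reporter.sigma_d_sq, reporter.sigma_phi_sq
    scale = _cartesian_scale(arrays, variant)
    for s in range(4):
        mean, var, _ = _step_moments(arrays, s, integ, variant, mu)
        y1, y2, h11, h12, h21, h22, bad = _obs_components(arrays, s, mean, variant)
        S11 = var * (h11 * h11 + h12 * h12) + sd2
        S12 = var * (h11 * h21 + h12 * h22)
        S22 = var * (h21 * h21 + h22 * h22) + sp2
        ll, _ = _gauss2_ll(y1, y2, S11, S12, S22)
        obs = arrays.obs[:, s]
        contrib[obs, s] = (ll + scale[:, s])[obs]
        contrib[obs & bad, s] = ORIGIN_PENALTY
        mu = mean


def _loglik_ekf(arrays, integ, reporter, variant, contrib):
    n = arrays.n_trials
    mu = np.zeros((n, 2))
    p11 = np.zeros(n)
    p12 = np.zeros(n)
    p22 = np.zeros(n)
    sd2, sp2 = reporter.sigma_d_sq, reporter.sigma_phi_sq
    scale = _cartesian_scale(arrays, variant)
    for s in range(4):
        mean, var, decay = _step_moments(arrays, s, integ, variant, mu)
        d2 = decay * decay
        p11 = d2 * p11 + var
        p12 = d2 * p12
        p22 = d2 * p22 + var
        mu = mean
        obs = arrays.obs[:, s]
        if not obs.any():
            continue
        y1, y2, h11, h12, h21, h22, bad = _obs_components(arrays, s, mu, variant)
        # PHt = P H^T
        A11 = p11 * h11 + p12 * h12
        A12 = p11 * h21 + p12 * h22
        A21 = p12 * h11 + p22 * h12
        A22 = p12 * h21 + p22 * h22
        # S = H P H^T + Sz (symmetrized)
        S11 = h11 * A11 + h12 * A21 + sd2
        S22 = h21 * A12 + h22 * A22 + sp2
        S12 = 0.5 * (h11 * A12 + h12 * A22 + h21 * A11 + h22 * A21)
        ll, det = _gauss2_ll(y1, y2, S11, S12, S22)
        # K = PHt S^{-1}
        ia, ib, id_ = S22 / det, -S12 / det, S11 / det
        K11 = A11 * ia + A12 * ib
        K12 = A11 * ib + A12 * id_
        K21 = A21 * ia + A22 * ib
        K22 = A21 * ib + A22 * id_
        # M = I - K H
        M11 = 1.0 - (K11 * h11 + K12 * h21)
        M12 = -(K11 * h12 + K12 * h22)
        M21 = -(K21 * h11 + K22 * h21)
        M22 = 1.0 - (K21 * h12 + K22 * h22)
        q11 = M11 * p11 + M12 * p12
        q12u = M11 * p12 + M12 * p22
        q21u = M21 * p11 + M22 * p12
        q22 = M21 * p12 + M22 * p22
        q12 = 0.5 * (q12u + q21u)
        u1 = mu[:, 0] + K11 * y1 + K12 * y2
        u2 = mu[:, 1] + K21 * y1 + K22 * y2
        contrib[obs, s] = (ll + scale[:, s])[obs]
        contrib[obs & bad, s] = ORIGIN_PENALTY
        upd = obs & ~bad
        mu = np.where(upd[:, None], np.stack([u1, u2], axis=1), mu)
        p11 = np.where(upd, q11, p11)
        p12 = np.where(upd, q12, p12)
        p22 = np.where(upd, q22, p22)


def trial_loglik(trial: pd.DataFrame | TrialArrays, integ: IntegratorParams,
                 reporter: ReportParams | None = None,
                 variant: VariantSpec | str = "full") -> float:
    """Total log-likelihood of one or more trials (sum over trials)."""
    arrays = trial if isinstance(trial, TrialArrays) \
        else TrialArrays.from_dataframe(trial)
    return float(trial_logliks(arrays, integ, reporter, variant).sum())
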