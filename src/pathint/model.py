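"""Maximum-likelihood fitting of path-integration error models.

`PathIntegrationModel` wraps a behavioral dataset (a tidy per-stop
trial table or prebuilt `TrialArrays`) together with a model variant;
``fit()`` maximizes the marginal log-likelihood over an unconstrained
reparameterization (log scale for the leak rate and all variances) with
seeded multi-start quasi-Newton optimization, and returns a
`PathIntegrationResults` carrying the estimates, their standard errors,
the log-likelihood and information criteria, with ``summary()``,
forward simulation and influence decomposition attached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .ekf import TrialArrays, trial_logliks
from .params import (IntegratorParams, ReportParams, VariantSpec, get_variant,
                     count_params)

__all__ = ["PathIntegrationModel", "PathIntegrationResults", "fit_cohort",
           "fit_group"]

_LOG_FLOOR = np.log(1e-8)   # lower bound for beta and variances (log scale)

# standard initial point: mild leak, unit gain, no bias, moderate noise
_INIT = {"beta": 0.05, "alpha": 1.0, "bias": (0.0, 0.0), "sigma0_sq": 0.1,
         "sigma_d_sq": 0.04, "sigma_phi_sq": 0.04}


def _pack(integ: IntegratorParams, rep: ReportParams | None,
          variant: VariantSpec) -> np.ndarray:
    x = [np.log(max(integ.beta, 1e-8)), integ.alpha]
    if variant.additive_bias_enabled:
        x += [integ.bias[0], integ.bias[1]]
    x.append(np.log(max(integ.sigma0_sq, 1e-8)))
    if variant.report_mode != "none":
        x += [np.log(max(rep.sigma_d_sq, 1e-8)),
              np.log(max(rep.sigma_phi_sq, 1e-8))]
    return np.array(x)


def _unpack(x: np.ndarray, variant: VariantSpec):
    x = np.asarray(x, dtype=float)
    i = 0
    beta = float(np.exp(np.clip(x[i], _LOG_FLOOR, 50))); i += 1
    alpha = float(x[i]); i += 1
    if variant.additive_bias_enabled:
        bias = (float(x[i]), float(x[i + 1])); i += 2
    else:
        bias = (0.0, 0.0)
    s0 = float(np.exp(np.clip(x[i], _LOG_FLOOR, 50))); i += 1
    integ = IntegratorParams(beta=beta, alpha=alpha, bias=bias, sigma0_sq=s0)
    rep = None
    if variant.report_mode != "none":
        rep = ReportParams(
            sigma_d_sq=float(np.exp(np.clip(x[i], _LOG_FLOOR, 50))),
            sigma_phi_sq=float(np.exp(np.clip(x[i + 1], _LOG_FLOOR, 50))))
    return integ, rep


def _param_names(variant: VariantSpec) -> list[str]:
    names = ["beta", "alpha"]
    if variant.additive_bias_enabled:
        names += ["bias_x", "bias_y"]
    names.append("sigma0_sq")
    if variant.report_mode != "none":
        names += ["sigma_d_sq", "sigma_phi_sq"]
    return names


class PathIntegrationModel:
    """A path-integration error model bound to a behavioral dataset.

    Parameters
    ----------
    data
        Tidy per-stop trial table (see `pathint.simulate`) or a
        `TrialArrays`.  Distances should be standardized (verbal-bias
        corrected); the constructor falls back to raw reports.
    variant
        Variant name (e.g. ``"full"``, ``"time"``, ``"full-RN"``) or a
        `VariantSpec`; see `pathint.params.VARIANTS`.
    """

    def __init__(self, data, variant: str | VariantSpec = "full"):
        self.variant = get_variant(variant)
        self.data = data if isinstance(data, TrialArrays) \
            else TrialArrays.from_dataframe(data)
        if self.data.n_obs < 1:
            raise ValueError("dataset has no observed stops")

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame,
                       variant: str | VariantSpec = "full",
                       standard: pd.DataFrame | None = None):
        """Build from a tidy trial table, standardizing distances first
        when a standardization-path table is supplied."""
        if standard is not None:
            from .errors import compute_errors
            trials = compute_errors(trials, standard)
        return cls(trials, variant)

    # -- likelihood ------------------------------------------------------

    def loglike(self, x: np.ndarray) -> float:
        """Total log-likelihood at a packed parameter vector."""
        integ, rep = _unpack(x, self.variant)
        ll = trial_logliks(self.data, integ, rep, self.variant)
        return float(ll.sum())

    def loglike_params(self, integ: IntegratorParams,
                       rep: ReportParams | None = None) -> float:
        return float(trial_logliks(self.data, integ, rep, self.variant).sum())

    def _objective(self, x: np.ndarray) -> float:
        try:
            ll = self.loglike(x)
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    def _start_points(self, restarts: int, seed) -> list[np.ndarray]:
        base = _pack(
            IntegratorParams(beta=_INIT["beta"], alpha=_INIT["alpha"],
                             bias=_INIT["bias"], sigma0_sq=_INIT["sigma0_sq"]),
            ReportParams(_INIT["sigma_d_sq"], _INIT["sigma_phi_sq"]),
            self.variant)
        pts = [base]
        rng = np.random.default_rng(seed)
        names = _param_names(self.variant)
        for _ in range(max(restarts - 1, 0)):
            x = base.copy()
            for j, nm in enumerate(names):
                if nm == "alpha":
                    x[j] += 0.15 * rng.standard_normal()
                elif nm.startswith("bias"):
                    x[j] += 0.05 * rng.standard_normal()
                else:  # log-scale rates/variances
                    x[j] += 1.0 * rng.standard_normal()
            pts.append(x)
        return pts

    # -- fitting ---------------------------------------------------------

    def fit(self, restarts: int = 8, seed: int = 0, method: str = "L-BFGS-B",
            maxiter: int = 500,
            start_params: np.ndarray | None = None) -> "PathIntegrationResults":
        """Maximize the log-likelihood with seeded multi-start.

        Returns the best local optimum across ``restarts`` starts (the
        first start is the standard initial point, the rest are
        dispersed perturbations of it).  ``start_params`` (a packed
        vector, e.g. a previous fit's ``xopt``) replaces the start
        points entirely.
        """
        best = None
        n_ok = 0
        starts = ([np.asarray(start_params, dtype=float)]
                  if start_params is not None
                  else self._start_points(restarts, seed))
        for x0 in starts:
            res = optimize.minimize(self._objective, x0, method=method,
                                    options={"maxiter": maxiter})
            if np.isfinite(res.fun):
                n_ok += 1
                if best is None or res.fun < best.fun:
                    best = res
        if best is None or best.fun >= 1e12:
            warnings.warn("all optimizer starts failed; returning "
                          "non-converged result")
            integ, rep = _unpack(self._start_points(1, seed)[0], self.variant)
            return PathIntegrationResults(
                model=self, integrator=integ, reporter=rep,
                loglik=-np.inf, converged=False, n_restarts_used=restarts,
                seed=seed, xopt=None)
        integ, rep = _unpack(best.x, self.variant)
        return PathIntegrationResults(
            model=self, integrator=integ, reporter=rep, loglik=-best.fun,
            converged=bool(best.success or np.isfinite(best.fun)),
            n_restarts_used=n_ok, seed=seed, xopt=best.x)


@dataclass
class PathIntegrationResults:
    """Fitted parameters, uncertainty, and diagnostics for one dataset."""

    model: PathIntegrationModel
    integrator: IntegratorParams
    reporter: ReportParams | None
    loglik: float
    converged: bool
    n_restarts_used: int
    seed: int
    xopt: np.ndarray | None
    _bse: dict | None = field(default=None, repr=False)

    # -- bookkeeping -----------------------------------------------------

    @property
    def variant(self) -> VariantSpec:
        return self.model.variant

    @property
    def n_obs(self) -> int:
        return self.model.data.n_obs

    @property
    def k(self) -> int:
        return count_params(self.variant, "group", 1)

    @property
    def bic(self) -> float:
        from .selection import bic
        return bic(self.loglik, self.n_obs, self.k)

    @property
    def params(self) -> dict:
        d = {"beta": self.integrator.beta, "alpha": self.integrator.alpha,
             "bias_x": self.integrator.bias[0], "bias_y": self.integrator.bias[1],
             "sigma0_sq": self.integrator.sigma0_sq}
        if self.reporter is not None:
            d["sigma_d_sq"] = self.reporter.sigma_d_sq
            d["sigma_phi_sq"] = self.reporter.sigma_phi_sq
        return d

    def loglik_per_trial(self, per_stop: bool = False):
        return trial_logliks(self.model.data, self.integrator, self.reporter,
                             self.variant, per_stop=per_stop)

    # -- uncertainty -----------------------------------------------------

    @property
    def bse(self) -> dict:
        """Approximate standard errors from the numerical Hessian of the
        log-likelihood at the optimum (delta method back to the natural
        scale for log-parameterized quantities); NaN where the Hessian
        is not usable."""
        if self._bse is None:
            self._bse = self._compute_bse()
        return self._bse

    def _compute_bse(self) -> dict:
        names = _param_names(self.variant)
        free = {"beta", "sigma0_sq", "sigma_d_sq", "sigma_phi_sq"}
        if self.xopt is None:
            return {n: np.nan for n in names}
        x = self.xopt
        k = len(x)
        h = 1e-4
        H = np.zeros((k, k))
        f0 = -self.model._objective(x)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h
                ej = np.zeros(k); ej[j] = h
                fpp = -self.model._objective(x + ei + ej)
                fpm = -self.model._objective(x + ei - ej)
                fmp = -self.model._objective(x - ei + ej)
                fmm = -self.model._objective(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        try:
            cov = np.linalg.inv(-H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            return {n: np.nan for n in names}
        vals = self.params
        out = {}
        for n, s in zip(names, se):
            out[n] = s * vals[n] if n in free else s   # log-scale delta method
        return out

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels."""
        lines = []
        w = 62
        lines.append("Path Integration Error Model".center(w))
        lines.append("=" * w)
        lines.append(f"{'Variant:':<18}{self.variant.name:<20}"
                     f"{'No. trials:':<14}{self.model.data.n_trials}")
        lines.append(f"{'Noise mode:':<18}{self.variant.noise_mode:<20}"
                     f"{'No. obs stops:':<14}{self.n_obs}")
        lines.append(f"{'Report mode:':<18}{self.variant.report_mode:<20}"
                     f"{'Converged:':<14}{self.converged}")
        lines.append(f"{'Log-likelihood:':<18}{self.loglik:<20.3f}"
                     f"{'BIC:':<14}{self.bic:.3f}")
        lines.append("-" * w)
        lines.append(f"{'parameter':<14}{'estimate':>14}{'std err':>14}")
        lines.append("-" * w)
        bse = self.bse
        for n, v in self.params.items():
            s = bse.get(n, np.nan)
            lines.append(f"{n:<14}{v:>14.5g}{s:>14.3g}")
        lines.append("=" * w)
        return "\n".join(lines)

    # -- simulation / decomposition --------------------------------------

    def predict_errors(self, design=None, n_reps: int = 100, seed: int = 0):
        """Model-predicted mean square homing error (see
        `pathint.influence.predict_errors`)."""
        from .influence import predict_errors
        return predict_errors(self.integrator, self.reporter,
                              variant=self.variant, design=design,
                              arrays=self.model.data, n_reps=n_reps, seed=seed)

    def influence(self, n_reps: int = 100, seed: int = 0) -> pd.DataFrame:
        """Relative influence of each parameter on the predicted square
        error (see `pathint.influence`)."""
        from .influence import influence_table
        return influence_table(self, n_reps=n_reps, seed=seed)

    def plot_errors(self, ax=None, n_reps: int = 100, seed: int = 0):
        """Observed vs model-predicted RMS error per stopping point."""
        import matplotlib.pyplot as plt
        from .influence import predict_errors
        if ax is None:
            _, ax = plt.subplots()
        pred = predict_errors(self.integrator, self.reporter, self.variant,
                              arrays=self.model.data, n_reps=n_reps, seed=seed,
                              per_stop=True)
        ax.plot(np.arange(1, 5), np.sqrt(pred), "o-", label="model RMS error")
        ax.set_xlabel("stopping point")
        ax.set_ylabel("error (m)")
        ax.legend()
        return ax


def fit_cohort(trials: pd.DataFrame, variant: str | VariantSpec = "full",
               standard: pd.DataFrame | None = None, restarts: int = 8,
               seed: int = 0) -> dict[str, PathIntegrationResults]:
    """Fit the variant individually for every participant in a tidy table."""
    if standard is not None:
        from .errors import compute_errors
        trials = compute_errors(trials, standard)
    out = {}
    for i, (pid, g) in enumerate(trials.groupby("participant_id")):
        out[pid] = PathIntegrationModel(g, variant).fit(
            restarts=restarts, seed=seed + i)
    return out


def fit_group(trials: pd.DataFrame, variant: str | VariantSpec = "full",
              standard: pd.DataFrame | None = None, restarts: int = 8,
              seed: int = 0) -> PathIntegrationResults:
    """Fit one shared parameter set to all participants pooled (the
    group-level fit)."""
    if standard is not None:
        from .errors import compute_errors
        trials = compute_errors(trials, standard)
    return PathIntegrationModel(trials, get_variant(variant)
                                .with_fit_level("group")).fit(
        restarts=restarts, seed=seed)
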