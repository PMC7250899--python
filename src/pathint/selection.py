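"""Model comparison: BIC, cross-validation schemes, and evidence labels.

All scores are "lower is better" and live on the -2 log-likelihood
scale so BIC and cross-validation numbers are directly comparable.
Likelihoods are evaluated on the common Cartesian report-position scale
(see `pathint.ekf`), which keeps comparisons meaningful across variants
with different observation spaces.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ekf import TrialArrays, trial_logliks
from .model import PathIntegrationModel
from .params import VariantSpec, get_variant

__all__ = [
    "bic",
    "evidence_label",
    "loocv",
    "cv_leave_shape_out",
    "cv_holdout_stop4",
    "compare",
]


def bic(loglik_total: float, n_obs: int, k: int) -> float:
    """Bayesian information criterion: -2 LL + k log(n); lower is better.

    ``n_obs`` counts observed stopping-point reports (each contributes
    one bivariate density term).
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * loglik_total + np.log(n_obs) * k


def evidence_label(delta: float) -> str:
    """Strength-of-evidence bucket for a BIC (or LOOCV) difference."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta > 10:
        return "very strong"
    if delta <= 2:
        return "inconclusive"
    return "positive"


def _as_arrays(dataset) -> TrialArrays:
    return dataset if isinstance(dataset, TrialArrays) \
        else TrialArrays.from_dataframe(dataset)


def _cv_by_folds(arrays: TrialArrays, variant: VariantSpec, fold_ids,
                 restarts: int, seed: int, maxiter: int,
                 warm_start: bool) -> float:
    """Generic held-out -2LL averaged over folds.

    Each fold is refit on the complement of the held-out trials; with
    ``warm_start`` every fold's optimizer starts at the full-dataset
    optimum (fast; fold fits remain separate optimizations), otherwise
    each fold multi-starts from the standard initial point.  Folds with
    non-converged fits are skipped with a warning.
    """
    fold_ids = np.asarray(fold_ids)
    folds = pd.unique(fold_ids)
    x_full = None
    if warm_start:
        full = PathIntegrationModel(arrays, variant).fit(
            restarts=max(restarts, 4), seed=seed)
        x_full = full.xopt
    scores = []
    for i, f in enumerate(folds):
        test = fold_ids == f
        train = ~test
        if train.sum() == 0:
            raise ValueError("cross-validation fold leaves no training data")
        model = PathIntegrationModel(arrays.subset(np.where(train)[0]), variant)
        res = model.fit(restarts=restarts, seed=seed + i, maxiter=maxiter,
                        start_params=x_full)
        if not res.converged or not np.isfinite(res.loglik):
            warnings.warn(f"fold {f!r}: fit did not converge; fold skipped")
            continue
        ll = trial_logliks(arrays.subset(np.where(test)[0]), res.integrator,
                           res.reporter, variant).sum()
        scores.append(-2.0 * float(ll))
    if not scores:
        raise RuntimeError("no cross-validation fold converged")
    return float(np.mean(scores))


def loocv(dataset, variant: str | VariantSpec = "full", restarts: int = 1,
          seed: int = 0, maxiter: int = 300, warm_start: bool = True) -> float:
    """Leave-one-trajectory-out CV score: -(2/T) sum of held-out LLs.

    One fold per trial; each fold is a separate optimization on the
    T-1 remaining trials (warm-started at the full-data optimum by
    default).
    """
    arrays = _as_arrays(dataset)
    if arrays.n_trials < 2:
        raise ValueError("LOOCV needs at least 2 trajectories")
    return _cv_by_folds(arrays, get_variant(variant),
                        np.arange(arrays.n_trials), restarts, seed, maxiter,
                        warm_start)


def cv_leave_shape_out(dataset, variant: str | VariantSpec = "full",
                       restarts: int = 1, seed: int = 0,
                       maxiter: int = 300, warm_start: bool = True) -> float:
    """CV folding by path shape: test on all trials of the held-out path."""
    arrays = _as_arrays(dataset)
    if arrays.trial_key is None or arrays.trial_key["path_id"].nunique() < 2:
        raise ValueError("leave-shape-out needs >= 2 distinct path shapes")
    return _cv_by_folds(arrays, get_variant(variant),
                        arrays.trial_key["path_id"].to_numpy(),
                        restarts, seed, maxiter, warm_start)


def cv_holdout_stop4(dataset, variant: str | VariantSpec = "full",
                     restarts: int = 4, seed: int = 0,
                     maxiter: int = 500):
    """Train with final-stop observations masked; score -2LL of the
    stop-4 terms only.  Returns ``(test_score, train_score)`` per
    observed stop, for the train-vs-test overfitting check."""
    arrays = _as_arrays(dataset)
    variant = get_variant(variant)
    masked = arrays.masked_stop4()
    if masked.n_obs < 1:
        raise ValueError("no observations left after masking stop 4")
    res = PathIntegrationModel(masked, variant).fit(restarts=restarts, seed=seed)
    if not np.isfinite(res.loglik):
        raise RuntimeError("holdout training fit failed")
    per_stop = trial_logliks(arrays, res.integrator, res.reporter, variant,
                             per_stop=True)
    test_mask = arrays.obs[:, 3]
    test = -2.0 * per_stop[:, 3][test_mask].mean()
    train_n = masked.obs.sum()
    train = -2.0 * per_stop[:, :3][masked.obs[:, :3]].sum() / max(train_n, 1)
    return float(test), float(train)


def compare(dataset, variants=("full", "time"), restarts: int = 6, seed: int = 0,
            include_loocv: bool = False, loocv_restarts: int = 1) -> pd.DataFrame:
    """Fit several variants to one dataset and tabulate BIC (and
    optionally LOOCV) with deltas against the best variant."""
    arrays = _as_arrays(dataset)
    rows = []
    for v in variants:
        spec = get_variant(v)
        res = PathIntegrationModel(arrays, spec).fit(restarts=restarts, seed=seed)
        row = {"variant": spec.name, "loglik": res.loglik, "k": res.k,
               "n_obs": res.n_obs, "bic": res.bic, "converged": res.converged}
        if include_loocv:
            row["loocv"] = loocv(arrays, spec, restarts=loocv_restarts, seed=seed)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("variant")
    df["delta_bic"] = df["bic"] - df["bic"].min()
    df["evidence"] = [evidence_label(d) for d in df["delta_bic"]]
    if include_loocv:
        df["delta_loocv"] = df["loocv"] - df["loocv"].min()
    return df
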