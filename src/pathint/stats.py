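"""Nonparametric group comparisons and ancillary behavioral analyses.

The workhorse is a one-sided permutation test on the difference of
group means (10,000 label shuffles by default, add-one p-value
estimator so p is never exactly zero); on top of it sit the trimmed
group comparison, the stopping-vs-non-stopping contrast at the final
stop, and the angular-velocity median split.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .errors import angular_speed

__all__ = [
    "permutation_test",
    "trimmed_group_comparison",
    "stopping_vs_nonstopping",
    "angular_velocity_median_split",
]


def _stat(a, b):
    return float(np.mean(a) - np.mean(b))


def permutation_test(values_a, values_b, n_perm: int = 10_000,
                     alternative: str = "greater", seed: int = 0,
                     exhaustive: bool = False) -> float:
    """Permutation test on the difference of group means.

    ``alternative='greater'`` tests mean(a) > mean(b).  The Monte-Carlo
    p-value uses the add-one estimator (1 + #{extreme}) / (1 + n_perm);
    with ``exhaustive=True`` all label assignments are enumerated and
    the exact p-value (including the observed assignment) is returned.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    obs = _stat(a, b)
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size

    def extreme(stat):
        if alternative == "greater":
            return stat >= obs
        if alternative == "less":
            return stat <= obs
        return abs(stat) >= abs(obs)

    if exhaustive:
        hits = total = 0
        for idx in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            total += 1
            hits += extreme(_stat(pooled[mask], pooled[~mask]))
        return hits / total

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        hits += extreme(_stat(pooled[perm[:na]], pooled[perm[na:]]))
    return (1 + hits) / (1 + n_perm)


def trimmed_group_comparison(values_a, values_b, trim_fraction: float = 0.1,
                             mode: str = "both-tails-both-groups",
                             n_perm: int = 10_000, alternative: str = "greater",
                             seed: int = 0) -> float:
    """Permutation test after trimming extreme-performing participants.

    Participants are ranked by their summary error (stable sort);
    ``both-tails-both-groups`` drops the best- and worst-performing
    fraction from each group, ``worst-older-only`` drops only the worst
    fraction of group a (the comparison's putatively worse group).
    """
    if mode not in ("both-tails-both-groups", "worst-older-only"):
        raise ValueError(f"unknown mode {mode!r}")

    def trim(v, both_tails: bool):
        v = np.asarray(v, dtype=float)
        k = int(np.floor(trim_fraction * v.size))
        if k == 0:
            return v
        order = np.argsort(v, kind="stable")
        keep = order[:-k] if not both_tails else order[k:-k]
        if keep.size == 0:
            raise ValueError("trimming empties a group")
        return v[keep]

    if mode == "both-tails-both-groups":
        a = trim(values_a, True)
        b = trim(values_b, True)
    else:
        a = trim(values_a, False)
        b = np.asarray(values_b, dtype=float)
    return permutation_test(a, b, n_perm=n_perm, alternative=alternative,
                            seed=seed)


def stopping_vs_nonstopping(errors: pd.DataFrame, n_perm: int = 10_000,
                            alternative: str = "two-sided",
                            seed: int = 0) -> pd.DataFrame:
    """Final-stop absolute error in trials with vs without intermediate
    stops, per group.

    Returns one row per group with mean +/- SEM for each condition, the
    mean difference (with - without), and a permutation p-value over
    trials.
    """
    final = errors[(errors["stop_index"] == 4) & errors["err_abs"].notna()]
    if final["with_stops"].nunique() < 2:
        raise ValueError("dataset needs trials both with and without stops")
    rows = []
    for group, g in final.groupby("group"):
        w = g.loc[g["with_stops"], "err_abs"].to_numpy()
        wo = g.loc[~g["with_stops"].astype(bool), "err_abs"].to_numpy()
        p = permutation_test(w, wo, n_perm=n_perm, alternative=alternative,
                             seed=seed)
        rows.append({
            "group": group,
            "n_with": w.size, "n_without": wo.size,
            "mean_with": w.mean(), "sem_with": w.std(ddof=1) / np.sqrt(w.size),
            "mean_without": wo.mean(),
            "sem_without": wo.std(ddof=1) / np.sqrt(wo.size),
            "difference": w.mean() - wo.mean(),
            "p_value": p,
        })
    return pd.DataFrame(rows)


def angular_velocity_median_split(errors: pd.DataFrame, n_perm: int = 2_000,
                                  alternative: str = "two-sided",
                                  seed: int = 0):
    """Within-participant median split of segments by angular speed.

    Each observed stop's incremental error is assigned to the high or
    low angular-speed half of that participant's segments (ties at the
    median go to the low half); returns per-participant means and a
    pooled permutation test of high vs low.
    """
    # restrict to trials with intermediate stops so every segment has a
    # report and the chord geometry is complete
    df = errors[errors["err_inc"].notna()]
    if "with_stops" in df.columns:
        df = df[df["with_stops"].astype(bool)]
    df = df.copy()
    rows = []
    for pid, g in df.groupby("participant_id"):
        segs = []
        for _, t in g.groupby(["block", "trial_index"]):
            t = t.sort_values("stop_index")
            ang = angular_speed(t)
            for (idx, row), a in zip(t.iterrows(), ang):
                segs.append((a, row["err_inc"]))
        if len(segs) < 2:
            continue
        a = np.array([s[0] for s in segs])
        e = np.array([s[1] for s in segs])
        med = np.median(a)
        high = a > med
        rows.append({"participant_id": pid,
                     "mean_err_high": e[high].mean() if high.any() else np.nan,
                     "mean_err_low": e[~high].mean() if (~high).any() else np.nan,
                     "n_high": int(high.sum()), "n_low": int((~high).sum())})
    per = pd.DataFrame(rows).dropna()
    p = permutation_test(per["mean_err_high"], per["mean_err_low"],
                         n_perm=n_perm, alternative=alternative, seed=seed)
    return per, p
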