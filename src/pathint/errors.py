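"""From raw reports to standardized path-integration errors.

Verbal distance reports are corrected for each participant's
multiplicative verbal bias using the straight standardization paths
(f_corr = d_correct / d_response, one factor per distance band and
block half), converted with the reported homing angle into a "presumed
starting point", and scored as the absolute error (distance from the
true start) and the incremental error (distance from the previously
presumed start, isolating the latest segment's contribution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import wrap_angle

BAND_EDGES = (4.0, 8.0)   # [0,4) short, [4,8) middle, [8,inf) long
BAND_LENGTHS = {2.0: "short", 6.0: "middle", 10.0: "long"}

__all__ = [
    "CorrectionFactors",
    "correction_factors",
    "correction_factor_table",
    "standardize_distance",
    "presumed_start",
    "absolute_error",
    "incremental_error",
    "compute_errors",
    "shuffled_baseline",
    "walking_speed",
    "angular_speed",
]


@dataclass(frozen=True)
class CorrectionFactors:
    f_short: float
    f_middle: float
    f_long: float
    block_half: tuple[int, int] | None = None   # (block, half) identifier

    def factor_for(self, verbal_distance_m: float) -> float:
        if verbal_distance_m < BAND_EDGES[0]:
            return self.f_short
        if verbal_distance_m < BAND_EDGES[1]:
            return self.f_middle
        return self.f_long


def correction_factors(standardization_responses, block_half=None) -> CorrectionFactors:
    """Correction factors from one standardization triplet.

    ``standardization_responses`` maps true length (2, 6, 10) to the
    verbal response in meters.  Nonpositive responses are rejected and
    the affected band's factor falls back to 1 with a warning.
    """
    factors = {}
    for L, name in BAND_LENGTHS.items():
        resp = standardization_responses.get(L)
        if resp is None or not np.isfinite(resp) or resp <= 0:
            warnings.warn(
                f"standardization response for {L} m path unusable ({resp!r}); "
                "falling back to factor 1")
            factors[name] = 1.0
        else:
            factors[name] = L / float(resp)
    return CorrectionFactors(factors["short"], factors["middle"],
                             factors["long"], block_half=block_half)


def correction_factor_table(standard_df: pd.DataFrame) -> pd.DataFrame:
    """Per participant x block x half correction factors from the
    standardization table (columns participant_id, block, half,
    true_length_m, response_m)."""
    rows = []
    for (pid, block, half), g in standard_df.groupby(
            ["participant_id", "block", "half"]):
        responses = dict(zip(g["true_length_m"], g["response_m"]))
        cf = correction_factors(responses, block_half=(int(block), int(half)))
        rows.append({"participant_id": pid, "block": int(block), "half": int(half),
                     "f_short": cf.f_short, "f_middle": cf.f_middle,
                     "f_long": cf.f_long})
    return pd.DataFrame(rows)


def standardize_distance(verbal_distance_m, factors: CorrectionFactors):
    """Multiply a verbal response by the correction factor of its band."""
    v = np.atleast_1d(np.asarray(verbal_distance_m, dtype=float))
    if np.any(v[np.isfinite(v)] < 0):
        raise ValueError("verbal distances must be >= 0")
    f = np.array([factors.factor_for(x) if np.isfinite(x) else np.nan for x in v])
    out = v * f
    return out if np.ndim(verbal_distance_m) else float(out[0])


def presumed_start(stop_xy, standardized_distance, reported_angle):
    """Project the report from the stop back toward the presumed start.

    ``reported_angle`` is the world-frame homing direction in radians.
    """
    stop_xy = np.asarray(stop_xy, dtype=float)
    d = np.asarray(standardized_distance, dtype=float)
    a = np.asarray(reported_angle, dtype=float)
    return stop_xy + np.stack([d * np.cos(a), d * np.sin(a)], axis=-1)


def absolute_error(presumed, true_start):
    """Euclidean distance between presumed and true starting point."""
    return np.linalg.norm(np.asarray(presumed, float) - np.asarray(true_start, float),
                          axis=-1)


def incremental_error(presumed, previous_presumed):
    """Distance between consecutive presumed starts: the error added by
    the latest segment only (at stop 1 the previous presumed start is
    the true start, so Err_inc = Err_abs there)."""
    return np.linalg.norm(
        np.asarray(presumed, float) - np.asarray(previous_presumed, float), axis=-1)


def _with_factors(trials: pd.DataFrame, standard: pd.DataFrame | None) -> pd.DataFrame:
    df = trials.copy()
    df["half"] = np.where(df["trial_index"] <= 8, 1, 2)
    if standard is None:
        df["standardized_distance_m"] = df["reported_distance_m"]
        return df
    # block halves map onto the standardization triplet of the same half
    fac = correction_factor_table(standard)
    # sessions beyond the first reuse block 1-3 factors cyclically
    df["_std_block"] = ((df["block"] - 1) % 3) + 1
    df = df.merge(fac, left_on=["participant_id", "_std_block", "half"],
                  right_on=["participant_id", "block", "half"],
                  suffixes=("", "_fac"), how="left")
    v = df["reported_distance_m"].to_numpy()
    f = np.where(v < BAND_EDGES[0], df["f_short"],
                 np.where(v < BAND_EDGES[1], df["f_middle"], df["f_long"]))
    df["standardized_distance_m"] = v * f
    df = df.drop(columns=["_std_block", "block_fac", "f_short", "f_middle", "f_long"],
                 errors="ignore")
    return df


def compute_errors(trials: pd.DataFrame,
                   standard: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-stop error table from a tidy trial table.

    Adds standardized distances (if a standardization table is given),
    presumed starting points, and absolute/incremental errors.  Rows
    without a report keep NaN errors.
    """
    df = _with_factors(trials, standard)
    ang = np.deg2rad(df["reported_angle_deg"].to_numpy())
    stop_xy = df[["true_x", "true_y"]].to_numpy()
    pres = presumed_start(stop_xy, df["standardized_distance_m"].to_numpy(), ang)
    df["presumed_x"] = pres[:, 0]
    df["presumed_y"] = pres[:, 1]
    df["err_abs"] = absolute_error(pres, np.zeros(2))
    # incremental: previous *observed* presumed start within the trial
    err_inc = np.full(len(df), np.nan)
    pos = {idx: i for i, idx in enumerate(df.index)}
    order = df.sort_values(["participant_id", "block", "trial_index", "stop_index"])
    for _, g in order.groupby(["participant_id", "block", "trial_index"], sort=False):
        prev = np.zeros(2)
        for idx in g.index:
            i = pos[idx]
            if np.all(np.isfinite(pres[i])):
                err_inc[i] = np.linalg.norm(pres[i] - prev)
                prev = pres[i]
    df["err_inc"] = err_inc
    return df


def shuffled_baseline(errors: pd.DataFrame, n_shuffles: int = 100, seed: int = 0,
                      pool: str = "participant"):
    """Mean absolute error under response shuffling.

    Responses (standardized distance, angle) are permuted across trials
    within the same stopping point and, by default, the same participant
    (``pool='all'`` shuffles across participants too), then re-projected
    from each trial's true stop.  Returns ``(observed, shuffled)``:
    observed mean error per stop, and an (n_shuffles, n_stops) array of
    shuffled means.
    """
    rng = np.random.default_rng(seed)
    df = errors.dropna(subset=["standardized_distance_m", "reported_angle_deg"])
    stops = sorted(df["stop_index"].unique())
    observed = df.groupby("stop_index")["err_abs"].mean().reindex(stops).to_numpy()
    if n_shuffles == 0:
        return observed, np.empty((0, len(stops)))
    keys = ["stop_index"] if pool == "all" else ["participant_id", "stop_index"]
    out = np.full((n_shuffles, len(stops)), np.nan)
    groups = []
    for key, g in df.groupby(keys):
        if len(g) < 2:
            warnings.warn(f"stratum {key} has < 2 trials; skipped in shuffling")
            continue
        groups.append(g)
    for k in range(n_shuffles):
        per_stop_sums = {s: [0.0, 0] for s in stops}
        for g in groups:
            perm = rng.permutation(len(g))
            d = g["standardized_distance_m"].to_numpy()[perm]
            a = np.deg2rad(g["reported_angle_deg"].to_numpy()[perm])
            pres = presumed_start(g[["true_x", "true_y"]].to_numpy(), d, a)
            errs = np.linalg.norm(pres, axis=1)
            s = int(g["stop_index"].iloc[0]) if len(set(g["stop_index"])) == 1 else None
            if s is None:
                for si, e in zip(g["stop_index"], errs):
                    per_stop_sums[int(si)][0] += e
                    per_stop_sums[int(si)][1] += 1
            else:
                per_stop_sums[s][0] += errs.sum()
                per_stop_sums[s][1] += len(errs)
        out[k] = [per_stop_sums[s][0] / per_stop_sums[s][1]
                  if per_stop_sums[s][1] else np.nan for s in stops]
    return observed, out


def walking_speed(trial_rows: pd.DataFrame) -> np.ndarray:
    """Cumulative traveled distance / cumulative elapsed time at each stop
    of one trial (rows ordered by stop_index)."""
    arc = trial_rows.get("seg_arc_m", trial_rows["seg_length_m"]).to_numpy()
    dur = trial_rows["seg_duration_s"].to_numpy()
    if np.any(dur <= 0):
        raise ValueError("segment durations must be > 0")
    return np.cumsum(arc) / np.cumsum(dur)


def angular_speed(trial_rows: pd.DataFrame) -> np.ndarray:
    """Unsigned heading change per segment divided by its duration (deg/s).

    Headings are taken from the stop-to-stop chords; the initial heading
    is along +x.
    """
    dx = np.diff(np.vstack([[0.0, 0.0], trial_rows[["true_x", "true_y"]].to_numpy()]),
                 axis=0)
    dur = trial_rows["seg_duration_s"].to_numpy()
    if np.any(dur <= 0):
        raise ValueError("segment durations must be > 0")
    headings = np.arctan2(dx[:, 1], dx[:, 0])
    turns = np.abs(wrap_angle(np.diff(np.concatenate([[0.0], headings]))))
    return np.rad2deg(turns) / dur
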