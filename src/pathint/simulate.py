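"""Forward simulation of behavioral datasets with known ground truth.

The generator walks an agent along the task's curved paths, evolves its
internal position estimate with the exact Ornstein-Uhlenbeck segment
transitions (never Euler steps), corrupts the homing-vector reports with
reporting noise, applies a multiplicative verbal distance bias, and
emits tidy tables shaped like the behavioral data of the study design
(plus the standardization-path responses needed to undo the verbal
bias).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .params import IntegratorParams, ReportParams
from . import ou
from .task import (CurvedPath, SessionDesign, make_paths, make_session_design,
                   STANDARDIZATION_LENGTHS)

__all__ = [
    "GenerativeAgent",
    "GroupSpec",
    "DEFAULT_GROUP_SPECS",
    "TrialRecord",
    "simulate_internal_estimates",
    "simulate_reports",
    "apply_verbal_bias",
    "bias_band",
    "simulate_trial",
    "simulate_standardization",
    "simulate_participant",
    "simulate_cohort",
    "wrap_angle",
]


def wrap_angle(phi):
    """Wrap angles to (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    out = -(np.mod(-phi + np.pi, 2.0 * np.pi) - np.pi)
    return out


@dataclass(frozen=True)
class GenerativeAgent:
    """Ground-truth parameter bundle for one simulated participant.

    ``integrator`` is interpreted in the scaling of the simulation mode
    (per meter for distance mode, per second for time mode).
    ``verbal_bias_factors`` are the multiplicative verbal biases of the
    short/middle/long distance bands: the verbal response equals the
    internally reported distance divided by the band's factor, so the
    standardization correction factor recovers it.
    """

    integrator: IntegratorParams = field(default_factory=IntegratorParams)
    reporter: ReportParams = field(default_factory=ReportParams)
    report_mode: str = "weber"                    # weber | constant | none
    verbal_bias_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)
    walking_speed_mean: float = 0.5               # m/s
    walking_speed_sd: float = 0.05
    pause_mean: float = 17.8                      # s spent reporting at a stop
    pause_sd: float = 4.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.verbal_bias_factors):
            raise ValueError("verbal bias factors must be > 0")
        if self.walking_speed_mean <= 0:
            raise ValueError("walking speed mean must be > 0")


def bias_band(distance_m: float) -> int:
    """Distance band index: [0,4) short, [4,8) middle, >=8 long."""
    if distance_m < 4.0:
        return 0
    if distance_m < 8.0:
        return 1
    return 2


@dataclass
class TrialRecord:
    """One trial: segments between stops, true stops, and reports."""

    path_id: str
    with_stops: bool
    block: int
    index: int                    # within-block trial index (1-based)
    seg_dx: np.ndarray            # (4, 2) chord displacement per segment
    seg_len: np.ndarray           # (4,) chord lengths |dx|
    seg_arc: np.ndarray           # (4,) traveled arc length per segment
    seg_dur: np.ndarray           # (4,) elapsed time per segment (incl. pauses)
    stop_positions: np.ndarray    # (4, 2) true stop coordinates
    reported_distance: np.ndarray  # (4,) m, NaN where no report
    reported_angle: np.ndarray     # (4,) rad, NaN where no report
    verbal_distance: np.ndarray    # (4,) m, bias-corrupted verbal response

    def __post_init__(self) -> None:
        assert self.seg_dx.shape == (4, 2)
        np.testing.assert_allclose(
            self.seg_len, np.linalg.norm(self.seg_dx, axis=1), atol=1e-9)
        if np.any(self.seg_dur <= 0):
            raise ValueError("segment durations must be > 0")


def _segments(path: CurvedPath):
    stops = path.stop_positions
    pts = np.vstack([np.zeros(2), stops])
    dx = np.diff(pts, axis=0)
    arcs = np.diff(np.concatenate([[0.0], path.arc_lengths_to_stops]))
    return dx, arcs


def simulate_internal_estimates(path: CurvedPath, agent: GenerativeAgent,
                                mode: str = "distance",
                                seed=None, durations=None, pauses=None):
    """Sample the internal position estimate at the 4 stops of ``path``.

    Each segment transition is drawn from the exact Gaussian OU kernel
    in the requested scaling (``distance``, ``time``, or ``constant``
    for stop-to-stop independent estimates around the mean chain).  In
    distance mode the estimate does not diffuse while the agent stands
    at a stop; in time mode each pause is an extra zero-velocity
    transition of the pause duration.

    Returns ``(xhat, durations)`` with ``xhat`` of shape (4, 2) and
    ``durations`` the total elapsed time per segment (movement plus the
    pause preceding it).
    """
    rng = np.random.default_rng(seed)
    dx, arcs = _segments(path)
    params = agent.integrator
    if durations is None:
        speeds = np.maximum(
            rng.normal(agent.walking_speed_mean, agent.walking_speed_sd, size=4),
            0.2 * agent.walking_speed_mean)
        move = arcs / speeds
    else:
        move = np.asarray(durations, dtype=float)
    if pauses is None:
        pauses = np.zeros(4)
    pauses = np.asarray(pauses, dtype=float)  # pause before each segment

    x = np.zeros(2)
    mu = np.zeros(2)   # deterministic mean chain (constant-noise mode)
    xhat = np.zeros((4, 2))
    for s in range(4):
        if mode == "distance":
            mean, var = ou.propagate_distance(x, dx[s], params)
        elif mode == "constant":
            # stop-to-stop independent estimates around the mean chain
            mu, var = ou.propagate_constant_noise(mu, dx[s], params)
            mean = mu
        elif mode == "time":
            if pauses[s] > 0:
                m0, v0 = ou.propagate_time(x, np.zeros(2), pauses[s], params)
                x = m0 + np.sqrt(v0) * rng.standard_normal(2)
            mean, var = ou.propagate_time(x, dx[s], move[s], params)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        x = mean + np.sqrt(var) * rng.standard_normal(2)
        xhat[s] = x
    return xhat, move + pauses


def simulate_reports(xhat, start_xy, reporter: ReportParams,
                     mode: str = "weber", seed=None):
    """Corrupt internal homing vectors into distance/angle reports.

    Weber mode draws ``d_hat = exp(log d + sigma_d eta)`` (log-normal,
    error magnitude growing with d); constant mode adds Gaussian noise
    of fixed size to d.  Angles get additive Gaussian noise and are
    wrapped to (-pi, pi].
    """
    rng = np.random.default_rng(seed)
    xhat = np.atleast_2d(np.asarray(xhat, dtype=float))
    rel = xhat - np.asarray(start_xy, dtype=float)
    d = np.linalg.norm(rel, axis=1)
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    sd = np.sqrt(reporter.sigma_d_sq)
    sphi = np.sqrt(reporter.sigma_phi_sq)
    if mode == "weber":
        if np.any(d <= 0):
            raise ValueError("degenerate trial: internal estimate at the start "
                             "point (log-distance undefined)")
        d_hat = np.exp(np.log(d) + sd * rng.standard_normal(d.shape))
    elif mode == "constant":
        d_hat = d + sd * rng.standard_normal(d.shape)
    elif mode == "none":
        d_hat = d.copy()
    else:
        raise ValueError(f"unknown report mode {mode!r}")
    phi_hat = wrap_angle(phi + sphi * rng.standard_normal(phi.shape))
    return d_hat, phi_hat


def apply_verbal_bias(reported_distance, agent: GenerativeAgent):
    """Divide the internal report by the verbal bias factor of its band.

    The standardization correction multiplies the verbal response by the
    recovered factor, undoing this corruption.
    """
    rep = np.atleast_1d(np.asarray(reported_distance, dtype=float))
    out = np.empty_like(rep)
    for i, d in enumerate(rep):
        out[i] = d / agent.verbal_bias_factors[bias_band(d)] if np.isfinite(d) else d
    return out


def simulate_trial(path: CurvedPath, agent: GenerativeAgent, *, with_stops: bool,
                   block: int, index: int, mode: str = "distance",
                   rng=None) -> TrialRecord:
    rng = np.random.default_rng(rng)
    pauses = np.zeros(4)
    if with_stops:
        # reporting pauses follow stops 1-3, i.e. precede segments 2-4
        pauses[1:] = np.maximum(rng.normal(agent.pause_mean, agent.pause_sd, size=3), 1.0)
    xhat, durations = simulate_internal_estimates(
        path, agent, mode=mode, seed=rng, pauses=pauses)
    dx, arcs = _segments(path)
    observed = np.array([with_stops, with_stops, with_stops, True])
    d_hat = np.full(4, np.nan)
    phi_hat = np.full(4, np.nan)
    d_hat[observed], phi_hat[observed] = simulate_reports(
        xhat[observed], (0.0, 0.0), agent.reporter, mode=agent.report_mode, seed=rng)
    verbal = apply_verbal_bias(d_hat, agent)
    return TrialRecord(
        path_id=path.path_id, with_stops=with_stops, block=block, index=index,
        seg_dx=dx, seg_len=np.linalg.norm(dx, axis=1), seg_arc=arcs,
        seg_dur=durations, stop_positions=path.stop_positions,
        reported_distance=d_hat, reported_angle=phi_hat, verbal_distance=verbal)


def simulate_standardization(agent: GenerativeAgent, rng=None) -> pd.DataFrame:
    """Verbal responses on the 6 standardization triplets of a session.

    Each straight path of true length L yields a Weber-noised internal
    report divided by the verbal bias factor of L's band.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for block in range(1, 4):
        for half in (1, 2):
            for L in STANDARDIZATION_LENGTHS:
                d_hat, _ = simulate_reports(
                    np.array([[L, 0.0]]), (0.0, 0.0), agent.reporter,
                    mode=agent.report_mode, seed=rng)
                verbal = float(d_hat[0] / agent.verbal_bias_factors[bias_band(L)])
                rows.append({"block": block, "half": half,
                             "true_length_m": L, "response_m": verbal})
    return pd.DataFrame(rows)


def _trial_rows(rec: TrialRecord, participant_id: str, group: str):
    rows = []
    for s in range(4):
        rows.append({
            "participant_id": participant_id,
            "group": group,
            "block": rec.block,
            "trial_index": rec.index,
            "path_id": rec.path_id,
            "stop_index": s + 1,
            "with_stops": rec.with_stops,
            "true_x": rec.stop_positions[s, 0],
            "true_y": rec.stop_positions[s, 1],
            "seg_length_m": rec.seg_len[s],
            "seg_arc_m": rec.seg_arc[s],
            "seg_duration_s": rec.seg_dur[s],
            "reported_distance_m": rec.verbal_distance[s],
            # I/O convention: the responded homing orientation (stop -> start),
            # i.e. the internal polar angle rotated by pi
            "reported_angle_deg": np.rad2deg(wrap_angle(rec.reported_angle[s] + np.pi)),
        })
    return rows


def simulate_participant(agent: GenerativeAgent, paths: list[CurvedPath],
                         design: SessionDesign, participant_id: str = "S01",
                         group: str = "young", mode: str = "distance",
                         rng=None, n_sessions: int = 1):
    """Simulate all trials of one participant.

    Returns ``(trials_df, standardization_df)``.  ``reported_distance_m``
    in the trial table is the *verbal* (bias-corrupted) response; the
    error-metrics pipeline recovers the standardized distance.
    """
    rng = np.random.default_rng(rng)
    by_id = {p.path_id: p for p in paths}
    rows = []
    for sess in range(n_sessions):
        for b, block in enumerate(design.blocks, start=1):
            for i, spec in enumerate(block, start=1):
                rec = simulate_trial(
                    by_id[spec.path_id], agent, with_stops=spec.with_stops,
                    block=3 * sess + b, index=i, mode=mode, rng=rng)
                rows.extend(_trial_rows(rec, participant_id, group))
    trials = pd.DataFrame(rows)
    standard = simulate_standardization(agent, rng=rng)
    standard.insert(0, "participant_id", participant_id)
    standard.insert(1, "group", group)
    return trials, standard


@dataclass(frozen=True)
class GroupSpec:
    """Population distribution over agent parameters for one age group.

    Positive rate/variance parameters scatter log-normally between
    participants (multiplicative sd ``rate_spread``); the gain and bias
    components scatter normally.
    """

    agent: GenerativeAgent
    rate_spread: float = 0.2
    alpha_sd: float = 0.05
    bias_sd: float = 0.02

    def draw(self, rng: np.random.Generator) -> GenerativeAgent:
        base = self.agent
        p = base.integrator
        ln = lambda v: v * np.exp(self.rate_spread * rng.standard_normal()) if v > 0 else v
        integ = IntegratorParams(
            beta=ln(p.beta),
            alpha=p.alpha + self.alpha_sd * rng.standard_normal(),
            bias=(p.bias[0] + self.bias_sd * rng.standard_normal(),
                  p.bias[1] + self.bias_sd * rng.standard_normal()),
            sigma0_sq=ln(p.sigma0_sq))
        rep = ReportParams(sigma_d_sq=ln(base.reporter.sigma_d_sq),
                           sigma_phi_sq=ln(base.reporter.sigma_phi_sq))
        factors = tuple(ln(f) for f in base.verbal_bias_factors)
        return replace(base, integrator=integ, reporter=rep,
                       verbal_bias_factors=factors)


#: Study-condition defaults: the dominant error source is accumulating
#: noise (larger in the older group), with a modest velocity-gain bias,
#: small leak and additive bias, Weber reporting noise, and stronger
#: verbal distance under-reporting in older adults.
DEFAULT_GROUP_SPECS: dict[str, GroupSpec] = {
    "young": GroupSpec(GenerativeAgent(
        integrator=IntegratorParams(beta=0.01, alpha=1.10,
                                    bias=(0.02, -0.01), sigma0_sq=0.15),
        reporter=ReportParams(sigma_d_sq=0.0625, sigma_phi_sq=0.04),
        verbal_bias_factors=(1.10, 1.05, 1.00))),
    "old": GroupSpec(GenerativeAgent(
        integrator=IntegratorParams(beta=0.03, alpha=1.15,
                                    bias=(0.05, -0.02), sigma0_sq=0.30),
        reporter=ReportParams(sigma_d_sq=0.09, sigma_phi_sq=0.0625),
        verbal_bias_factors=(1.30, 1.20, 1.10))),
}


def _agent_truth(agent: GenerativeAgent) -> dict:
    d = asdict(agent)
    return d


def simulate_cohort(n_young: int, n_old: int,
                    group_param_specs: dict[str, GroupSpec] | None = None,
                    design: SessionDesign | None = None, seed: int = 0,
                    paths: list[CurvedPath] | None = None,
                    mode: str = "distance"):
    """Simulate a two-group cohort.

    Returns ``(trials_df, standardization_df, truth)`` where ``truth``
    maps participant ids to their generating agent parameters (for
    parameter-recovery tests).  The same paths and trial order are used
    for every participant, as in the study design.
    """
    specs = group_param_specs or DEFAULT_GROUP_SPECS
    rng = np.random.default_rng(seed)
    if paths is None:
        paths = make_paths(int(rng.integers(2**31 - 1)))
    if design is None:
        design = make_session_design(int(rng.integers(2**31 - 1)))
    trial_frames, std_frames, truth = [], [], {}
    counts = [("young", n_young), ("old", n_old)]
    for group, n in counts:
        for i in range(n):
            pid = f"{group[0].upper()}{i + 1:03d}"
            agent = specs[group].draw(rng)
            t, s = simulate_participant(
                agent, paths, design, participant_id=pid, group=group,
                mode=mode, rng=rng)
            trial_frames.append(t)
            std_frames.append(s)
            truth[pid] = _agent_truth(agent)
    trials = pd.concat(trial_frames, ignore_index=True)
    standard = pd.concat(std_frames, ignore_index=True)
    return trials, standard, truth


def save_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
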