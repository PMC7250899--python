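"""Construction of the path-integration task: curved paths and session design.

The task guides a participant along four-legged curved paths built from
leg lengths in {2, 3.5, 5, 6.5} m and turn angles of {55, 80, 105}
degrees (left or right).  The four-legged skeleton is smoothed into a
corner-free curve with a natural cubic spline through the turning
points.  A session consists of 3 blocks of 16 trials: each of the 10
paths once with intermediate stops, plus paths 1-6 once more with a
report only at the path's end.  Straight standardization paths of
10, 2 and 6 m (in that order) follow the 4th and 12th trial of a block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

ALLOWED_LEGS = (2.0, 3.5, 5.0, 6.5)
ALLOWED_ANGLES = (55.0, 80.0, 105.0)
STANDARDIZATION_LENGTHS = (10.0, 2.0, 6.0)  # presented in this order
N_PATHS = 10
ARENA_WIDTH = 10.0   # m, tracking-area footprint the curve must fit in
ARENA_HEIGHT = 8.0

__all__ = [
    "PathSkeleton",
    "CurvedPath",
    "TrialSpec",
    "SessionDesign",
    "build_skeleton",
    "interpolate_curved_path",
    "make_paths",
    "make_session_design",
    "ALLOWED_LEGS",
    "ALLOWED_ANGLES",
    "STANDARDIZATION_LENGTHS",
]


@dataclass(frozen=True)
class PathSkeleton:
    """Four-legged dead-reckoned path: 4 leg lengths, 3 signed turn angles.

    Angles are degrees, positive = left turn.  The first leg points
    along +x from the origin.
    """

    leg_lengths: tuple[float, float, float, float]
    turn_angles: tuple[float, float, float]

    @property
    def waypoints(self) -> np.ndarray:
        """The 5 turning points (start, 3 turns, end), shape (5, 2)."""
        pts = [np.zeros(2)]
        heading = 0.0
        for i, leg in enumerate(self.leg_lengths):
            pts.append(pts[-1] + leg * np.array([np.cos(heading), np.sin(heading)]))
            if i < len(self.turn_angles):
                heading += np.deg2rad(self.turn_angles[i])
        return np.array(pts)

    def mirrored(self) -> "PathSkeleton":
        """Reflection across the first leg (turn directions flipped)."""
        return PathSkeleton(self.leg_lengths,
                            tuple(-a for a in self.turn_angles))


def build_skeleton(leg_lengths, turn_angles) -> PathSkeleton:
    """Validate legs/angles against the task's allowed sets."""
    legs = tuple(float(v) for v in leg_lengths)
    angles = tuple(float(v) for v in turn_angles)
    if len(legs) != 4 or len(angles) != 3:
        raise ValueError("a skeleton has 4 legs and 3 turn angles")
    for leg in legs:
        if leg not in ALLOWED_LEGS:
            raise ValueError(f"leg length {leg} not in {ALLOWED_LEGS}")
    for a in angles:
        if abs(a) not in ALLOWED_ANGLES:
            raise ValueError(f"|turn angle| {abs(a)} not in {ALLOWED_ANGLES}")
    return PathSkeleton(legs, angles)


@dataclass(frozen=True)
class CurvedPath:
    """Arc-length-sampled curve through a skeleton's turning points."""

    path_id: str
    waypoints: np.ndarray          # (n, 2), ~uniform arc-length spacing
    stop_indices: tuple[int, int, int, int]
    total_length: float
    skeleton: PathSkeleton | None = None

    @property
    def stop_positions(self) -> np.ndarray:
        return self.waypoints[list(self.stop_indices)]

    @property
    def arc_lengths_to_stops(self) -> np.ndarray:
        """Cumulative traveled distance from the start to each stop."""
        seglen = np.linalg.norm(np.diff(self.waypoints, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        return cum[list(self.stop_indices)]

    @property
    def bounding_box(self) -> tuple[float, float]:
        span = self.waypoints.max(axis=0) - self.waypoints.min(axis=0)
        return float(span[0]), float(span[1])


def interpolate_curved_path(skeleton: PathSkeleton, sample_spacing_m: float = 0.05,
                            path_id: str = "path") -> CurvedPath:
    """Natural cubic spline through the 5 skeleton points, resampled at
    approximately uniform arc length.

    Stops sit at the curve points closest to the skeleton's three
    turning points and at the endpoint.
    """
    if not sample_spacing_m > 0:
        raise ValueError("sample_spacing_m must be > 0")
    pts = skeleton.waypoints
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chord < 1e-9):
        raise ValueError("degenerate skeleton: coincident turning points")
    t = np.concatenate([[0.0], np.cumsum(chord)])  # chord-length parameter
    spline = CubicSpline(t, pts, bc_type="natural", axis=0)
    # dense evaluation, then arc-length reparameterization
    t_dense = np.linspace(0.0, t[-1], max(2, int(round(t[-1] / sample_spacing_m)) * 20))
    dense = spline(t_dense)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(arc[-1])
    n_samples = max(2, int(round(total / sample_spacing_m)) + 1)
    arc_targets = np.linspace(0.0, total, n_samples)
    t_of_arc = np.interp(arc_targets, arc, t_dense)
    waypoints = spline(t_of_arc)
    # exact endpoints at knots
    waypoints[0] = pts[0]
    waypoints[-1] = pts[-1]
    knot_arcs = np.interp(t[1:], t_dense, arc)
    stop_idx = tuple(int(i) for i in
                     np.searchsorted(arc_targets, knot_arcs[:-1], side="left")) + (n_samples - 1,)
    stop_idx = tuple(min(i, n_samples - 1) for i in stop_idx)
    # pin the stop samples exactly onto the turning points
    for i, k in zip(stop_idx[:3], range(1, 4)):
        waypoints[i] = pts[k]
    total = float(np.linalg.norm(np.diff(waypoints, axis=0), axis=1).sum())
    return CurvedPath(path_id=path_id, waypoints=waypoints,
                      stop_indices=stop_idx, total_length=total,
                      skeleton=skeleton)


def _sample_leg_multiset(rng: np.random.Generator) -> tuple[float, ...]:
    # multisets from the allowed lengths summing to 17 m, so all paths
    # have near-identical total length (the splined arcs land ~17.7 m)
    target = 17.0
    for _ in range(1000):
        legs = tuple(rng.choice(ALLOWED_LEGS, size=4))
        if abs(sum(legs) - target) < 1e-9:
            return tuple(float(v) for v in rng.permutation(legs))
    raise RuntimeError("could not sample a leg multiset")  # pragma: no cover


def _sample_skeleton(rng: np.random.Generator, signs: str) -> PathSkeleton:
    """Rejection-sample a skeleton whose curve fits the tracking area.

    ``signs`` is 'mixed', 'right', or 'left'.
    """
    for _ in range(10_000):
        legs = _sample_leg_multiset(rng)
        mags = rng.choice(ALLOWED_ANGLES, size=3)
        if signs == "mixed":
            s = rng.choice([-1.0, 1.0], size=3)
            if abs(s.sum()) == 3:  # all same direction: not mixed
                continue
        elif signs == "right":
            s = -np.ones(3)
        else:
            s = np.ones(3)
        skel = PathSkeleton(legs, tuple(float(m * si) for m, si in zip(mags, s)))
        curve = interpolate_curved_path(skel)
        w, h = curve.bounding_box
        if w <= ARENA_WIDTH and h <= ARENA_HEIGHT:
            return skel
    raise RuntimeError("could not sample a fitting skeleton")  # pragma: no cover


def make_paths(seed: int, sample_spacing_m: float = 0.05) -> list[CurvedPath]:
    """Generate the session's 10 curved paths.

    Paths 1-6 mix left and right turns; path 7 has only right turns and
    path 8 is its mirror; path 9 has only left turns and path 10 is its
    mirror (turn directions counterbalanced, as in the task design).
    """
    rng = np.random.default_rng(seed)
    skels: list[PathSkeleton] = [_sample_skeleton(rng, "mixed") for _ in range(6)]
    p7 = _sample_skeleton(rng, "right")
    p9 = _sample_skeleton(rng, "left")
    skels += [p7, p7.mirrored(), p9, p9.mirrored()]
    return [interpolate_curved_path(s, sample_spacing_m, path_id=f"P{i + 1:02d}")
            for i, s in enumerate(skels)]


@dataclass(frozen=True)
class TrialSpec:
    path_id: str
    with_stops: bool


@dataclass(frozen=True)
class SessionDesign:
    """Trial order for one session: 3 blocks x 16 trials.

    Standardization triplets (10, 2, 6 m straight paths) follow the 4th
    and 12th trial of each block; trials 1-8 of a block are corrected
    with the first triplet's factors, trials 9-16 with the second's.
    """

    blocks: tuple[tuple[TrialSpec, ...], ...]
    standardization_lengths: tuple[float, float, float] = STANDARDIZATION_LENGTHS
    seed: int | None = None

    @property
    def trials(self) -> list[TrialSpec]:
        return [t for block in self.blocks for t in block]

    @property
    def n_with_stops(self) -> int:
        return sum(t.with_stops for t in self.trials)

    @property
    def n_without_stops(self) -> int:
        return sum(not t.with_stops for t in self.trials)


def _min_gap_ok(seq: list[TrialSpec], min_between: int = 3) -> bool:
    last_seen: dict[str, int] = {}
    for i, spec in enumerate(seq):
        j = last_seen.get(spec.path_id)
        if j is not None and i - j - 1 < min_between:
            return False
        last_seen[spec.path_id] = i
    return True


def make_session_design(seed: int) -> SessionDesign:
    """Pseudo-randomized trial order, reproducible from ``seed``.

    Each block holds paths 1-10 with intermediate stops plus paths 1-6
    without; the order is re-shuffled until at least three other trials
    separate repeated instances of the same path (checked across the
    whole 48-trial session).
    """
    rng = np.random.default_rng(seed)
    base = ([TrialSpec(f"P{i + 1:02d}", True) for i in range(N_PATHS)]
            + [TrialSpec(f"P{i + 1:02d}", False) for i in range(6)])
    for _ in range(100_000):
        blocks = []
        for _b in range(3):
            order = list(rng.permutation(len(base)))
            blocks.append(tuple(base[i] for i in order))
        if _min_gap_ok([t for b in blocks for t in b]):
            return SessionDesign(blocks=tuple(blocks), seed=seed)
    raise RuntimeError("could not satisfy the trial-spacing constraint")  # pragma: no cover
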