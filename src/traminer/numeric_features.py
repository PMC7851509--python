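"""Numeric locomotion indicators: wandering-pattern counts and low-level motion metrics.

The Martino–Saltzman model classifies indoor travel into four patterns —
*direct* (a simple trip between two locations), *pacing* (at least three
consecutive back-and-forth moves between two locations), *lapping* (at least
two consecutive circuits over at least three distinct locations), and
*random* (aimless movement through more than four locations with multiple
direction changes).  Pacing, lapping, and random are indicators of cognitive
impairment.  Locations are discretized to the nearest (here: firing) sensor.

Alongside pattern counts, low-level motion indicators are computed per
trajectory: mean absolute jerk (rate of change of acceleration), count of
sharp angles (turns of at least 90°), total absolute turning angle, path
efficiency (start-to-end displacement over path length), and straightness
(chord-over-arc at each interior junction, averaged).  Per person-day these
aggregate into a numeric feature vector (NFE) for tabular classifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .preprocess import Trajectory

__all__ = [
    "PatternCounts",
    "MotionIndicators",
    "NfeVector",
    "detect_travel_patterns",
    "detect_patterns_in_sequence",
    "compute_motion_indicators",
    "build_nfe_daily_vector",
]

SHARP_ANGLE_DEG = 90.0
RANDOM_MIN_DISTINCT = 5  # "more than four locations"
RANDOM_MIN_TURNS = 2
RANDOM_TURN_DEG = 45.0


@dataclass(frozen=True)
class PatternCounts:
    pacing: int = 0
    lapping: int = 0
    random: int = 0

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


@dataclass(frozen=True)
class MotionIndicators:
    """Low-level motion indicators of one trajectory.

    Statistics that need more points than the trajectory has are NaN
    (undefined), never coerced to 0.
    """

    mean_jerk: float
    straightness: float
    sharp_angle_count: float
    turning_angle_sum: float
    path_efficiency: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class NfeVector:
    """Per person-day numeric feature vector."""

    pacing_count: int
    lapping_count: int
    random_count: int
    mean_jerk: float
    mean_straightness: float
    sharp_angle_count: int

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.pacing_count,
                self.lapping_count,
                self.random_count,
                self.mean_jerk,
                self.mean_straightness,
                self.sharp_angle_count,
            ],
            dtype=float,
        )


# ---------------------------------------------------------------------------
# travel-pattern detection


def _collapse(seq: list) -> list:
    out = []
    for s in seq:
        if not out or out[-1] != s:
            out.append(s)
    return out


def _pacing_moves(seq: list, i: int) -> int:
    """Longest alternating window between two distinct locations starting at i,
    in moves; 0 if shorter than three moves."""
    n = len(seq)
    if i + 1 >= n or seq[i] == seq[i + 1]:
        return 0
    j = i + 2
    while j < n and seq[j] == seq[j - 2]:
        j += 1
    moves = j - i - 1
    return moves if moves >= 3 else 0


def _lapping_moves(seq: list, i: int) -> int:
    """Longest window starting at i that repeats a cycle of >=3 distinct
    locations for >=2 full circuits, in moves; 0 if none."""
    n = len(seq)
    best = 0
    max_p = (n - i - 1) // 2
    for p in range(3, max_p + 1):
        cycle = seq[i : i + p]
        if len(set(cycle)) != p:
            continue
        j = i + p
        while j < n and seq[j] == seq[j - p]:
            j += 1
        moves = j - i - 1
        if moves >= 2 * p and moves > best:
            best = moves
    return best


def _turn_angles_deg(coords: np.ndarray) -> np.ndarray:
    """Heading changes at interior points of a polyline, degrees in [0, 180]."""
    if len(coords) < 3:
        return np.empty(0)
    v = np.diff(np.asarray(coords, float), axis=0)
    norms = np.hypot(v[:, 0], v[:, 1])
    angles = []
    for k in range(len(v) - 1):
        if norms[k] == 0 or norms[k + 1] == 0:
            continue
        cosang = np.dot(v[k], v[k + 1]) / (norms[k] * norms[k + 1])
        angles.append(math.degrees(math.acos(np.clip(cosang, -1.0, 1.0))))
    return np.asarray(angles)


def detect_patterns_in_sequence(locations, coords=None) -> PatternCounts:
    """Count non-overlapping maximal wandering episodes in a location sequence.

    A single left-to-right scan: at each position the longest pacing window
    and the longest lapping window are compared and the longer one (pacing on
    ties) is consumed as one episode; consumed locations cannot seed another
    episode.  Leftover maximal runs qualify as one random episode each when
    they visit more than four distinct locations with at least two direction
    changes of >=45 degrees (``coords`` supplies per-location planar
    coordinates; without them the random count is 0).
    """
    seq = _collapse(list(locations))
    n = len(seq)
    consumed = np.zeros(n, dtype=bool)
    pacing = lapping = random_ = 0
    i = 0
    while i < n - 1:
        lp = _pacing_moves(seq, i)
        ll = _lapping_moves(seq, i)
        if max(lp, ll) > 0:
            if lp >= ll:
                pacing += 1
                moves = lp
            else:
                lapping += 1
                moves = ll
            consumed[i : i + moves + 1] = True
            i += moves + 1
        else:
            i += 1
    if coords is not None:
        coords = dict(coords)
        # maximal unconsumed runs
        start = None
        runs = []
        for k in range(n + 1):
            free = k < n and not consumed[k]
            if free and start is None:
                start = k
            elif not free and start is not None:
                runs.append((start, k))
                start = None
        for a, b in runs:
            run = seq[a:b]
            if len(set(run)) < RANDOM_MIN_DISTINCT:
                continue
            pts = np.array([coords[loc] for loc in run], float)
            turns = _turn_angles_deg(pts)
            if (turns >= RANDOM_TURN_DEG - 1e-9).sum() >= RANDOM_MIN_TURNS:
                random_ += 1
    return PatternCounts(pacing=pacing, lapping=lapping, random=random_)


def detect_travel_patterns(traj: Trajectory) -> PatternCounts:
    """Martino–Saltzman pattern counts of one trajectory.

    Locations are the firing sensors; their recorded coordinates drive the
    direction-change test of the random pattern.
    """
    seq = traj.sensor_sequence
    xy = traj.xy
    coords = {s: tuple(p) for s, p in zip(seq, xy)}
    return detect_patterns_in_sequence(seq, coords)


# ---------------------------------------------------------------------------
# low-level motion indicators


def compute_motion_indicators(traj: Trajectory) -> MotionIndicators:
    """Finite-difference motion indicators of one trajectory.

    Per-segment speeds are differentiated at segment midpoints into
    per-junction accelerations, and those into jerk; ``mean_jerk`` is the mean
    absolute jerk.  A trajectory with a single acceleration sample has
    constant observed acceleration, hence jerk 0; with none, jerk is NaN.
    Angles are heading changes between successive direction vectors
    (straight-ahead 0°, U-turn 180°).
    """
    xy = traj.xy
    t = traj.t_seconds
    n = len(xy)
    if n < 2:
        raise ValueError("trajectory needs at least 2 records")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ValueError("non-increasing timestamps; run cleaning first")
    steps = np.hypot(*np.diff(xy, axis=0).T)
    speeds = steps / dt
    mid = (t[:-1] + t[1:]) / 2.0

    if n >= 3:
        acc = np.diff(speeds) / np.diff(mid)
        if len(acc) >= 2:
            jerk = np.diff(acc) / np.diff(t[1:-1]) if n >= 4 else np.empty(0)
            mean_jerk = float(np.mean(np.abs(jerk))) if len(jerk) else 0.0
        else:
            mean_jerk = 0.0  # single acceleration sample: no observed change
    else:
        mean_jerk = float("nan")

    angles = _turn_angles_deg(xy)
    if n >= 3:
        sharp = float((angles >= SHARP_ANGLE_DEG - 1e-9).sum())
        turning = float(angles.sum())
    else:
        sharp = float("nan")
        turning = float("nan")

    path_len = float(steps.sum())
    if path_len > 0:
        efficiency = float(np.hypot(*(xy[-1] - xy[0])) / path_len)
    else:
        efficiency = float("nan")

    if n >= 3:
        chords = np.hypot(*(xy[2:] - xy[:-2]).T)
        arcs = steps[:-1] + steps[1:]
        ok = arcs > 0
        straightness = float(np.mean(chords[ok] / arcs[ok])) if ok.any() else float("nan")
    else:
        straightness = float("nan")

    return MotionIndicators(
        mean_jerk=mean_jerk,
        straightness=straightness,
        sharp_angle_count=sharp,
        turning_angle_sum=turning,
        path_efficiency=efficiency,
    )


def build_nfe_daily_vector(trajs: list[Trajectory]) -> NfeVector:
    """Aggregate one person-day of trajectories into an NFE vector.

    Pattern counts and sharp angles are summed; jerk and straightness are
    averaged over trajectories weighted by interior-junction count (NaN
    entries excluded).
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    pacing = lapping = random_ = 0
    sharp = 0.0
    jerk_vals, straight_vals, weights = [], [], []
    for traj in trajs:
        pc = detect_travel_patterns(traj)
        pacing += pc.pacing
        lapping += pc.lapping
        random_ += pc.random
        mi = compute_motion_indicators(traj)
        if not math.isnan(mi.sharp_angle_count):
            sharp += mi.sharp_angle_count
        w = max(len(traj) - 2, 0)
        if w > 0:
            if not math.isnan(mi.mean_jerk):
                jerk_vals.append(mi.mean_jerk)
                weights.append(w)
            if not math.isnan(mi.straightness):
                straight_vals.append((mi.straightness, w))
    mean_jerk = (
        float(np.average(jerk_vals, weights=weights)) if jerk_vals else float("nan")
    )
    mean_straight = (
        float(np.average([s for s, _ in straight_vals], weights=[w for _, w in straight_vals]))
        if straight_vals
        else float("nan")
    )
    return NfeVector(
        pacing_count=pacing,
        lapping_count=lapping,
        random_count=random_,
        mean_jerk=mean_jerk,
        mean_straightness=mean_straight,
        sharp_angle_count=int(sharp),
    )
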