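"""Seeded synthetic smart-home layouts and class-conditional locomotion streams.

The simulator emulates a single-occupant instrumented apartment: a ~10 m ×
13 m six-room floor plan carrying 51 ceiling motion sensors on a ~1.4 m grid
plus 16 door sensors on walls (67 sensors total).  A simulated person walks
between sensors; every arrival at a sensor fires one activation event, so the
event stream has the same shape as a real deployment's.

Per cognitive-status class the simulator controls the Martino–Saltzman
pattern mix of the walks (healthy residents travel mostly directly; impaired
residents produce progressively more pacing, lapping, and random episodes),
the gait-speed distribution (slower with impairment), teleport-like sensor
misfires at a configurable rate (these violate the cleaning thresholds by
construction), and inter-trajectory silences longer than any segmentation
threshold in use, so ground-truth trajectory boundaries are recoverable.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .io_events import SensorMap
from .numeric_features import detect_patterns_in_sequence

__all__ = [
    "CohortSpec",
    "SyntheticLayout",
    "PersonDay",
    "Cohort",
    "generate_layout",
    "generate_pattern_path",
    "simulate_person_day",
    "generate_cohort",
]

CLASSES = ("healthy", "MCI", "PwD")

DEFAULT_PATTERN_MIX = {
    # direct, pacing, lapping, random: wandering grows with impairment, and
    # its kind shifts — early impairment paces and laps, advanced dementia
    # adds disproportionately more random travel
    "healthy": (0.85, 0.07, 0.05, 0.03),
    "MCI": (0.55, 0.22, 0.18, 0.05),
    "PwD": (0.25, 0.20, 0.20, 0.35),
}

DEFAULT_SPEED_PROFILE = {
    # mean, sd of the person-level gait speed, m/s
    "healthy": (1.1, 0.12),
    "MCI": (0.85, 0.12),
    "PwD": (0.6, 0.12),
}

#: Wandering severity per class: (max pacing back-and-forth moves,
#: max lapping circuits).  Impaired residents repeat episodes longer.
DEFAULT_WANDER_INTENSITY = {
    "healthy": (4, 2),
    "MCI": (8, 3),
    "PwD": (14, 5),
}

#: Movement legs chained into one trajectory, per class (lo, hi inclusive).
#: Disoriented locomotion prolongs activity bouts.
DEFAULT_LEGS = {
    "healthy": (2, 4),
    "MCI": (4, 7),
    "PwD": (6, 10),
}

PATTERNS = ("direct", "pacing", "lapping", "random")

# six-room floor plan over a 10 m x 13 m footprint
ROOMS = {
    "kitchen": (0.0, 0.0, 4.0, 5.0),
    "living": (4.0, 0.0, 10.0, 6.0),
    "bathroom": (0.0, 5.0, 4.0, 9.0),
    "bedroom1": (4.0, 6.0, 7.0, 13.0),
    "bedroom2": (7.0, 6.0, 10.0, 13.0),
    "bedroom3": (0.0, 9.0, 4.0, 13.0),
}

DOOR_POSITIONS = [
    (4.0, 2.5), (2.0, 5.0), (4.0, 7.5), (2.0, 9.0),
    (5.5, 6.0), (8.5, 6.0), (7.0, 9.5), (4.0, 11.0),
    (5.0, 0.0), (10.0, 3.0), (0.0, 2.0), (9.0, 13.0),
    (1.0, 0.0), (10.0, 9.0), (0.0, 11.0), (6.0, 13.0),
]

NEIGHBOR_RADIUS_M = 2.5  # sensors this close are walkable in one step


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort."""

    persons_per_class: tuple[int, int, int] = (12, 10, 8)  # healthy, MCI, PwD
    trajectories_per_person: int = 20
    legs_per_trajectory: dict = field(default_factory=lambda: dict(DEFAULT_LEGS))
    pattern_mix: dict = field(default_factory=lambda: dict(DEFAULT_PATTERN_MIX))
    speed_profile: dict = field(default_factory=lambda: dict(DEFAULT_SPEED_PROFILE))
    wander_intensity: dict = field(
        default_factory=lambda: dict(DEFAULT_WANDER_INTENSITY)
    )
    noise_rate: float = 2.0  # teleport misfires per 100 events
    early_fire_rate: float = 20.0  # premature PIR firings per 100 events
    gap_range: tuple[float, float] = (240.0, 600.0)  # inter-trajectory silence, s
    n_motion: int = 51
    n_door: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, mix in self.pattern_mix.items():
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"pattern mix for {cls!r} must sum to 1")
        if self.noise_rate < 0 or self.early_fire_rate < 0:
            raise ValueError("rates must be >= 0")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for key in ("pattern_mix", "speed_profile", "wander_intensity", "legs_per_trajectory"):
            d[key] = {k: list(v) for k, v in d[key].items()}
        return d


@dataclass
class SyntheticLayout:
    """Home geometry plus the walkability graph between sensors."""

    rooms: dict
    sensor_ids: list[str]
    positions: np.ndarray  # (n, 2) meters, aligned with sensor_ids
    kinds: list[str]

    def __post_init__(self) -> None:
        tree = cKDTree(self.positions)
        pairs = tree.query_pairs(NEIGHBOR_RADIUS_M, output_type="ndarray")
        n = len(self.sensor_ids)
        w = np.hypot(*(self.positions[pairs[:, 0]] - self.positions[pairs[:, 1]]).T)
        graph = coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([pairs[:, 0], pairs[:, 1]]),
              np.concatenate([pairs[:, 1], pairs[:, 0]]))),
            shape=(n, n),
        ).tocsr()
        self._graph = graph
        self.neighbors = [graph.indices[graph.indptr[i]:graph.indptr[i + 1]].tolist()
                          for i in range(n)]
        self._dist, self._pred = dijkstra(graph, return_predecessors=True)

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_ids)

    def route(self, a: int, b: int) -> list[int]:
        """Shortest sensor-graph walk from a to b (inclusive)."""
        if not np.isfinite(self._dist[a, b]):
            raise ValueError("sensors are not connected in the walkability graph")
        path = [b]
        while path[-1] != a:
            path.append(int(self._pred[a, path[-1]]))
        return path[::-1]

    def sensor_map(self) -> SensorMap:
        df = pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "kind": self.kinds,
                "ordinal": np.arange(1, self.n_sensors + 1),
            },
            index=pd.Index(self.sensor_ids, name="s_id"),
        )
        return SensorMap(df)


def generate_layout(
    spec: CohortSpec | None = None, seed: int | None = None
) -> tuple[SyntheticLayout, SensorMap]:
    """Instrument the floor plan with motion + door sensors, seeded.

    Motion sensors sit on a regular ~1.4 m grid (with small jitter) thinned
    down to the requested count such that no two removed grid points are
    adjacent — this keeps every nearest-neighbor distance well below 3 m.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cols, rows = 7, 9
    xs = (np.arange(cols) + 0.5) * 10.0 / cols
    ys = (np.arange(rows) + 0.5) * 13.0 / rows
    grid = np.array([(x, y) for y in ys for x in xs])
    n_remove = len(grid) - spec.n_motion
    if n_remove < 0:
        raise ValueError(
            f"cannot place {spec.n_motion} motion sensors on a {len(grid)}-point grid"
        )
    removed: list[int] = []
    for i in rng.permutation(len(grid)):
        if len(removed) == n_remove:
            break
        if all(np.hypot(*(grid[i] - grid[j])) > 1.6 for j in removed):
            removed.append(int(i))
    if len(removed) < n_remove:
        raise ValueError("infeasible sensor density")
    keep = np.setdiff1d(np.arange(len(grid)), removed)
    motion = grid[keep] + rng.uniform(-0.1, 0.1, size=(len(keep), 2))
    doors = np.array(DOOR_POSITIONS[: spec.n_door], dtype=float)
    if len(doors) < spec.n_door:
        raise ValueError(f"at most {len(DOOR_POSITIONS)} door sensors supported")
    ids = [f"M{i:03d}" for i in range(1, len(motion) + 1)] + [
        f"D{i:03d}" for i in range(1, len(doors) + 1)
    ]
    positions = np.vstack([motion, doors])
    kinds = ["motion"] * len(motion) + ["door"] * len(doors)
    layout = SyntheticLayout(
        rooms=dict(ROOMS), sensor_ids=ids, positions=positions, kinds=kinds
    )
    return layout, layout.sensor_map()


def _nearby(layout: SyntheticLayout, anchor: int, radius: float) -> list[int]:
    d = np.hypot(*(layout.positions - layout.positions[anchor]).T)
    return [int(i) for i in np.flatnonzero((d > 0) & (d <= radius))]


def generate_pattern_path(
    pattern: str,
    layout: SyntheticLayout,
    rng: np.random.Generator,
    start: int | None = None,
    max_moves: int = 6,
    max_circuits: int = 3,
) -> list[int]:
    """Sensor-index walk realizing one Martino–Saltzman pattern.

    The emitted walk satisfies the corresponding pattern-detector predicate
    (direct walks register no pattern at all).  ``start`` anchors the walk
    near a given sensor so consecutive legs chain into a continuous path.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    n = layout.n_sensors
    coords = {i: tuple(layout.positions[i]) for i in range(n)}

    for _ in range(200):
        anchor = int(start if start is not None else rng.integers(n))
        if pattern == "direct":
            d = np.hypot(*(layout.positions - layout.positions[anchor]).T)
            far = np.flatnonzero(d >= 4.0)
            if len(far) == 0:
                start = None
                continue
            goal = int(rng.choice(far))
            try:
                path = layout.route(anchor, goal)
            except ValueError:
                start = None
                continue
            counts = detect_patterns_in_sequence(path, coords)
            if counts.pacing == counts.lapping == counts.random == 0:
                return path
        elif pattern == "pacing":
            nbrs = _nearby(layout, anchor, NEIGHBOR_RADIUS_M)
            if not nbrs:
                start = None
                continue
            b = int(rng.choice(nbrs))
            moves = int(rng.integers(3, max(4, max_moves + 1)))
            path = [anchor if k % 2 == 0 else b for k in range(moves + 1)]
            return path
        elif pattern == "lapping":
            nbrs = _nearby(layout, anchor, NEIGHBOR_RADIUS_M)
            rng.shuffle(nbrs)
            cycle = None
            for b in nbrs:
                cands = [
                    c
                    for c in _nearby(layout, b, NEIGHBOR_RADIUS_M)
                    if c not in (anchor, b)
                    and np.hypot(*(layout.positions[c] - layout.positions[anchor])) <= NEIGHBOR_RADIUS_M
                ]
                if cands:
                    cycle = [anchor, b, int(rng.choice(cands))]
                    break
            if cycle is None:
                start = None
                continue
            circuits = int(rng.integers(2, max(3, max_circuits + 1)))
            return cycle * circuits + [cycle[0]]
        else:  # random
            path = [anchor]
            prev = None
            for _ in range(int(rng.integers(8, 14))):
                nbrs = [j for j in layout.neighbors[path[-1]] if j != prev]
                if not nbrs:
                    break
                prev = path[-1]
                path.append(int(rng.choice(nbrs)))
            counts = detect_patterns_in_sequence(path, coords)
            if counts.random >= 1 and counts.pacing == 0 and counts.lapping == 0:
                return path
            start = None
    raise ValueError(f"layout too small to realize pattern {pattern!r}")


@dataclass
class PersonDay:
    """One simulated person-day: the raw stream plus embedded ground truth."""

    person_id: str
    label: str
    events: pd.DataFrame  # timestamp, s_id, value (file-order, noise included)
    boundaries: list[tuple[float, float]]  # per-trajectory (t_start, t_end), epoch s
    leg_patterns: list[list[str]]  # per-trajectory pattern of each leg
    n_noise: int


def _truncnorm(rng, mean, sd, lo, hi) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def simulate_person_day(
    label: str,
    spec: CohortSpec,
    layout: SyntheticLayout,
    rng: np.random.Generator,
    person_id: str = "p0",
    t0: pd.Timestamp = pd.Timestamp("2011-06-01 08:00:00"),
) -> PersonDay:
    """Simulate one labeled person-day of sensor activations.

    Each trajectory chains several pattern legs (mix set by the class);
    inter-sensor travel times follow the person's gait speed; silences
    between trajectories exceed the top of the segmentation sweep by
    construction.  Two sensor artifacts are emulated: *early firings*
    (overlapping PIR detection ranges trigger a sensor well before the person
    reaches it, compressing the apparent inter-firing time and inflating the
    apparent speed into the upper speed ranges — more strongly for faster
    walkers) at ``spec.early_fire_rate`` per 100 events, and *teleport
    misfires* at ``spec.noise_rate`` per 100 events, which jump farther than
    the cleaning distance threshold and are therefore removable.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown class {label!r}")
    mix = np.asarray(spec.pattern_mix[label], dtype=float)
    mean, sd = spec.speed_profile[label]
    speed = _truncnorm(rng, mean, sd, 0.3, 1.6)
    noise_rng = np.random.default_rng(rng.integers(2**31))

    t = 0.0  # seconds from t0
    rows: list[tuple[float, int]] = []  # (t_rel, sensor_idx)
    boundaries: list[tuple[float, float]] = []
    leg_patterns: list[list[str]] = []
    current = int(rng.integers(layout.n_sensors))
    for _ in range(spec.trajectories_per_person):
        lo, hi = spec.legs_per_trajectory[label]
        n_legs = int(rng.integers(lo, hi + 1))
        patterns = [PATTERNS[int(k)] for k in rng.choice(4, size=n_legs, p=mix)]
        leg_patterns.append(patterns)
        start_t = t
        rows.append((t, current))
        max_moves, max_circuits = spec.wander_intensity[label]
        for pat in patterns:
            path = generate_pattern_path(
                pat, layout, rng, start=current,
                max_moves=max_moves, max_circuits=max_circuits,
            )
            if path[0] != current:
                path = layout.route(current, path[0])[1:] + path[1:]
            for s in path:
                if s == current:
                    continue
                dist = float(np.hypot(*(layout.positions[s] - layout.positions[current])))
                leg_speed = float(np.clip(speed * (1 + rng.normal(0, 0.1)), 0.3, 1.8))
                dt = max(dist / leg_speed * (1 + rng.normal(0, 0.05)), 0.15)
                if rng.random() < spec.early_fire_rate / 100.0:
                    # premature detection: the sensor ahead fires early
                    dt *= float(rng.uniform(0.15, 0.6))
                t += dt
                rows.append((t, s))
                current = s
        boundaries.append((start_t, t))
        t += float(rng.uniform(*spec.gap_range))

    # teleport misfire injection between consecutive events of a trajectory
    out_rows: list[tuple[float, int]] = []
    n_noise = 0
    for k, (tk, sk) in enumerate(rows):
        out_rows.append((tk, sk))
        if k + 1 < len(rows):
            t_next = rows[k + 1][0]
            same_traj = any(b[0] <= tk and t_next <= b[1] for b in boundaries)
            if same_traj and noise_rng.random() < spec.noise_rate / 100.0:
                d = np.hypot(*(layout.positions - layout.positions[sk]).T)
                far = np.flatnonzero(d > 5.5)
                if len(far):
                    ghost = int(noise_rng.choice(far))
                    out_rows.append((tk + min(0.05, (t_next - tk) / 2), ghost))
                    n_noise += 1

    # millisecond timestamps, strictly increasing
    ts: list[float] = []
    for tk, _ in out_rows:
        tms = round(tk, 3)
        if ts and tms <= ts[-1]:
            tms = ts[-1] + 0.001
        ts.append(tms)
    stamps = t0 + pd.to_timedelta(np.round(np.array(ts) * 1000).astype("int64"), unit="ms")
    events = pd.DataFrame(
        {
            "timestamp": stamps.strftime("%Y-%m-%d %H:%M:%S.%f").str.slice(0, 23),
            "s_id": [layout.sensor_ids[s] for _, s in out_rows],
            "value": "ON",
        }
    )
    t0_s = t0.timestamp()
    return PersonDay(
        person_id=person_id,
        label=label,
        events=events,
        boundaries=[(a + t0_s, b + t0_s) for a, b in boundaries],
        leg_patterns=leg_patterns,
        n_noise=n_noise,
    )


@dataclass
class Cohort:
    """A labeled synthetic cohort: layout, sensor map, person-days, manifest."""

    layout: SyntheticLayout
    sensor_map: SensorMap
    persons: list[PersonDay]
    manifest: dict

    @property
    def labels(self) -> dict[str, str]:
        return {p.person_id: p.label for p in self.persons}


def generate_cohort(spec: CohortSpec = CohortSpec()) -> Cohort:
    """Generate a labeled cohort of person-days, reproducible from the seed."""
    if min(spec.persons_per_class) < 2:
        raise ValueError("need at least 2 persons per class for LOPO")
    layout, sensor_map = generate_layout(spec)
    ss = np.random.SeedSequence(spec.seed)
    persons: list[PersonDay] = []
    n_total = sum(spec.persons_per_class)
    children = ss.spawn(n_total)
    k = 0
    for label, n in zip(CLASSES, spec.persons_per_class):
        for i in range(n):
            rng = np.random.default_rng(children[k])
            persons.append(
                simulate_person_day(
                    label, spec, layout, rng, person_id=f"{label}_{i:02d}"
                )
            )
            k += 1
    spec_json = json.dumps(spec.to_jsonable(), sort_keys=True)
    manifest = {
        "seed": spec.seed,
        "spec": spec.to_jsonable(),
        "spec_sha256": hashlib.sha256(spec_json.encode()).hexdigest(),
        "persons": [
            {
                "person_id": p.person_id,
                "label": p.label,
                "n_events": int(len(p.events)),
                "n_trajectories": len(p.boundaries),
                "n_noise_events": p.n_noise,
            }
            for p in persons
        ],
    }
    return Cohort(layout=layout, sensor_map=sensor_map, persons=persons, manifest=manifest)
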