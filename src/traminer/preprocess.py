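"""Position-data cleaning and trajectory segmentation.

Indoor positioning from presence sensors is noisy: sensor misfires produce
teleport-like jumps that no walking person can perform.  Cleaning removes a
record whenever the step from the last surviving record implies either a
speed above ``T_v`` (default 15 m/s) or a straight-line displacement above
``T_d`` (default 5 m, chosen because adjacent sensors in the reference
deployment are never more than 3 m apart).  The survivor stays the comparison
anchor, so a burst of consecutive bad readings is pruned one by one.

The cleaned history is then partitioned into trajectories: maximal runs of
records whose inter-record time gap never exceeds ``T_s``.  A silence longer
than ``T_s`` closes the current trajectory; the next one starts at the first
record after the gap, so trajectories never share records (pass
``shared_boundary=True`` for the alternative convention where the next
trajectory re-uses the boundary record).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_events import PositionHistory

__all__ = ["CleaningConfig", "Trajectory", "clean_positions", "segment_trajectories"]


@dataclass(frozen=True)
class CleaningConfig:
    """Plausibility thresholds for consecutive position records.

    T_v : maximum speed in m/s (faster steps are sensor noise).
    T_d : maximum step displacement in m (longer steps skip non-contiguous
          sensors and are sensor noise).
    """

    T_v: float = 15.0
    T_d: float = 5.0

    def __post_init__(self) -> None:
        if self.T_v <= 0 or self.T_d <= 0:
            raise ValueError("cleaning thresholds must be positive")


@dataclass
class Trajectory:
    """A temporally ordered run of position records bounded by long silences."""

    records: pd.DataFrame  # columns t, x, y, s_id
    person_id: str = ""
    index: int = 0

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def t_seconds(self) -> np.ndarray:
        return self.records["t"].to_numpy("datetime64[ns]").astype("int64") / 1e9

    @property
    def xy(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(float)

    @property
    def sensor_sequence(self) -> list[str]:
        return self.records["s_id"].tolist()


def _implausible(dx: float, dy: float, dt: float, cfg: CleaningConfig) -> bool:
    dist = float(np.hypot(dx, dy))
    if dist > cfg.T_d:
        return True
    # dt == 0 at identical positions is collapsed separately before this test
    return dt > 0 and dist / dt > cfg.T_v


def clean_positions(
    history: PositionHistory, cfg: CleaningConfig = CleaningConfig()
) -> PositionHistory:
    """Remove implausible readings with a single anchored forward scan.

    The first record is always kept.  Each subsequent record is compared with
    the last *surviving* record; it is deleted if the step exceeds ``T_d`` or
    implies a speed above ``T_v``.  Exact duplicates (same timestamp, same
    position) collapse to one record; a zero-time step to a *different*
    position is infinite speed and is deleted.  The output is a subsequence of
    the input.
    """
    n = len(history)
    if n == 0:
        return PositionHistory(history.records.iloc[:0], history.person_id)
    t = history.t_seconds
    xy = history.xy
    keep = [0]
    anchor = 0
    for i in range(1, n):
        dt = t[i] - t[anchor]
        dx = xy[i, 0] - xy[anchor, 0]
        dy = xy[i, 1] - xy[anchor, 1]
        if dt == 0:
            if dx == 0 and dy == 0:
                continue  # duplicate reading
            # simultaneous reading elsewhere: infinite speed
            continue
        if _implausible(dx, dy, dt, cfg):
            continue
        keep.append(i)
        anchor = i
    return PositionHistory(history.records.iloc[keep], history.person_id)


def segment_trajectories(
    history: PositionHistory,
    T_s: float,
    *,
    shared_boundary: bool = False,
    min_records: int = 2,
) -> list[Trajectory]:
    """Partition a cleaned history into trajectories at silences longer than T_s.

    Consecutive records with a gap ≤ ``T_s`` seconds stay together; a longer
    gap closes the trajectory.  Trajectories with fewer than ``min_records``
    records are dropped (a single point has no drawable path or speed).
    """
    if T_s <= 0:
        raise ValueError("T_s must be positive")
    n = len(history)
    if n == 0:
        return []
    t = history.t_seconds
    breaks = np.flatnonzero(np.diff(t) > T_s)  # gap after index b
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [n]))  # exclusive
    out: list[Trajectory] = []
    for start, end in zip(starts, ends):
        if shared_boundary and start > 0:
            start = start - 1  # literal shared-record convention
        if end - start < min_records:
            continue
        out.append(
            Trajectory(
                history.records.iloc[start:end],
                person_id=history.person_id,
                index=len(out),
            )
        )
    return out
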