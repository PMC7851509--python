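"""Reading sensor maps and raw event streams, and joining them into position histories.

A deployment is described by a *sensor map* (one row per sensor: id, planar
coordinates in meters, and kind ``motion``/``door``) and produces a *raw event
stream* (timestamp, sensor id, value).  Joining the stream against the map
yields the person's *position history*: the temporally ordered sequence of
points witnessed by sensor firings, which is the input of cleaning and
segmentation.

File dialects are plain CSV with a header row; timestamps are ISO-8601 with
millisecond precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SensorMap",
    "PositionHistory",
    "ACTIVATION_VALUES",
    "load_sensor_map",
    "load_event_stream",
    "to_position_history",
    "write_position_history",
    "read_position_history",
]

#: Sensor values that witness presence.  OFF/close releases carry no new
#: position information, so by default only these activate a position record.
ACTIVATION_VALUES = frozenset({"ON", "OPEN"})

EVENT_COLUMNS = ["timestamp", "s_id", "value"]


@dataclass(frozen=True)
class SensorMap:
    """Sensor inventory of one deployment.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per sensor, indexed by ``s_id``, columns ``x``, ``y``,
        ``kind``, and ``ordinal`` (a stable 1..N index in file order, used by
        the sensor-sequence image encoding).
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, s_id: str) -> bool:
        return s_id in self.table.index

    @property
    def n_sensors(self) -> int:
        return len(self.table)

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) over all sensors, meters."""
        x = self.table["x"].to_numpy(float)
        y = self.table["y"].to_numpy(float)
        return float(x.min()), float(y.min()), float(x.max()), float(y.max())

    def position(self, s_id: str) -> tuple[float, float]:
        row = self.table.loc[s_id]
        return float(row["x"]), float(row["y"])

    def ordinal(self, s_id: str) -> int:
        return int(self.table.loc[s_id, "ordinal"])

    def ordinals(self, s_ids) -> np.ndarray:
        return self.table.loc[list(s_ids), "ordinal"].to_numpy(int)


@dataclass
class PositionHistory:
    """Ordered sequence of position records for one person.

    ``records`` has columns ``t`` (datetime64[ns]), ``x``, ``y`` (meters) and
    ``s_id`` (the sensor that fired, kept as metadata).  Rows are sorted by
    ``t``; ties keep stream order (stable sort).
    """

    records: pd.DataFrame
    person_id: str = ""

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def t_seconds(self) -> np.ndarray:
        """Timestamps as float seconds since the epoch."""
        return self.records["t"].to_numpy("datetime64[ns]").astype("int64") / 1e9

    @property
    def xy(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(float)


def load_sensor_map(path) -> SensorMap:
    """Read a sensor position table (``s_id,x,y[,kind]`` CSV).

    Each sensor also receives a stable ordinal index 1..N in file order.
    Raises ``ValueError`` on duplicate ids or non-numeric coordinates (the
    error names the offending id / row).
    """
    df = pd.read_csv(path, dtype={"s_id": str})
    missing = {"s_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"sensor map {path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"sensor map {path}: no rows")
    dupes = df["s_id"][df["s_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"sensor map {path}: duplicate sensor id {dupes.iloc[0]!r}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | ~np.isfinite(coerced)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"sensor map {path}: non-numeric {col} coordinate at data row {row + 1}"
            )
        df[col] = coerced.astype(float)
    if "kind" not in df.columns:
        df["kind"] = "motion"
    df["ordinal"] = np.arange(1, len(df) + 1)
    return SensorMap(df.set_index("s_id")[["x", "y", "kind", "ordinal"]])


def load_event_stream(path, strict: bool = True) -> pd.DataFrame:
    """Read a raw event stream (``timestamp,s_id,value`` CSV) in file order.

    In strict mode an unparseable timestamp raises ``ValueError`` naming the
    row; in lenient mode malformed rows are dropped with one summary warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event stream {path}: missing columns {sorted(missing)}")
    t = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = t.isna() | (df["s_id"].str.strip() == "")
    if bad.any():
        if strict:
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"event stream {path}: malformed row {row + 1}: "
                f"{df.iloc[row].tolist()}"
            )
        warnings.warn(
            f"event stream {path}: skipped {int(bad.sum())} malformed row(s)",
            stacklevel=2,
        )
    out = df.loc[~bad, ["s_id", "value"]].copy()
    out.insert(0, "t", t[~bad])
    out["s_id"] = out["s_id"].str.strip()
    out["value"] = out["value"].str.strip()
    return out.reset_index(drop=True)


def to_position_history(
    events: pd.DataFrame,
    sensor_map: SensorMap,
    *,
    person_id: str = "",
    strict: bool = True,
    activation_only: bool = True,
) -> PositionHistory:
    """Join events with the sensor map into a sorted position history.

    Each retained event becomes one record at the firing sensor's coordinates.
    ``activation_only`` keeps only presence-witnessing values (ON/open); set it
    False to position every event.  Unknown sensor ids raise in strict mode
    and are skipped with a warning otherwise.  Sorting by timestamp is stable,
    so simultaneous events keep stream order.
    """
    ev = events
    if activation_only:
        ev = ev[ev["value"].str.upper().isin(ACTIVATION_VALUES)]
    known = ev["s_id"].isin(sensor_map.table.index)
    if not known.all():
        unknown = ev.loc[~known, "s_id"].iloc[0]
        if strict:
            raise KeyError(f"event references unknown sensor id {unknown!r}")
        warnings.warn(
            f"skipped {int((~known).sum())} event(s) with unknown sensor ids",
            stacklevel=2,
        )
        ev = ev[known]
    joined = ev.join(sensor_map.table[["x", "y"]], on="s_id")
    records = joined[["t", "x", "y", "s_id"]].sort_values("t", kind="stable")
    return PositionHistory(records.reset_index(drop=True), person_id=person_id)


def write_position_history(history: PositionHistory, path) -> None:
    """Write a history as CSV (ms-precision ISO timestamps); round-trips exactly."""
    out = history.records.copy()
    out["t"] = out["t"].dt.strftime("%Y-%m-%d %H:%M:%S.%f").str.slice(0, 23)
    out.to_csv(path, index=False)


def read_position_history(path, person_id: str = "") -> PositionHistory:
    df = pd.read_csv(path, dtype={"s_id": str})
    df["t"] = pd.to_datetime(df["t"], format="ISO8601")
    return PositionHistory(df[["t", "x", "y", "s_id"]], person_id=person_id)
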