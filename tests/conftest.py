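import numpy as np
import pandas as pd
import pytest

from traminer.io_events import PositionHistory
from traminer.preprocess import Trajectory
from traminer.synthetic_data import CohortSpec, generate_layout

T0 = pd.Timestamp("2011-06-01 08:00:00")


def make_history(times_s, points, s_ids=None, person_id="p0") -> PositionHistory:
    """Build a PositionHistory from relative seconds and (x, y) points."""
    times_s = list(times_s)
    points = [tuple(p) for p in points]
    if s_ids is None:
        s_ids = [f"S{i}" for i in range(len(points))]
    df = pd.DataFrame(
        {
            "t": [T0 + pd.Timedelta(milliseconds=round(float(s) * 1000)) for s in times_s],
            "x": [p[0] for p in points],
            "y": [p[1] for p in points],
            "s_id": s_ids,
        }
    )
    return PositionHistory(df, person_id=person_id)


def make_trajectory(times_s, points, s_ids=None) -> Trajectory:
    return Trajectory(make_history(times_s, points, s_ids).records)


@pytest.fixture(scope="session")
def default_layout():
    layout, sensor_map = generate_layout(CohortSpec())
    return layout, sensor_map
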