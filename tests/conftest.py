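import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_series(values, start="2023-03-06 00:00", epoch_minutes=15, tz="Europe/London"):
    """Activity series on a clock-aligned 15-minute grid."""
    idx = pd.date_range(start=pd.Timestamp(start, tz=tz), periods=len(values),
                        freq=f"{epoch_minutes}min")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


@pytest.fixture
def night_trace():
    """Quiet 23:00-03:00, active 03:00-03:30, quiet 03:30-07:00 (15-min epochs).

    Outside 23:00-07:00 the window epochs are fully active so the rest period
    is pinned to the constructed quiet block.
    """
    idx = pd.date_range(pd.Timestamp("2023-03-06 22:00", tz="Europe/London"),
                        pd.Timestamp("2023-03-07 08:00", tz="Europe/London"),
                        freq="15min", inclusive="left")
    vals = np.full(len(idx), 100.0)
    for i, ts in enumerate(idx):
        t = ts.hour + ts.minute / 60
        in_quiet1 = (t >= 23) or (t < 3)
        in_quiet2 = 3.5 <= t < 7
        if in_quiet1 or in_quiet2:
            vals[i] = 0.0
    return pd.Series(vals, index=idx)


def make_frames(times, xs, ys, sensor="s1", resident="r1", tz="Europe/London"):
    ts = pd.DatetimeIndex(pd.to_datetime(list(times)))
    if ts.tz is None:
        ts = ts.tz_localize(tz)
    return pd.DataFrame({"timestamp": ts, "sensor_id": sensor,
                         "resident_id": resident,
                         "x": np.asarray(xs, float), "y": np.asarray(ys, float)})
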