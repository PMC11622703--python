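"""Night-time rest and disturbance metrics from epoch-level activity.

A night is scored inside a configurable clock window (default 22:00-08:00
local). The rest period spans from the start of the first run of at least
``min_run`` consecutive quiet epochs (activity <= theta) to the end of the
last such run; a night with no qualifying quiet run is left unscored. Sleep
disturbances are maximal runs of epochs above theta inside the rest period
lasting at least ``min_bout`` epochs. Total sleep is the rest span minus the
summed disturbance minutes, and wake time is the clock time of rest offset.

Thresholds are deliberately configuration, not constants: theta=10 (percent
activity), min_run=4 epochs (one hour) and min_bout=1 epoch (15 minutes) are
the defaults. Scheduled care checks at night can register as genuine movement
bouts; no correction is attempted for them.

Aggregation uses medians (per resident over nights, then over residents),
which resist the heavy skew of count data from small cohorts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SleepError(ValueError):
    """Invalid sleep-scoring input."""


DEFAULT_NIGHT_WINDOW = (dt.time(22, 0), dt.time(8, 0))


@dataclass(frozen=True)
class NightRecord:
    night_of: dt.date
    rest_onset: pd.Timestamp | None
    rest_offset: pd.Timestamp | None
    n_disturbances: int | None
    bout_lengths: list[float] = field(default_factory=list)  # minutes
    total_sleep_hours: float | None = None
    wake_time: dt.time | None = None

    @property
    def scored(self) -> bool:
        return self.rest_onset is not None


@dataclass(frozen=True)
class SleepSummary:
    phase: str
    median_disturbances: float
    median_bout_minutes: float
    median_total_sleep_hours: float
    n_residents: int


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open (start, end) index pairs."""
    out = []
    i, n = 0, mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def night_slice(activity: pd.Series, night_of: dt.date,
                window: tuple[dt.time, dt.time] = DEFAULT_NIGHT_WINDOW) -> pd.Series:
    """Epochs of one night's window (evening of ``night_of`` to next morning)."""
    tz = activity.index.tz
    start = pd.Timestamp(dt.datetime.combine(night_of, window[0]), tz=tz)
    end_date = night_of + dt.timedelta(days=1) if window[1] <= window[0] else night_of
    end = pd.Timestamp(dt.datetime.combine(end_date, window[1]), tz=tz)
    return activity[(activity.index >= start) & (activity.index < end)]


def detect_rest_period(
    night: pd.Series, theta: float = 10.0, min_run: int = 4
) -> tuple[pd.Timestamp, pd.Timestamp] | None:
    """(rest_onset, rest_offset) for one night's epochs, or None if unscored.

    Quiet means activity <= theta; missing epochs break quiet runs.
    """
    if not 0 <= theta <= 100:
        raise SleepError(f"theta must lie in [0, 100], got {theta}")
    if night.empty:
        return None
    vals = night.to_numpy(dtype=float)
    quiet = ~np.isnan(vals) & (vals <= theta)
    qualifying = [(a, b) for a, b in _runs(quiet) if b - a >= min_run]
    if not qualifying:
        return None
    epoch = night.index[1] - night.index[0] if len(night) > 1 else pd.Timedelta(minutes=15)
    onset = night.index[qualifying[0][0]]
    offset = night.index[qualifying[-1][1] - 1] + epoch
    return onset, offset


def count_disturbances(
    night: pd.Series,
    rest_period: tuple[pd.Timestamp, pd.Timestamp],
    theta: float = 10.0,
    min_bout: int = 1,
) -> tuple[int, list[float]]:
    """(n_disturbances, bout lengths in minutes) inside the rest period."""
    if not 0 <= theta <= 100:
        raise SleepError(f"theta must lie in [0, 100], got {theta}")
    onset, offset = rest_period
    inside = night[(night.index >= onset) & (night.index < offset)]
    vals = inside.to_numpy(dtype=float)
    active = ~np.isnan(vals) & (vals > theta)
    epoch_min = ((inside.index[1] - inside.index[0]).total_seconds() / 60
                 if len(inside) > 1 else 15.0)
    bouts = [(b - a) * epoch_min for a, b in _runs(active) if b - a >= min_bout]
    return len(bouts), bouts


def total_sleep_and_wake(
    rest_period: tuple[pd.Timestamp, pd.Timestamp], bout_lengths: list[float]
) -> tuple[float, dt.time]:
    """(total sleep hours, wake clock time) from a rest span and its bouts."""
    onset, offset = rest_period
    span_h = (offset - onset).total_seconds() / 3600.0
    sleep_h = span_h - sum(bout_lengths) / 60.0
    return sleep_h, offset.time()


def score_night(
    activity: pd.Series,
    night_of: dt.date,
    window: tuple[dt.time, dt.time] = DEFAULT_NIGHT_WINDOW,
    theta: float = 10.0,
    min_run: int = 4,
    min_bout: int = 1,
) -> NightRecord:
    night = night_slice(activity, night_of, window)
    rest = detect_rest_period(night, theta, min_run)
    if rest is None:
        return NightRecord(night_of, None, None, None)
    n, bouts = count_disturbances(night, rest, theta, min_bout)
    sleep_h, wake = total_sleep_and_wake(rest, bouts)
    return NightRecord(night_of, rest[0], rest[1], n, bouts, sleep_h, wake)


def score_nights(activity: pd.Series, **kwargs) -> pd.DataFrame:
    """Score every night in the series; one row per night, unscored rows NaN."""
    if activity.empty:
        raise SleepError("empty activity series")
    dates = sorted({ts.date() for ts in activity.index})
    rows = []
    for d in dates:
        rec = score_night(activity, d, **kwargs)
        rows.append({
            "night_of": rec.night_of,
            "rest_onset": rec.rest_onset,
            "rest_offset": rec.rest_offset,
            "n_disturbances": rec.n_disturbances if rec.scored else np.nan,
            "median_bout_minutes": (float(np.median(rec.bout_lengths))
                                    if rec.scored and rec.bout_lengths else
                                    (0.0 if rec.scored else np.nan)),
            "total_sleep_hours": rec.total_sleep_hours if rec.scored else np.nan,
            "wake_time": rec.wake_time,
        })
    return pd.DataFrame(rows)


def summarize_sleep(
    nights_by_resident: dict[str, pd.DataFrame],
    phase: str,
    exclude: set[str] | None = None,
) -> SleepSummary:
    """Group sleep summary: per-resident medians over nights, then the group
    median over residents. ``exclude`` supports leave-one-out reanalysis
    (e.g. dropping a resident on sleep medication)."""
    exclude = exclude or set()
    per_res = {"n_disturbances": [], "median_bout_minutes": [], "total_sleep_hours": []}
    n_res = 0
    for rid, df in nights_by_resident.items():
        if rid in exclude:
            continue
        scored = df.dropna(subset=["n_disturbances"])
        if scored.empty:
            continue
        n_res += 1
        for col in per_res:
            per_res[col].append(float(scored[col].median()))
    if n_res == 0:
        raise SleepError("no scored nights in any included resident")
    return SleepSummary(
        phase=phase,
        median_disturbances=float(np.median(per_res["n_disturbances"])),
        median_bout_minutes=float(np.median(per_res["median_bout_minutes"])),
        median_total_sleep_hours=float(np.median(per_res["total_sleep_hours"])),
        n_residents=n_res,
    )
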