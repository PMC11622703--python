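"""Nonparametric circadian rest-activity metrics: IS, IV, RA and sundowning.

All metrics operate on a per-resident activity series (percent activity per
15-minute epoch, tz-aware DatetimeIndex) binned to hourly means first, the
standard convention in rest-activity research:

* interdaily stability IS = N * sum_h (xbar_h - xbar)^2 / (p * sum_i (x_i - xbar)^2)
  — the fraction of total variance explained by the average 24-hour profile
  (p = 24 hourly bins); 1 for a perfectly repeated daily pattern.
* intradaily variability IV = N * sum (x_i - x_{i-1})^2 / ((N-1) * sum (x_i - xbar)^2)
  — normalized mean squared successive difference; higher = more fragmented.
  The theoretical maximum is 4 (strict alternation); typical human data fall
  between 0 and 2.
* relative amplitude RA = (M10 - L5) / (M10 + L5) where M10 / L5 are the
  means of the 10 most / 5 least active *consecutive* hours of the average
  day (windows wrap midnight).

Missing data: hours with under 50% epoch coverage are dropped, and all sums
run over the available hours with N adjusted; IV uses only truly consecutive
hour pairs. Zero-variance series leave the metrics undefined (NaN).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd


class CircadianError(ValueError):
    """Series unsuitable for the requested rhythm metric."""


@dataclass(frozen=True)
class RhythmMetrics:
    IS: float
    IV: float
    RA: float
    M10: float
    L5: float
    n_days: int


@dataclass(frozen=True)
class SundowningResult:
    phase: str
    sunset_time: dt.time
    window_hours: float
    mean_activity_pct: float


def hourly_means(series: pd.Series, min_coverage: float = 0.5) -> pd.Series:
    """Hourly means of an epoch-level series, dropping poorly covered hours.

    Coverage is the answered fraction of the hour's epoch slots (4 slots for
    15-minute epochs); hours below ``min_coverage`` become NaN.
    """
    if series.empty:
        raise CircadianError("empty activity series")
    vals = series.dropna()
    epoch_minutes = 15
    if len(series.index) >= 2:
        step = (series.index[1] - series.index[0]).total_seconds() / 60
        if step > 0:
            epoch_minutes = int(round(step))
    slots_per_hour = max(1, 60 // epoch_minutes)
    grp = vals.groupby(vals.index.floor("h"))
    means = grp.mean()
    counts = grp.size()
    means[counts < min_coverage * slots_per_hour] = np.nan
    full = pd.date_range(series.index.min().floor("h"),
                         series.index.max().floor("h"), freq="h",
                         tz=series.index.tz)
    return means.reindex(full)


def interdaily_stability(series: pd.Series, min_days: int = 2) -> float:
    """IS in [0, 1]; NaN when total variance is zero (flagged undefined)."""
    hourly = hourly_means(series)
    x = hourly.dropna()
    n_days = len(np.unique(x.index.date))
    if n_days < min_days:
        raise CircadianError(f"IS needs >= {min_days} days of data, got {n_days}")
    v = x.to_numpy(dtype=float)
    xbar = v.mean()
    sst = ((v - xbar) ** 2).sum()
    if sst == 0:
        return float("nan")
    hour_means = x.groupby(x.index.hour).mean().to_numpy()
    p = hour_means.size
    n = v.size
    ssb = ((hour_means - xbar) ** 2).sum()
    return float(n * ssb / (p * sst))


def intradaily_variability(series: pd.Series) -> float:
    """IV >= 0; NaN when variance is zero. Only consecutive-hour pairs count."""
    hourly = hourly_means(series)
    x = hourly.to_numpy(dtype=float)
    valid = ~np.isnan(x)
    if valid.sum() < 2:
        raise CircadianError("IV needs >= 2 hourly values")
    v = x[valid]
    xbar = v.mean()
    sst = ((v - xbar) ** 2).sum()
    if sst == 0:
        return float("nan")
    pair = valid[1:] & valid[:-1]
    m = pair.sum()
    if m == 0:
        return float("nan")
    d2 = (x[1:][pair] - x[:-1][pair]) ** 2
    n = v.size
    # Generalizes N * sum(d^2) / ((N-1) * SST): mean squared successive
    # difference over available pairs, over variance.
    return float((d2.sum() / m) / (sst / n))


def average_day_profile(series: pd.Series) -> np.ndarray:
    """Mean activity per hour-of-day (24 values) over the analysis span."""
    hourly = hourly_means(series).dropna()
    prof = hourly.groupby(hourly.index.hour).mean()
    if len(prof) < 24:
        raise CircadianError(f"average day profile incomplete: {len(prof)}/24 hours")
    return prof.sort_index().to_numpy(dtype=float)


def _best_window_mean(profile: np.ndarray, width: int, take_max: bool) -> float:
    wrapped = np.concatenate([profile, profile[: width - 1]])
    sums = np.convolve(wrapped, np.ones(width), mode="valid")[:24]
    return float((sums.max() if take_max else sums.min()) / width)


def relative_amplitude(series: pd.Series) -> tuple[float, float, float]:
    """(RA, M10, L5) on the average 24-hour profile; NaN RA when M10+L5 = 0."""
    profile = average_day_profile(series)
    m10 = _best_window_mean(profile, 10, take_max=True)
    l5 = _best_window_mean(profile, 5, take_max=False)
    denom = m10 + l5
    ra = float("nan") if denom == 0 else (m10 - l5) / denom
    return float(ra), m10, l5


def rhythm_metrics(series: pd.Series) -> RhythmMetrics:
    """All three nonparametric metrics for one resident over one phase."""
    ra, m10, l5 = relative_amplitude(series)
    return RhythmMetrics(
        IS=interdaily_stability(series),
        IV=intradaily_variability(series),
        RA=ra,
        M10=m10,
        L5=l5,
        n_days=len(np.unique(series.dropna().index.date)),
    )


#: Configured sunset times per phase (the study months' approximate sunsets).
DEFAULT_SUNSET_BY_PHASE = {
    "baseline": dt.time(20, 0),
    "weeks5_10": dt.time(21, 0),
    "weeks10_16": dt.time(22, 0),
}


def sundowning_activity(
    series: pd.Series,
    phase: str,
    sunset_config: dict[str, dt.time] | None = None,
    window_hours: float = 4.0,
) -> SundowningResult:
    """Mean activity in the pre-sunset window, the sundowning proxy.

    The window is [sunset - window_hours, sunset) in local civil time, pooled
    over every day of the phase.
    """
    sunsets = sunset_config or DEFAULT_SUNSET_BY_PHASE
    if phase not in sunsets:
        raise CircadianError(f"no configured sunset time for phase {phase!r}")
    sunset = sunsets[phase]
    vals = series.dropna()
    if vals.empty:
        raise CircadianError("empty activity series")
    minutes = vals.index.hour * 60 + vals.index.minute
    end = sunset.hour * 60 + sunset.minute
    start = end - int(window_hours * 60)
    in_window = (minutes >= start) & (minutes < end)
    if not in_window.any():
        raise CircadianError("no epochs fall inside the sundowning window")
    return SundowningResult(
        phase=phase,
        sunset_time=sunset,
        window_hours=window_hours,
        mean_activity_pct=float(vals[in_window].mean()),
    )
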