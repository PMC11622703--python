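"""Study phase plan: calendar weeks mapped to analysis phases.

The trial runs 16 weeks: a static-lighting baseline (weeks 1-4), then the
dynamic program, analysed as a midpoint (weeks 5-10) and an end-of-
intervention (weeks 10-16) phase. Printed week ranges share week 10; the
plan uses half-open week ranges [5, 10) and [10, 17) so no week is counted
in two phases.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd


class PhaseError(ValueError):
    """Invalid phase plan or out-of-plan query."""


#: (label, first week, one-past-last week), weeks numbered from 1.
DEFAULT_PHASES: tuple[tuple[str, int, int], ...] = (
    ("baseline", 1, 5),
    ("weeks5_10", 5, 10),
    ("weeks10_16", 10, 17),
)


@dataclass(frozen=True)
class PhasePlan:
    """Ordered study phases over a 16-week trial starting at ``start_date``."""

    start_date: dt.date
    phases: tuple[tuple[str, int, int], ...] = DEFAULT_PHASES

    def __post_init__(self) -> None:
        prev_end = 1
        for label, a, b in self.phases:
            if a >= b:
                raise PhaseError(f"phase {label!r} has empty week range [{a}, {b})")
            if a != prev_end:
                raise PhaseError(f"phase {label!r} does not abut the previous phase")
            prev_end = b

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.phases]

    @property
    def n_weeks(self) -> int:
        return self.phases[-1][2] - 1

    def week_of(self, ts) -> int:
        """1-based study week containing a timestamp or date."""
        d = ts.date() if hasattr(ts, "date") else ts
        return (d - self.start_date).days // 7 + 1

    def phase_of(self, ts) -> str | None:
        """Phase label for a timestamp, or None outside the plan."""
        week = self.week_of(ts)
        for label, a, b in self.phases:
            if a <= week < b:
                return label
        return None

    def phase_range(self, label: str):
        """(start, end) timestamps (half-open) of a phase, naive local."""
        for lab, a, b in self.phases:
            if lab == label:
                start = self.start_date + dt.timedelta(weeks=a - 1)
                end = self.start_date + dt.timedelta(weeks=b - 1)
                return pd.Timestamp(start), pd.Timestamp(end)
        raise PhaseError(f"unknown phase {label!r}")

    def slice_phase(self, series: pd.Series, label: str) -> pd.Series:
        """Restrict a time-indexed series to one phase (local civil time)."""
        start, end = self.phase_range(label)
        idx = series.index
        if idx.tz is not None:
            start = start.tz_localize(idx.tz)
            end = end.tz_localize(idx.tz)
        return series[(idx >= start) & (idx < end)]

    def weeks_in_phase(self, label: str) -> list[int]:
        for lab, a, b in self.phases:
            if lab == label:
                return list(range(a, b))
        raise PhaseError(f"unknown phase {label!r}")


def aggregate_phase(
    values: pd.DataFrame,
    plan: PhasePlan,
    aggregator: str = "mean",
    week_col: str = "week",
    value_col: str = "value",
) -> pd.DataFrame:
    """Collapse per-week values to one value per resident per phase.

    ``values`` holds columns resident_id, ``week_col``, ``value_col``.
    ``aggregator`` is "mean" (default for well-being scores and activity
    metrics) or "median" (default for skewed sleep counts). Weeks outside the
    plan are left untouched by dropping them from the output only.
    """
    if aggregator not in ("mean", "median"):
        raise PhaseError(f"aggregator must be mean or median, got {aggregator!r}")
    rows = []
    for label in plan.labels:
        weeks = set(plan.weeks_in_phase(label))
        sub = values[values[week_col].isin(weeks)]
        if sub.empty:
            raise PhaseError(f"no data in phase {label!r}")
        agg = sub.groupby("resident_id")[value_col].agg(aggregator)
        for rid, v in agg.items():
            rows.append({"resident_id": rid, "phase": label, value_col: v})
    return pd.DataFrame(rows)
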