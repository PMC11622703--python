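"""Lighting program representation and melanopic dose quantities.

The intervention luminaires run a fixed daily schedule of photopic setpoints
(illuminance at eye level, correlated colour temperature, drive output).
Because a fixed LED spectrum implies fixed spectral conversion factors, the
circadian quantities are scalar transforms of photopic illuminance:

* melanopic EDI  = illuminance x melanopic ratio (the ratio is constant for
  a fixed spectrum),
* circadian light (CL_A) = illuminance x cl_a_per_lux, then the circadian
  stimulus (CS) follows the Rea saturation model

      CS = 0.7 * (1 - 1 / (1 + (CL_A / 355.7)**1.1026))

  which rises from 0 towards an asymptote of 0.7.

Both conversion factors are anchored on the 260-lux setpoint of the shipped
dynamic program (CS 0.404, M-EDI 331 lx) rather than integrated from a
spectral power distribution; a single anchored ratio reproduces the published
300-lux CS to 3 decimals and leaves a ~0.002 residual at 550 lux, where the
correlated colour temperature (and hence the true spectrum) differs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

# Rea circadian-stimulus saturation model constants.
CS_SATURATION = 0.7
CS_HALF_SATURATION_CLA = 355.7
CS_EXPONENT = 1.1026

# Anchor row of the dynamic program: 260 lx -> CS 0.404, M-EDI 331 lx.
ANCHOR_ILLUMINANCE_LUX = 260.0
ANCHOR_CS = 0.404
ANCHOR_MEDI_LUX = 331.0

#: Melanopic EDI per photopic lux for the fixed intervention spectrum.
DEFAULT_MELANOPIC_RATIO = ANCHOR_MEDI_LUX / ANCHOR_ILLUMINANCE_LUX

STUDY_PHASES = ("baseline", "weeks5_10", "weeks10_16")


class LightingError(ValueError):
    """Invalid lighting input (empty schedule, out-of-range quantity)."""


@dataclass(frozen=True)
class ScheduleEntry:
    """One block of the daily lighting program, active on [start, end)."""

    start: dt.time
    end: dt.time
    illuminance: float  # lux at eye level
    cct: float  # kelvin
    output_pct: float  # luminaire drive, %

    def __post_init__(self) -> None:
        if self.illuminance <= 0:
            raise LightingError(f"illuminance must be positive, got {self.illuminance}")
        if not 1000 <= self.cct <= 20000:
            raise LightingError(f"cct {self.cct} K outside plausible range [1000, 20000]")


@dataclass(frozen=True)
class LightingMetrics:
    illuminance: float
    cl_a: float
    cs: float
    m_edi: float
    melanopic_ratio: float
    cl_a_per_lux: float


def circadian_stimulus(cl_a: float) -> float:
    """Circadian stimulus for circadian light ``cl_a`` (saturating at 0.7)."""
    cl = np.asarray(cl_a, dtype=float)
    if np.any(cl < 0):
        raise LightingError("cl_a must be nonnegative")
    out = CS_SATURATION * (
        1.0 - 1.0 / (1.0 + (cl / CS_HALF_SATURATION_CLA) ** CS_EXPONENT)
    )
    return float(out) if np.isscalar(cl_a) else out


def invert_cs(cs: float) -> float:
    """Closed-form inverse of :func:`circadian_stimulus` on (0, 0.7)."""
    if not 0.0 < cs < CS_SATURATION:
        raise LightingError(f"cs must lie in (0, {CS_SATURATION}), got {cs}")
    ratio = CS_SATURATION / (CS_SATURATION - cs) - 1.0
    return CS_HALF_SATURATION_CLA * ratio ** (1.0 / CS_EXPONENT)


#: Circadian light per photopic lux, anchored at the 260-lux setpoint.
DEFAULT_CLA_PER_LUX = invert_cs(ANCHOR_CS) / ANCHOR_ILLUMINANCE_LUX


def melanopic_edi(illuminance: float, melanopic_ratio: float = DEFAULT_MELANOPIC_RATIO) -> float:
    """Melanopic equivalent daylight illuminance (lux) for a photopic level."""
    if illuminance <= 0 or melanopic_ratio <= 0:
        raise LightingError("illuminance and melanopic_ratio must be positive")
    return illuminance * melanopic_ratio


def lighting_metrics(
    illuminance: float,
    melanopic_ratio: float = DEFAULT_MELANOPIC_RATIO,
    cl_a_per_lux: float = DEFAULT_CLA_PER_LUX,
) -> LightingMetrics:
    """All melanopic quantities for a photopic illuminance under the fixed spectrum."""
    cl_a = illuminance * cl_a_per_lux
    return LightingMetrics(
        illuminance=illuminance,
        cl_a=cl_a,
        cs=circadian_stimulus(cl_a),
        m_edi=melanopic_edi(illuminance, melanopic_ratio),
        melanopic_ratio=melanopic_ratio,
        cl_a_per_lux=cl_a_per_lux,
    )


def _parse_time(value) -> dt.time:
    if isinstance(value, dt.time):
        return value
    return dt.time.fromisoformat(str(value))


def load_schedule(source) -> list[ScheduleEntry]:
    """Load a daily lighting schedule from a YAML file path or parsed list."""
    if isinstance(source, (str,)) or hasattr(source, "read"):
        with open(source) as fh:  # type: ignore[arg-type]
            raw = yaml.safe_load(fh)
    else:
        raw = source
    entries = [
        ScheduleEntry(
            start=_parse_time(e["start"]),
            end=_parse_time(e["end"]),
            illuminance=float(e["illuminance"]),
            cct=float(e["cct"]),
            output_pct=float(e["output_pct"]),
        )
        for e in raw
    ]
    entries.sort(key=lambda e: e.start)
    for a, b in zip(entries, entries[1:]):
        if a.end > b.start:
            raise LightingError(f"schedule entries overlap: {a} / {b}")
    if not entries:
        raise LightingError("schedule is empty")
    return entries


def default_dynamic_schedule() -> list[ScheduleEntry]:
    """The packaged dynamic (daylight-mimicking) program."""
    with resources.files("circalight.data").joinpath("schedule_dynamic.yaml").open() as fh:
        return load_schedule(yaml.safe_load(fh))


def schedule_lookup(t: dt.time, schedule: Sequence[ScheduleEntry]) -> ScheduleEntry:
    """Schedule entry active at clock time ``t``.

    Before the first block the first block's values are held; after the last
    block the last block's values are held (until lights-off, which the
    switch log governs).
    """
    if not schedule:
        raise LightingError("schedule is empty")
    for entry in schedule:
        if entry.start <= t < entry.end:
            return entry
    if t < schedule[0].start:
        return schedule[0]
    return schedule[-1]


@dataclass(frozen=True)
class ExposureSummary:
    phase: str
    pct_time_in_rooms: float
    pct_lights_on_while_present: float
    pct_dynamic_exposure: float


def switch_state_per_epoch(
    switch_log: pd.DataFrame, epochs: pd.DatetimeIndex, epoch_minutes: int = 15
) -> pd.Series:
    """Fraction of each epoch during which the room lights were on.

    ``switch_log`` has columns timestamp, room_id, state ("on"/"off"); the
    state before the first event is taken as the complement of that event.
    Fractions are exact for the step function implied by the log.
    """
    if switch_log.empty:
        raise LightingError("switch log is empty")
    log = switch_log.sort_values("timestamp")
    times = pd.DatetimeIndex(log["timestamp"])
    states = (log["state"].str.lower() == "on").to_numpy()
    initial = not states[0]

    step = pd.Timedelta(minutes=epoch_minutes)
    out = np.empty(len(epochs))
    # Per-epoch overlap with "on" intervals; logs are short so a scan is fine.
    on_starts, on_ends = [], []
    cur_on = initial
    cur_start = min(times[0], epochs[0]) - pd.Timedelta(days=1)
    for t, s in zip(times, states):
        if s and not cur_on:
            cur_start, cur_on = t, True
        elif not s and cur_on:
            on_starts.append(cur_start)
            on_ends.append(t)
            cur_on = False
    if cur_on:
        on_starts.append(cur_start)
        on_ends.append(max(times[-1], epochs[-1]) + step + pd.Timedelta(days=1))
    if on_starts:
        s_arr = pd.DatetimeIndex(on_starts).asi8.astype(float)
        e_arr = pd.DatetimeIndex(on_ends).asi8.astype(float)
        ep_s = epochs.asi8.astype(float)
        ep_e = ep_s + step.value
        overlap = np.clip(
            np.minimum(ep_e[:, None], e_arr[None, :]) - np.maximum(ep_s[:, None], s_arr[None, :]),
            0.0,
            None,
        ).sum(axis=1)
        out = overlap / step.value
    else:
        out[:] = 0.0
    return pd.Series(out, index=epochs, name="on_fraction")


def exposure_summary(
    occupancy: pd.Series,
    switch_log: pd.DataFrame,
    phase: str,
    epoch_minutes: int = 15,
) -> ExposureSummary:
    """Dynamic-lighting exposure for one study phase.

    ``occupancy`` is the per-epoch fraction of time the resident was present
    in sensored rooms. Time away from the rooms is attributed to the common
    areas, which run fully dynamic lighting during the intervention phases,
    so dynamic exposure = (present with lights on) + (absent). The baseline
    phase is fully static lighting by design, hence 0% exposure.

    Within an epoch, presence and switch state are combined as a product of
    fractions; this is exact whenever the lights do not toggle inside the
    epoch (the usual case for 15-minute epochs).
    """
    if phase not in STUDY_PHASES:
        raise LightingError(f"unknown phase {phase!r}")
    occupancy = occupancy.dropna()
    if occupancy.empty:
        raise LightingError("occupancy series is empty")
    if switch_log.empty:
        raise LightingError("switch log is empty")
    # Switch state holds forward from each event, so the log covers the phase
    # as long as it starts no later than the phase does.
    log_times = pd.DatetimeIndex(switch_log["timestamp"])
    if log_times.min() > occupancy.index.max() + pd.Timedelta(minutes=epoch_minutes):
        raise LightingError("switch log does not cover the phase")

    on_frac = switch_state_per_epoch(switch_log, pd.DatetimeIndex(occupancy.index), epoch_minutes)
    present = occupancy.to_numpy(dtype=float)
    present_and_on = present * on_frac.to_numpy()

    pct_in_rooms = 100.0 * present.mean()
    tot_present = present.sum()
    pct_on_while_present = 100.0 * present_and_on.sum() / tot_present if tot_present > 0 else 0.0
    if phase == "baseline":
        pct_dynamic = 0.0
    else:
        pct_dynamic = 100.0 * (present_and_on + (1.0 - present)).mean()
    return ExposureSummary(
        phase=phase,
        pct_time_in_rooms=pct_in_rooms,
        pct_lights_on_while_present=pct_on_while_present,
        pct_dynamic_exposure=pct_dynamic,
    )
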