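"""Raw radar frame ingestion into epoch-level activity and occupancy.

Frames are per-resident positional samples (timestamp, sensor_id,
resident_id, x, y) captured nominally at 8 Hz while the resident is inside a
sensored room. Processing:

1. Per-epoch translation: the Euclidean displacement of each consecutive
   frame pair is credited to the (clock-aligned, half-open) 15-minute epoch
   containing the *later* frame, so no displacement is lost at boundaries.
   Pairs separated by more than the absence-gap threshold are discarded — a
   long gap means the resident left the sensored rooms and the straight-line
   jump is not movement the sensor observed.
2. Normalization: each epoch total is divided by the running maximum epoch
   total seen so far for that resident (mode "running_max", the default), or
   by the series-wide maximum ("global_max"), giving percent activity in
   [0, 100]. Epochs without frames stay missing (NaN), never zero.
3. Occupancy: consecutive frames closer than the gap threshold form presence
   runs; each epoch's present fraction is the covered share of its span.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

FRAME_COLUMNS = ["timestamp", "sensor_id", "resident_id", "x", "y"]
DEFAULT_EPOCH_MINUTES = 15
DEFAULT_GAP_THRESHOLD_S = 60.0


class IngestError(ValueError):
    """Malformed frame stream or epoch request."""


def read_frames_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return df[FRAME_COLUMNS]


def write_frames_csv(frames: pd.DataFrame, path) -> None:
    frames.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S.%f%z")


def read_frames_jsonl(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(json.loads(line))
    df = pd.DataFrame(rows, columns=FRAME_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    return df


def write_frames_jsonl(frames: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in frames.itertuples(index=False):
            fh.write(json.dumps({
                "timestamp": row.timestamp.isoformat(),
                "sensor_id": row.sensor_id,
                "resident_id": row.resident_id,
                "x": round(float(row.x), 4),
                "y": round(float(row.y), 4),
            }) + "\n")


def _pair_displacements(frames: pd.DataFrame, gap_threshold_s: float):
    """(later-frame timestamps, displacement magnitudes) for retained pairs."""
    ts = pd.DatetimeIndex(frames["timestamp"])
    x = frames["x"].to_numpy(dtype=float)
    y = frames["y"].to_numpy(dtype=float)
    if len(ts) < 2:
        return ts[:0], np.empty(0)
    dt_s = np.diff(ts.asi8) / 1e9
    disp = np.hypot(np.diff(x), np.diff(y))
    keep = dt_s <= gap_threshold_s
    return ts[1:][keep], disp[keep]


def total_translation(
    frames: pd.DataFrame,
    epoch_start: pd.Timestamp,
    epoch_end: pd.Timestamp,
    gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S,
) -> float:
    """Summed x-y displacement (metres) credited to [epoch_start, epoch_end)."""
    frames = frames.sort_values("timestamp")
    later_ts, disp = _pair_displacements(frames, gap_threshold_s)
    mask = (later_ts >= epoch_start) & (later_ts < epoch_end)
    return float(disp[mask].sum())


def bin_translations(
    frames: pd.DataFrame,
    epoch_minutes: int = DEFAULT_EPOCH_MINUTES,
    gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S,
) -> pd.Series:
    """Per-epoch raw translation (metres) on a complete clock-aligned grid.

    Epochs containing at least one frame get a (possibly zero) total; epochs
    with no frames are NaN — missingness is explicit, never coded as rest.
    """
    if frames.empty:
        raise IngestError("empty frame stream")
    frames = frames.sort_values("timestamp")
    ts = pd.DatetimeIndex(frames["timestamp"])
    freq = f"{epoch_minutes}min"
    grid = pd.date_range(ts.min().floor(freq), ts.max().floor(freq), freq=freq)
    later_ts, disp = _pair_displacements(frames, gap_threshold_s)
    totals = pd.Series(0.0, index=grid, name="raw_translation")
    if len(later_ts):
        sums = pd.Series(disp).groupby(later_ts.floor(freq)).sum()
        totals.loc[sums.index] = sums.to_numpy()
    has_frames = pd.Series(True, index=ts.floor(freq)).groupby(level=0).any()
    totals[~totals.index.isin(has_frames.index)] = np.nan
    return totals


def normalize_activity(raw: pd.Series, mode: str = "running_max") -> pd.DataFrame:
    """Percent activity per epoch from raw per-epoch translations.

    running_max: activity(e) = 100 * raw(e) / max(raw up to and including e);
    global_max: divide by the series-wide maximum instead. A zero maximum
    yields 0% (no movement observed yet). Raw totals must be nonnegative.
    """
    vals = raw.to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] < 0):
        raise IngestError("negative raw translation")
    if mode == "running_max":
        denom = np.fmax.accumulate(np.where(np.isnan(vals), -np.inf, vals))
        denom[denom == -np.inf] = np.nan
    elif mode == "global_max":
        denom = np.full_like(vals, np.nanmax(vals))
    else:
        raise IngestError(f"unknown normalization mode {mode!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * vals / denom
    pct[(denom == 0) & ~np.isnan(vals)] = 0.0
    return pd.DataFrame({
        "activity_pct": pct,
        "raw_translation": vals,
    }, index=raw.index)


def presence_runs(
    frames: pd.DataFrame, gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Maximal intervals during which frames arrive within the gap threshold."""
    ts = pd.DatetimeIndex(frames.sort_values("timestamp")["timestamp"])
    if len(ts) == 0:
        return []
    gaps = np.diff(ts.asi8) / 1e9
    breaks = np.flatnonzero(gaps > gap_threshold_s)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(ts) - 1]])
    return [(ts[a], ts[b]) for a, b in zip(starts, ends)]


def occupancy_fraction(
    frames: pd.DataFrame,
    room_map: dict[str, str],
    epoch_minutes: int = DEFAULT_EPOCH_MINUTES,
    gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S,
) -> pd.DataFrame:
    """Per-epoch present fraction (and modal room) for one resident.

    Unmapped sensor ids are an error: an unknown sensor means the room
    registry is stale, not that the resident vanished.
    """
    if frames.empty:
        raise IngestError("empty frame stream")
    unknown = set(frames["sensor_id"]) - set(room_map)
    if unknown:
        raise IngestError(f"unmapped sensor ids: {sorted(unknown)}")
    frames = frames.sort_values("timestamp")
    runs = presence_runs(frames, gap_threshold_s)
    freq = f"{epoch_minutes}min"
    ts = pd.DatetimeIndex(frames["timestamp"])
    grid = pd.date_range(ts.min().floor(freq), ts.max().floor(freq), freq=freq)
    step_ns = pd.Timedelta(minutes=epoch_minutes).value

    ep_s = grid.asi8.astype(float)
    ep_e = ep_s + step_ns
    covered = np.zeros(len(grid))
    for a, b in runs:
        overlap = np.clip(np.minimum(ep_e, float(b.value)) - np.maximum(ep_s, float(a.value)),
                          0.0, None)
        covered += overlap
    fraction = covered / step_ns

    rooms = frames["sensor_id"].map(room_map)
    modal = rooms.groupby(ts.floor(freq)).agg(lambda s: s.mode().iloc[0])
    out = pd.DataFrame({"present_fraction": fraction}, index=grid)
    out["room_id"] = modal.reindex(grid)
    return out


def write_epoch_csv(table: pd.DataFrame | pd.Series, path) -> None:
    """Write an epoch-indexed activity/occupancy table with ISO timestamps."""
    df = table.to_frame() if isinstance(table, pd.Series) else table
    df = df.rename_axis("epoch_start")
    df.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S%z")


def read_epoch_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["epoch_start"] = pd.to_datetime(df["epoch_start"], format="ISO8601")
    return df.set_index("epoch_start")


def activity_series(
    frames: pd.DataFrame,
    epoch_minutes: int = DEFAULT_EPOCH_MINUTES,
    gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S,
    mode: str = "running_max",
) -> pd.DataFrame:
    """Frame stream -> normalized activity (the full stage-1 transform)."""
    raw = bin_translations(frames, epoch_minutes, gap_threshold_s)
    return normalize_activity(raw, mode)
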