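"""Seeded synthetic cohort generator with known circadian ground truth.

Care-home radar and well-being data are not publicly shareable, so every
downstream stage is exercised against fully synthetic cohorts whose
generating parameters are known exactly:

* Activity: a clipped cosinor — activity(t) = clip(mesor + amplitude *
  cos(2*pi*(t - acrophase)/24) + N(0, noise_sd), 0, 100) per 15-minute
  epoch — plus night disturbance bouts: per night a Poisson count of bouts,
  each starting uniformly inside the bed window with exponentially
  distributed duration and elevated activity.
* Presence: a two-state semi-Markov process (exponential dwell times in
  "in sensored rooms" / "in common areas") tuned to a target occupancy
  fraction; residents are always in their rooms during the bed window.
* Frames: positional samples emitted only while present. Mode "sparse"
  (default) emits one frame per ``frame_interval_s`` with the epoch's target
  translation spread evenly over its frame pairs — epoch totals and presence
  runs are preserved exactly at a tractable data volume. Mode "burst" emits
  an 8 Hz movement burst each epoch plus sparse keep-alive frames,
  mimicking the native capture rate; use it on short spans.
* Switch log: per presence session outside the bed window the room lights
  turn on with probability ``lights_on_given_present``, off at session end.
* QUALIDEM panel: weekly item responses drawn around per-resident subscale
  latent means that drift week to week and shift under injected effects.

Intervention effects are injected at phase boundaries in *metric* space:
an effect on "RA" re-solves the cosinor amplitude so the noiseless relative
amplitude shifts by exactly delta; "IS" rescales the noise SD via the
variance decomposition IS = V24 / (V24 + sigma_h^2); "sleep_disturbances"
shifts the nightly Poisson mean; a QUALIDEM subscale letter shifts that
subscale's latent mean by delta week-level SDs.

Seeding: one master seed; resident k uses ``SeedSequence([master, k])``,
split into independent child streams (activity noise, disturbances,
presence, switches); the QUALIDEM panel uses ``SeedSequence([master,
100000 + k])``. Identical seeds give byte-identical datasets.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .phases import PhasePlan
from .qualidem import ItemMap, load_item_map

STUDY_PHASES = ("baseline", "weeks5_10", "weeks10_16")


class SyntheticError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class ResidentProfile:
    """Ground-truth behavioural parameters for one simulated resident."""

    resident_id: str
    mesor: float = 30.0  # activity %
    amplitude: float = 45.0  # activity %; clipped at 0 -> quiet overnight plateau
    acrophase: float = 15.0  # hours from midnight (peak activity mid-afternoon)
    noise_sd: float = 3.0  # activity %
    n_disturbances_per_night: float = 1.5  # Poisson mean
    disturbance_bout_minutes: float = 20.0  # exponential mean
    bed_window: tuple[dt.time, dt.time] = (dt.time(22, 0), dt.time(7, 0))
    room_occupancy_fraction: float = 0.7
    lights_on_given_present: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.mesor <= 100 and self.amplitude >= 0):
            raise SyntheticError("mesor must be in [0,100] and amplitude nonnegative")
        if self.noise_sd < 0 or self.n_disturbances_per_night < 0:
            raise SyntheticError("noise_sd and disturbance count must be nonnegative")
        if self.disturbance_bout_minutes <= 0:
            raise SyntheticError("disturbance_bout_minutes must be positive")
        start, end = self.bed_window
        if start < dt.time(18, 0) or end > dt.time(12, 0):
            raise SyntheticError("bed window must start in the evening and end in the morning")
        for frac in (self.room_occupancy_fraction, self.lights_on_given_present):
            if not 0 <= frac <= 1:
                raise SyntheticError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class InterventionEffect:
    """A signed ground-truth shift of one metric during one phase."""

    parameter: str  # "RA" | "IS" | "sleep_disturbances" | QUALIDEM subscale letter
    phase: str
    delta: float

    def __post_init__(self) -> None:
        if self.phase not in STUDY_PHASES:
            raise SyntheticError(f"unknown phase {self.phase!r}; expected one of {STUDY_PHASES}")


@dataclass
class CohortConfig:
    start_date: dt.date = dt.date(2023, 3, 6)  # an arbitrary Monday
    n_weeks: int = 16
    epoch_minutes: int = 15
    tz: str = "Europe/London"
    frame_mode: str = "sparse"  # "sparse" | "burst"
    frame_interval_s: float = 45.0
    burst_rate_hz: float = 8.0
    burst_seconds: float = 20.0
    present_dwell_minutes: float = 60.0
    translation_scale_m: float = 40.0  # epoch metres at 100% activity
    qualidem_week_sd: float = 0.25  # week-to-week latent drift (rating units)
    qualidem_item_sd: float = 0.6
    qualidem_resident_sd: float = 0.3
    qualidem_latent_base: float = 1.8


@dataclass
class CohortDataset:
    frames: dict[str, pd.DataFrame]
    switch_log: pd.DataFrame
    qualidem_panel: pd.DataFrame
    truth: dict
    room_map: dict[str, str]
    plan: PhasePlan
    config: CohortConfig


# ---------------------------------------------------------------------------
# Ground-truth metric algebra (used both to inject effects and by oracles)

def cosinor_hourly_profile(mesor: float, amplitude: float, acrophase: float,
                           epoch_minutes: int = 15) -> np.ndarray:
    """Noiseless hourly-mean 24h profile of the clipped cosinor."""
    slots = 60 // epoch_minutes
    t = (np.arange(24 * slots) * epoch_minutes) / 60.0
    vals = np.clip(mesor + amplitude * np.cos(2 * np.pi * (t - acrophase) / 24.0), 0, 100)
    return vals.reshape(24, slots).mean(axis=1)


def _window_mean(profile: np.ndarray, width: int, take_max: bool) -> float:
    wrapped = np.concatenate([profile, profile[: width - 1]])
    sums = np.convolve(wrapped, np.ones(width), mode="valid")[:24]
    return float((sums.max() if take_max else sums.min()) / width)


def cosinor_ra(mesor: float, amplitude: float, acrophase: float) -> float:
    """Noiseless relative amplitude implied by a cosinor parameterisation."""
    prof = cosinor_hourly_profile(mesor, amplitude, acrophase)
    m10 = _window_mean(prof, 10, True)
    l5 = _window_mean(prof, 5, False)
    return (m10 - l5) / (m10 + l5) if (m10 + l5) > 0 else float("nan")


def expected_hourly_profile(profile: ResidentProfile, amplitude: float | None = None,
                            disturbance_rate: float | None = None,
                            epoch_minutes: int = 15) -> np.ndarray:
    """Expected hourly activity profile of the full generator (noise-free mean).

    Adds the night-disturbance regime to the clipped cosinor: a bed-window
    epoch is disturbed with probability q = rate * E[bout epochs] / window
    epochs, and a disturbed epoch reads max(base, U(40, 90)) (mean 65). This
    is the generator's own ground truth for profile-level metrics such as RA.
    """
    a = profile.amplitude if amplitude is None else amplitude
    rate = (profile.n_disturbances_per_night if disturbance_rate is None
            else disturbance_rate)
    slots = 60 // epoch_minutes
    t = (np.arange(24 * slots) * epoch_minutes) / 60.0
    base = np.clip(profile.mesor + a * np.cos(2 * np.pi * (t - profile.acrophase) / 24.0),
                   0, 100)
    bw_start = profile.bed_window[0].hour + profile.bed_window[0].minute / 60.0
    bw_end = profile.bed_window[1].hour + profile.bed_window[1].minute / 60.0
    in_bed = (t >= bw_start) | (t < bw_end)
    n_win = int(in_bed.sum())
    vals = base.copy()
    if rate > 0 and n_win > 0:
        e_bout_epochs = 1.0 / (1.0 - np.exp(-epoch_minutes / profile.disturbance_bout_minutes))
        q = min(1.0, rate * e_bout_epochs / n_win)
        level = 65.0  # mean disturbed-epoch activity, U(40, 90)
        vals[in_bed] = (1 - q) * base[in_bed] + q * np.maximum(base[in_bed], level)
    return vals.reshape(24, slots).mean(axis=1)


def expected_ra(profile: ResidentProfile, amplitude: float | None = None,
                disturbance_rate: float | None = None) -> float:
    """Ground-truth relative amplitude of the generator's expected profile."""
    prof = expected_hourly_profile(profile, amplitude, disturbance_rate)
    m10 = _window_mean(prof, 10, True)
    l5 = _window_mean(prof, 5, False)
    return (m10 - l5) / (m10 + l5) if (m10 + l5) > 0 else float("nan")


def amplitude_for_ra(profile: ResidentProfile, target_ra: float) -> float:
    """Amplitude whose expected-profile RA equals ``target_ra`` (exact solve)."""
    if not 0 < target_ra < 1:
        raise SyntheticError(f"target RA must lie in (0, 1), got {target_ra}")
    hi = 2.0 * max(profile.mesor, 100 - profile.mesor)
    f = lambda a: expected_ra(profile, a) - target_ra
    if f(hi) < 0:
        raise SyntheticError(f"RA {target_ra} unreachable for mesor {profile.mesor}")
    return float(brentq(f, 1e-9, hi, xtol=1e-10))


def noise_sd_for_is(mesor: float, amplitude: float, acrophase: float,
                    target_is: float, epoch_minutes: int = 15) -> float:
    """Noise SD whose expected interdaily stability is ``target_is``.

    Uses IS ~= V24 / (V24 + sigma^2 / slots_per_hour) where V24 is the
    population variance of the hourly cosinor profile.
    """
    if not 0 < target_is <= 1:
        raise SyntheticError(f"target IS must lie in (0, 1], got {target_is}")
    prof = cosinor_hourly_profile(mesor, amplitude, acrophase, epoch_minutes)
    v24 = float(prof.var())
    slots = 60 // epoch_minutes
    if target_is == 1.0:
        return 0.0
    return float(np.sqrt(slots * v24 * (1.0 / target_is - 1.0)))


def _phase_generator_params(profile: ResidentProfile,
                            effects: list[InterventionEffect]) -> dict[str, dict]:
    """Per-phase (amplitude, noise_sd, disturbance rate) after effect injection."""
    params = {
        ph: {
            "amplitude": profile.amplitude,
            "noise_sd": profile.noise_sd,
            "disturbance_rate": profile.n_disturbances_per_night,
        }
        for ph in STUDY_PHASES
    }
    for eff in effects:
        p = params[eff.phase]
        if eff.parameter == "RA":
            base_ra = expected_ra(profile)
            p["amplitude"] = amplitude_for_ra(profile, base_ra + eff.delta)
        elif eff.parameter == "IS":
            base_is = 1.0
            if profile.noise_sd > 0:
                prof = cosinor_hourly_profile(profile.mesor, profile.amplitude,
                                              profile.acrophase)
                v24 = float(prof.var())
                base_is = v24 / (v24 + profile.noise_sd**2 / 4.0)
            p["noise_sd"] = noise_sd_for_is(profile.mesor, p["amplitude"],
                                            profile.acrophase,
                                            min(1.0, base_is + eff.delta))
        elif eff.parameter == "sleep_disturbances":
            p["disturbance_rate"] = max(0.0, p["disturbance_rate"] + eff.delta)
        elif len(eff.parameter) == 1 and eff.parameter.isalpha():
            continue  # QUALIDEM effect, handled by the panel generator
        else:
            raise SyntheticError(f"unknown effect parameter {eff.parameter!r}")
    return params


# ---------------------------------------------------------------------------
# Epoch-level activity (the fast path all Monte-Carlo work runs on)

def _validate_date_range(date_range) -> tuple[dt.date, dt.date]:
    start, end = date_range
    if (end - start).days < 1:
        raise SyntheticError("date_range must cover at least one whole day")
    return start, end


def simulate_activity_epochs(
    profile: ResidentProfile,
    phase_effects: list[InterventionEffect],
    date_range: tuple[dt.date, dt.date],
    seed,
    plan: PhasePlan | None = None,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Ground-truth epoch table: activity %, raw translation, disturbance flag.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    start, end = _validate_date_range(date_range)
    cfg = config or CohortConfig()
    plan = plan or PhasePlan(start_date=start)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_noise, rng_dist = (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(2))

    idx = pd.date_range(
        pd.Timestamp(start, tz=cfg.tz), pd.Timestamp(end, tz=cfg.tz),
        freq=f"{cfg.epoch_minutes}min", inclusive="left",
    )
    hours = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    params = _phase_generator_params(profile, phase_effects)
    # Vectorized week -> phase mapping (local civil dates).
    days = (idx.tz_localize(None).normalize() - pd.Timestamp(plan.start_date)).days
    weeks = np.asarray(days) // 7 + 1
    phase_of_epoch = np.full(len(idx), "baseline", dtype=object)
    for label, a, b in plan.phases:
        phase_of_epoch[(weeks >= a) & (weeks < b)] = label

    amplitude = np.empty(len(idx))
    noise_sd = np.empty(len(idx))
    for ph in STUDY_PHASES:
        m = phase_of_epoch == ph
        amplitude[m] = params[ph]["amplitude"]
        noise_sd[m] = params[ph]["noise_sd"]

    base = profile.mesor + amplitude * np.cos(2 * np.pi * (hours - profile.acrophase) / 24.0)
    activity = base + rng_noise.normal(0.0, 1.0, len(idx)) * noise_sd

    # Night disturbance bouts: per night, Poisson count of exponential bouts.
    disturbed = np.zeros(len(idx), dtype=bool)
    bw_start, bw_end = profile.bed_window
    night = start
    while night < end:
        ph = plan.phase_of(pd.Timestamp(night)) or "baseline"
        rate = params[ph]["disturbance_rate"]
        count = rng_dist.poisson(rate) if rate > 0 else 0
        win_start = pd.Timestamp(dt.datetime.combine(night, bw_start), tz=cfg.tz)
        win_end = pd.Timestamp(dt.datetime.combine(night + dt.timedelta(days=1), bw_end),
                               tz=cfg.tz)
        window_h = (win_end - win_start).total_seconds() / 3600.0
        for _ in range(count):
            start_h = rng_dist.uniform(0.0, window_h)
            dur_ep = max(1, int(np.ceil(
                rng_dist.exponential(profile.disturbance_bout_minutes) / cfg.epoch_minutes)))
            level = rng_dist.uniform(40.0, 90.0)
            t0 = win_start + pd.Timedelta(hours=start_h)
            t0 = t0.floor(f"{cfg.epoch_minutes}min")
            bout_ts = [t0 + k * pd.Timedelta(minutes=cfg.epoch_minutes)
                       for k in range(dur_ep)]
            bout_ts = [ts for ts in bout_ts if ts < win_end]
            loc = idx.get_indexer(pd.DatetimeIndex(bout_ts))
            loc = loc[loc >= 0]
            activity[loc] = np.maximum(activity[loc], level)
            disturbed[loc] = True
        night += dt.timedelta(days=1)

    activity = np.clip(activity, 0.0, 100.0)
    return pd.DataFrame({
        "activity_true": activity,
        "raw_translation": activity / 100.0 * cfg.translation_scale_m,
        "is_disturbance": disturbed,
        "phase": phase_of_epoch,
    }, index=idx)


# ---------------------------------------------------------------------------
# Presence, frames and switch events

def _presence_sessions(profile: ResidentProfile, idx_start: pd.Timestamp,
                       idx_end: pd.Timestamp, cfg: CohortConfig, rng) -> list:
    """Alternating present intervals [(t0, t1), ...] over the span.

    Exponential dwells; the bed window forces presence. Returns a merged,
    sorted list of presence intervals.
    """
    f = profile.room_occupancy_fraction
    if f >= 1.0:
        return [(idx_start, idx_end)]
    mu_p = cfg.present_dwell_minutes
    mu_a = mu_p * (1.0 - f) / max(f, 1e-9)
    intervals = []
    t = idx_start
    present = rng.random() < f
    while t < idx_end:
        dwell = pd.Timedelta(minutes=float(rng.exponential(mu_p if present else mu_a)))
        t2 = min(t + dwell, idx_end)
        if present:
            intervals.append((t, t2))
        t, present = t2, not present
    # Force presence during every bed window.
    bw_start, bw_end = profile.bed_window
    day = idx_start.date()
    while pd.Timestamp(dt.datetime.combine(day, bw_start), tz=idx_start.tz) < idx_end:
        a = pd.Timestamp(dt.datetime.combine(day, bw_start), tz=idx_start.tz)
        b = pd.Timestamp(dt.datetime.combine(day + dt.timedelta(days=1), bw_end),
                         tz=idx_start.tz)
        intervals.append((max(a, idx_start), min(b, idx_end)))
        day += dt.timedelta(days=1)
    intervals = [iv for iv in intervals if iv[0] < iv[1]]
    intervals.sort()
    merged = [intervals[0]]
    for a, b in intervals[1:]:
        if a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _emit_frames(epochs: pd.DataFrame, sessions: list, sensor_id: str,
                 resident_id: str, cfg: CohortConfig, rng) -> pd.DataFrame:
    """Frames realising each epoch's target translation over present time."""
    times = []
    for a, b in sessions:
        span_s = (b - a).total_seconds()
        if cfg.frame_mode == "sparse":
            n = max(2, int(span_s / cfg.frame_interval_s) + 1)
            times.append(a.value + (np.linspace(0.0, span_s, n) * 1e9).astype(np.int64))
        elif cfg.frame_mode == "burst":
            keep = np.arange(0.0, span_s, cfg.frame_interval_s)
            ep = pd.Timestamp(a).floor(f"{cfg.epoch_minutes}min")
            bursts = []
            while ep < b:
                b0 = max((ep - a).total_seconds(), 0.0)
                b1 = min(b0 + cfg.burst_seconds, span_s)
                if b1 > b0:
                    bursts.append(np.arange(b0, b1, 1.0 / cfg.burst_rate_hz))
                ep += pd.Timedelta(minutes=cfg.epoch_minutes)
            t = np.unique(np.concatenate([keep, *bursts, [span_s]]))
            times.append(a.value + (t * 1e9).astype(np.int64))
        else:
            raise SyntheticError(f"unknown frame_mode {cfg.frame_mode!r}")
    if not times:
        return pd.DataFrame(columns=["timestamp", "sensor_id", "resident_id", "x", "y"])
    ts_ns = np.concatenate(times)
    ts_ns.sort(kind="stable")
    ts = pd.DatetimeIndex(ts_ns, tz="UTC").tz_convert(epochs.index.tz)

    # Distribute each epoch's target translation equally over its valid pairs
    # (pair = consecutive frames <= 60 s apart, credited to the later frame).
    gap_ok = np.diff(ts_ns) / 1e9 <= 60.0
    freq = f"{cfg.epoch_minutes}min"
    later_epoch = ts.floor(freq)[1:]
    steps = np.zeros(len(ts_ns) - 1)
    target = epochs["raw_translation"]
    pair_epochs = later_epoch[gap_ok]
    counts = pd.Series(1, index=pair_epochs).groupby(level=0).sum()
    tgt = target.reindex(counts.index).fillna(0.0)
    per_pair = (tgt / counts).reindex(pair_epochs).to_numpy()
    steps[gap_ok] = per_pair

    theta = rng.uniform(0.0, 2 * np.pi, len(steps))
    dx = np.concatenate([[0.0], steps * np.cos(theta)])
    dy = np.concatenate([[0.0], steps * np.sin(theta)])
    return pd.DataFrame({
        "timestamp": ts,
        "sensor_id": sensor_id,
        "resident_id": resident_id,
        "x": 2.5 + np.cumsum(dx),
        "y": 2.5 + np.cumsum(dy),
    })


def _switch_events(sessions: list, profile: ResidentProfile, room_id: str,
                   span: tuple[pd.Timestamp, pd.Timestamp], rng) -> pd.DataFrame:
    """Lights on per presence session outside the bed window, off at its end."""
    bw_start = profile.bed_window[0]
    rows = [{"timestamp": span[0], "room_id": room_id, "state": "off"}]
    for a, b in sessions:
        if a.time() >= bw_start or a.time() < profile.bed_window[1]:
            continue  # settled for the night: lights stay off
        if rng.random() < profile.lights_on_given_present:
            rows.append({"timestamp": a, "room_id": room_id, "state": "on"})
            rows.append({"timestamp": b, "room_id": room_id, "state": "off"})
    return pd.DataFrame(rows)


def simulate_resident(
    profile: ResidentProfile,
    phase_effects: list[InterventionEffect],
    date_range: tuple[dt.date, dt.date],
    seed,
    plan: PhasePlan | None = None,
    config: CohortConfig | None = None,
    return_truth: bool = False,
):
    """(frame stream, switch events[, ground-truth epochs]) for one resident.

    Deterministic per seed; with ``return_truth`` the epoch table that the
    frames realise is returned as a third element."""
    start, end = _validate_date_range(date_range)
    cfg = config or CohortConfig()
    plan = plan or PhasePlan(start_date=start)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_epochs, ss_presence, ss_frames, ss_switch = ss.spawn(4)

    epochs = simulate_activity_epochs(profile, phase_effects, date_range,
                                      ss_epochs, plan, cfg)
    rng_p = np.random.Generator(np.random.PCG64(ss_presence))
    rng_f = np.random.Generator(np.random.PCG64(ss_frames))
    rng_s = np.random.Generator(np.random.PCG64(ss_switch))

    sessions = _presence_sessions(profile, epochs.index[0],
                                  epochs.index[-1] + pd.Timedelta(minutes=cfg.epoch_minutes),
                                  cfg, rng_p)
    sensor_id = f"{profile.resident_id}-sensor"
    room_id = f"{profile.resident_id}-flat"
    frames = _emit_frames(epochs, sessions, sensor_id, profile.resident_id, cfg, rng_f)
    switches = _switch_events(sessions, profile, room_id,
                              (epochs.index[0], epochs.index[-1]), rng_s)
    if return_truth:
        return frames, switches, epochs
    return frames, switches


# ---------------------------------------------------------------------------
# QUALIDEM panel

def simulate_qualidem_panel(
    profiles: list[ResidentProfile],
    effects: list[InterventionEffect],
    n_weeks: int,
    seed,
    item_map: ItemMap | None = None,
    plan: PhasePlan | None = None,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Weekly item-response table (resident_id, week, one column per item).

    Responses are integer ratings drawn from a truncated discrete normal
    around a subscale-level latent mean; reverse-coded items are emitted
    pre-reversal so scoring recovers the latent scale. Effects on a subscale
    letter shift its latent mean by delta week-level SDs in the named phase.
    """
    if n_weeks < 1:
        raise SyntheticError("n_weeks must be >= 1")
    cfg = config or CohortConfig()
    item_map = item_map or load_item_map()
    plan = plan or PhasePlan(start_date=cfg.start_date)
    known = set(item_map.subscales)
    for eff in effects:
        if len(eff.parameter) == 1 and eff.parameter.isalpha() and eff.parameter not in known:
            raise SyntheticError(f"unknown QUALIDEM subscale {eff.parameter!r}")
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    entropy = master.entropy

    week_phase = {}
    for label, a, b in plan.phases:
        for w in range(a, min(b, n_weeks + 1)):
            week_phase[w] = label

    shift = {(e.parameter, e.phase): e.delta * cfg.qualidem_week_sd
             for e in effects if len(e.parameter) == 1 and e.parameter.isalpha()}

    lo, hi = item_map.rating_min, item_map.rating_max
    rows = []
    for k, prof in enumerate(profiles):
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([entropy, 100000 + k])))
        base = {s: float(np.clip(cfg.qualidem_latent_base
                                 + rng.normal(0.0, cfg.qualidem_resident_sd),
                                 lo + 0.5, hi - 0.5))
                for s in item_map.subscales}
        for week in range(1, n_weeks + 1):
            ph = week_phase.get(week, plan.labels[-1])
            row = {"resident_id": prof.resident_id, "week": week}
            for sub in item_map.subscales:
                latent = base[sub] + rng.normal(0.0, 1.0) * cfg.qualidem_week_sd
                latent += shift.get((sub, ph), 0.0)
                for item in item_map.items_of(sub):
                    _, reverse = item_map.items[item]
                    r = int(np.clip(round(latent + rng.normal(0.0, 1.0) * cfg.qualidem_item_sd),
                                    lo, hi))
                    row[item] = (hi - r + lo) if reverse else r
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole cohort

def _check_profiles(profiles: list[ResidentProfile]) -> None:
    if not profiles:
        raise SyntheticError("at least one resident profile is required")
    ids = [p.resident_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise SyntheticError("duplicate resident_id in profile list")


def simulate_cohort_epochs(
    profiles: list[ResidentProfile],
    effects: list[InterventionEffect],
    config: CohortConfig | None = None,
    seed: int = 0,
    plan: PhasePlan | None = None,
) -> tuple[dict[str, pd.DataFrame], PhasePlan]:
    """Fast path: per-resident ground-truth epoch tables, no frame emission."""
    _check_profiles(profiles)
    cfg = config or CohortConfig()
    plan = plan or PhasePlan(start_date=cfg.start_date)
    end = cfg.start_date + dt.timedelta(weeks=cfg.n_weeks)
    master = np.random.SeedSequence(seed)
    out = {}
    for k, prof in enumerate(profiles):
        ss = np.random.SeedSequence([master.entropy, k])
        out[prof.resident_id] = simulate_activity_epochs(
            prof, effects, (cfg.start_date, end), ss.spawn(1)[0], plan, cfg)
    return out, plan


def simulate_cohort(
    profiles: list[ResidentProfile],
    effects: list[InterventionEffect],
    config: CohortConfig | None = None,
    seed: int = 0,
) -> CohortDataset:
    """Full synthetic study: frames, switch log, QUALIDEM panel, ground truth."""
    _check_profiles(profiles)
    cfg = config or CohortConfig()
    plan = PhasePlan(start_date=cfg.start_date)
    end = cfg.start_date + dt.timedelta(weeks=cfg.n_weeks)
    master = np.random.SeedSequence(seed)

    frames: dict[str, pd.DataFrame] = {}
    switches = []
    room_map: dict[str, str] = {}
    truth: dict = {"seed": seed, "profiles": {}, "effects": [asdict(e) for e in effects]}
    for k, prof in enumerate(profiles):
        ss = np.random.SeedSequence([master.entropy, k])
        f, s = simulate_resident(prof, effects, (cfg.start_date, end), ss, plan, cfg)
        frames[prof.resident_id] = f
        switches.append(s)
        room_map[f"{prof.resident_id}-sensor"] = f"{prof.resident_id}-flat"
        rec = asdict(prof)
        rec["bed_window"] = [t.isoformat() for t in prof.bed_window]
        rec["phase_params"] = _phase_generator_params(prof, effects)
        truth["profiles"][prof.resident_id] = rec

    panel = simulate_qualidem_panel(profiles, effects, cfg.n_weeks, master,
                                    plan=plan, config=cfg)
    switch_log = pd.concat(switches, ignore_index=True).sort_values(
        ["timestamp", "room_id"]).reset_index(drop=True)
    return CohortDataset(frames=frames, switch_log=switch_log, qualidem_panel=panel,
                         truth=truth, room_map=room_map, plan=plan, config=cfg)


def write_cohort(dataset: CohortDataset, outdir) -> None:
    """Write a cohort to disk: JSONL frames, CSV switch log and panel, JSON truth."""
    from pathlib import Path
    from . import ingest

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for rid, f in dataset.frames.items():
        ingest.write_frames_jsonl(f, out / f"frames_{rid}.jsonl")
    dataset.switch_log.to_csv(out / "switch_log.csv", index=False,
                              date_format="%Y-%m-%dT%H:%M:%S%z")
    dataset.qualidem_panel.to_csv(out / "qualidem_panel.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=2, default=str)
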