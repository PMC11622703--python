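"""End-to-end study orchestration: data -> metrics -> phase contrasts -> report.

A study run either simulates a synthetic cohort or ingests recorded inputs,
then for every resident computes per-phase rest-activity metrics (IS, IV,
RA), sleep metrics (disturbance counts, bout lengths, total sleep),
sundowning-window activity, dynamic-lighting exposure and weekly QUALIDEM
subscale scores; finally it runs the paired baseline/intervention contrasts
and writes a report (markdown + JSON + intermediate CSVs).

All randomness flows from the single config seed; rerunning with the same
config produces byte-identical report bodies.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circadian, ingest, lighting, qualidem, sleep, stats, synthetic
from .phases import PhasePlan


class ConfigError(ValueError):
    """Invalid study configuration; message names the offending field."""


RHYTHM_PARAMS = ("IS", "IV", "RA")
SLEEP_PARAMS = ("sleep_disturbances", "sleep_bout_minutes", "total_sleep_hours")
DEFAULT_CONTRASTS = (("baseline", "weeks5_10"), ("baseline", "weeks10_16"),
                     ("weeks5_10", "weeks10_16"))


@dataclass
class StudyConfig:
    seed: int = 0
    out_dir: str = "study_out"
    # --- simulation (used unless `inputs` is given) ---
    n_residents: int = 11
    n_weeks: int = 16
    start_date: dt.date = dt.date(2023, 3, 6)
    frame_mode: str = "epoch"  # "epoch" | "sparse" | "burst"
    effects: list[synthetic.InterventionEffect] = field(default_factory=list)
    profile_overrides: dict = field(default_factory=dict)
    # --- recorded inputs (optional alternative to simulation) ---
    inputs: dict | None = None
    # --- thresholds ---
    theta: float = 10.0
    min_run: int = 4
    min_bout: int = 1
    night_window: tuple[dt.time, dt.time] = sleep.DEFAULT_NIGHT_WINDOW
    gap_threshold_s: float = 60.0
    normalization: str = "running_max"
    burn_in_days: int = 1
    # --- lighting anchors ---
    melanopic_ratio: float = lighting.DEFAULT_MELANOPIC_RATIO
    cl_a_per_lux: float = lighting.DEFAULT_CLA_PER_LUX
    sunset_by_phase: dict = field(default_factory=lambda: dict(
        circadian.DEFAULT_SUNSET_BY_PHASE))
    # --- aggregation & statistics ---
    qualidem_aggregator: str = "mean"
    sleep_aggregator: str = "median"
    alpha: float = 0.05
    alpha_norm: float = 0.05
    forced_nonparametric: tuple[str, ...] = ("E", "H")
    holm: bool = False

    def __post_init__(self) -> None:
        if self.frame_mode not in ("epoch", "sparse", "burst"):
            raise ConfigError(f"frame_mode: unknown value {self.frame_mode!r}")
        if self.n_residents < 1 and self.inputs is None:
            raise ConfigError("n_residents: must be >= 1")
        if not 0 <= self.theta <= 100:
            raise ConfigError(f"theta: {self.theta} outside [0, 100]")
        if self.qualidem_aggregator not in ("mean", "median"):
            raise ConfigError("qualidem_aggregator: must be mean or median")


def load_config(path) -> StudyConfig:
    """Build a StudyConfig from a YAML file, validating field by field."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, value in raw.items():
        if key == "effects":
            kwargs[key] = [synthetic.InterventionEffect(**e) for e in value]
        elif key == "start_date":
            kwargs[key] = value if isinstance(value, dt.date) else dt.date.fromisoformat(value)
        elif key == "night_window":
            kwargs[key] = tuple(dt.time.fromisoformat(t) for t in value)
        elif key == "sunset_by_phase":
            kwargs[key] = {k: dt.time.fromisoformat(str(v)) for k, v in value.items()}
        elif key == "forced_nonparametric":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    unknown = set(kwargs) - {f.name for f in dataclasses.fields(StudyConfig)}
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    return StudyConfig(**kwargs)


@dataclass
class StudyReport:
    rhythm: pd.DataFrame  # resident, phase, IS, IV, RA, M10, L5
    sleep_nightly: pd.DataFrame
    sleep_phase: pd.DataFrame  # resident, phase, the three sleep params
    sundowning: pd.DataFrame
    qualidem_weekly: pd.DataFrame
    qualidem_phase: pd.DataFrame
    exposure: pd.DataFrame | None
    comparisons: pd.DataFrame
    provenance: dict


def _config_hash(config: StudyConfig) -> str:
    fields = dataclasses.asdict(config)
    fields.pop("out_dir", None)  # output location is not scientific config
    blob = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_profiles(config: StudyConfig) -> list[synthetic.ResidentProfile]:
    """One profile per resident; overrides apply to every profile."""
    return [
        synthetic.ResidentProfile(resident_id=f"resident_{i+1:02d}",
                                  **config.profile_overrides)
        for i in range(config.n_residents)
    ]


def _activity_by_resident(config: StudyConfig, plan: PhasePlan):
    """(activity series per resident, occupancy per resident or None,
    switch log or None, qualidem panel)."""
    cohort_cfg = synthetic.CohortConfig(start_date=config.start_date,
                                        n_weeks=config.n_weeks)
    if config.inputs is not None:
        return _load_recorded(config, plan)
    profiles = default_profiles(config)
    if config.frame_mode == "epoch":
        epochs, _ = synthetic.simulate_cohort_epochs(
            profiles, config.effects, cohort_cfg, config.seed)
        activity = {rid: df["activity_true"].rename("activity_pct")
                    for rid, df in epochs.items()}
        panel = synthetic.simulate_qualidem_panel(
            profiles, config.effects, config.n_weeks,
            np.random.SeedSequence(config.seed), plan=plan, config=cohort_cfg)
        return activity, None, None, panel
    cohort_cfg.frame_mode = config.frame_mode
    dataset = synthetic.simulate_cohort(profiles, config.effects, cohort_cfg,
                                        config.seed)
    activity, occupancy = {}, {}
    for rid, frames in dataset.frames.items():
        act = ingest.activity_series(frames, gap_threshold_s=config.gap_threshold_s,
                                     mode=config.normalization)
        activity[rid] = act["activity_pct"]
        occupancy[rid] = ingest.occupancy_fraction(
            frames, dataset.room_map, gap_threshold_s=config.gap_threshold_s)
    return activity, occupancy, dataset.switch_log, dataset.qualidem_panel


def _load_recorded(config: StudyConfig, plan: PhasePlan):
    paths = config.inputs or {}
    for key in ("frames", "switch_log", "qualidem"):
        if key not in paths:
            raise ConfigError(f"inputs.{key}: missing path")
    room_map = paths.get("room_map") or {}
    activity, occupancy = {}, {}
    for rid, fpath in paths["frames"].items():
        frames = (ingest.read_frames_jsonl(fpath) if str(fpath).endswith(".jsonl")
                  else ingest.read_frames_csv(fpath))
        act = ingest.activity_series(frames, gap_threshold_s=config.gap_threshold_s,
                                     mode=config.normalization)
        activity[rid] = act["activity_pct"]
        if room_map:
            occupancy[rid] = ingest.occupancy_fraction(
                frames, room_map, gap_threshold_s=config.gap_threshold_s)
    switch_log = pd.read_csv(paths["switch_log"], parse_dates=["timestamp"])
    panel = pd.read_csv(paths["qualidem"])
    return activity, occupancy or None, switch_log, panel


def _phase_rhythm_table(activity: dict, plan: PhasePlan, config: StudyConfig) -> pd.DataFrame:
    rows = []
    for rid, series in activity.items():
        s = series
        if config.burn_in_days:
            s = s[s.index >= s.index[0] + pd.Timedelta(days=config.burn_in_days)]
        for label in plan.labels:
            sub = plan.slice_phase(s, label)
            try:
                m = circadian.rhythm_metrics(sub)
                rows.append({"resident_id": rid, "phase": label, "IS": m.IS,
                             "IV": m.IV, "RA": m.RA, "M10": m.M10, "L5": m.L5,
                             "n_days": m.n_days})
            except circadian.CircadianError:
                rows.append({"resident_id": rid, "phase": label, "IS": np.nan,
                             "IV": np.nan, "RA": np.nan, "M10": np.nan,
                             "L5": np.nan, "n_days": 0})
    return pd.DataFrame(rows)


def _sleep_tables(activity: dict, plan: PhasePlan, config: StudyConfig):
    nightly_rows, phase_rows = [], []
    for rid, series in activity.items():
        nights = sleep.score_nights(series, window=config.night_window,
                                    theta=config.theta, min_run=config.min_run,
                                    min_bout=config.min_bout)
        nights.insert(0, "resident_id", rid)
        nights["phase"] = [plan.phase_of(d) for d in nights["night_of"]]
        nightly_rows.append(nights)
        agg = config.sleep_aggregator
        for label in plan.labels:
            sub = nights[(nights["phase"] == label)].dropna(subset=["n_disturbances"])
            if sub.empty:
                continue
            phase_rows.append({
                "resident_id": rid, "phase": label,
                "sleep_disturbances": float(sub["n_disturbances"].agg(agg)),
                "sleep_bout_minutes": float(sub["median_bout_minutes"].agg(agg)),
                "total_sleep_hours": float(sub["total_sleep_hours"].agg(agg)),
            })
    return pd.concat(nightly_rows, ignore_index=True), pd.DataFrame(phase_rows)


def _sundowning_table(activity: dict, plan: PhasePlan, config: StudyConfig) -> pd.DataFrame:
    rows = []
    for rid, series in activity.items():
        for label in plan.labels:
            sub = plan.slice_phase(series, label)
            try:
                res = circadian.sundowning_activity(sub, label, config.sunset_by_phase)
                rows.append({"resident_id": rid, "phase": label,
                             "sundowning_activity": res.mean_activity_pct,
                             "sunset_time": res.sunset_time.isoformat()})
            except circadian.CircadianError:
                continue
    return pd.DataFrame(rows)


def _qualidem_tables(panel: pd.DataFrame, plan: PhasePlan, config: StudyConfig):
    weekly = qualidem.score_panel(panel)
    subscales = [c for c in weekly.columns if c not in ("resident_id", "week")]
    rows = []
    for label in plan.labels:
        weeks = set(plan.weeks_in_phase(label)) & set(weekly["week"])
        sub = weekly[weekly["week"].isin(weeks)]
        agg = sub.groupby("resident_id")[subscales].agg(config.qualidem_aggregator)
        for rid, rec in agg.iterrows():
            rows.append({"resident_id": rid, "phase": label, **rec.to_dict()})
    return weekly, pd.DataFrame(rows)


def _exposure_table(occupancy, switch_log, plan: PhasePlan) -> pd.DataFrame | None:
    if occupancy is None or switch_log is None:
        return None
    rows = []
    for rid, occ in occupancy.items():
        room = f"{rid}-flat"
        log = switch_log[switch_log["room_id"] == room]
        if log.empty:
            log = switch_log
        series = occ["present_fraction"]
        for label in plan.labels:
            sub = plan.slice_phase(series, label)
            if sub.dropna().empty:
                continue
            summ = lighting.exposure_summary(sub, log, label)
            rows.append({"resident_id": rid, "phase": label,
                         "pct_time_in_rooms": summ.pct_time_in_rooms,
                         "pct_lights_on_while_present": summ.pct_lights_on_while_present,
                         "pct_dynamic_exposure": summ.pct_dynamic_exposure})
    return pd.DataFrame(rows)


def _compare(per_phase: pd.DataFrame, params: list[str], plan: PhasePlan,
             config: StudyConfig) -> list[dict]:
    out = []
    wide = per_phase.set_index(["resident_id", "phase"])
    for param in params:
        forced = ("nonparametric" if param in config.forced_nonparametric else None)
        for a, b in DEFAULT_CONTRASTS:
            try:
                tbl = wide[param].unstack("phase")[[a, b]].dropna()
            except KeyError:
                continue
            if len(tbl) < 3:
                continue
            try:
                res = stats.paired_compare(tbl[a], tbl[b], parameter=param,
                                           contrast=f"{a} vs {b}",
                                           forced_branch=forced,
                                           alpha_norm=config.alpha_norm)
            except stats.StatsError:
                continue
            out.append(dataclasses.asdict(res))
    return out


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full analysis chain and return (and write) the report."""
    plan = PhasePlan(start_date=config.start_date)
    activity, occupancy, switch_log, panel = _activity_by_resident(config, plan)

    rhythm = _phase_rhythm_table(activity, plan, config)
    sleep_nightly, sleep_phase = _sleep_tables(activity, plan, config)
    sundown = _sundowning_table(activity, plan, config)
    weekly, qualidem_phase = _qualidem_tables(panel, plan, config)
    exposure = _exposure_table(occupancy, switch_log, plan)

    comparisons = []
    comparisons += _compare(rhythm, list(RHYTHM_PARAMS), plan, config)
    if not sleep_phase.empty:
        comparisons += _compare(sleep_phase, list(SLEEP_PARAMS), plan, config)
    if not sundown.empty:
        comparisons += _compare(sundown, ["sundowning_activity"], plan, config)
    analysed = [c for c in qualidem_phase.columns
                if c in qualidem.ANALYSIS_SUBSCALES]
    comparisons += _compare(qualidem_phase, analysed, plan, config)
    comp_df = pd.DataFrame(comparisons)
    if config.holm and not comp_df.empty:
        comp_df["p_holm"] = stats.holm_correction(comp_df["p_value"].fillna(1.0))

    provenance = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_residents": len(activity),
        "phases": [list(p) for p in plan.phases],
        "thresholds": {"theta": config.theta, "min_run": config.min_run,
                       "min_bout": config.min_bout,
                       "gap_threshold_s": config.gap_threshold_s,
                       "normalization": config.normalization},
        "lighting_anchors": {"melanopic_ratio": config.melanopic_ratio,
                             "cl_a_per_lux": config.cl_a_per_lux},
    }
    report = StudyReport(rhythm, sleep_nightly, sleep_phase, sundown, weekly,
                         qualidem_phase, exposure, comp_df, provenance)
    write_report(report, config.out_dir)
    return report


def render_markdown(report: StudyReport) -> str:
    """Markdown summary mirroring the contrast table layout."""
    lines = ["# Study report", "",
             f"Seed {report.provenance['seed']}, config {report.provenance['config_hash']}, "
             f"{report.provenance['n_residents']} residents.", "",
             "## Phase contrasts", "",
             "| Parameter | Contrast | Test | P | Effect size | Label |",
             "|---|---|---|---|---|---|"]
    for row in report.comparisons.to_dict("records"):
        p = "" if pd.isna(row["p_value"]) else f"{row['p_value']:.3g}"
        es = "" if pd.isna(row["effect_size"]) else f"{row['effect_size']:.3f}"
        lines.append(f"| {row['parameter']} | {row['contrast']} | {row['test']} "
                     f"| {p} | {es} | {row['effect_label']} |")
    if report.exposure is not None and not report.exposure.empty:
        lines += ["", "## Dynamic-lighting exposure (group means, %)", ""]
        grp = report.exposure.groupby("phase")[
            ["pct_time_in_rooms", "pct_lights_on_while_present",
             "pct_dynamic_exposure"]].mean()
        lines.append("| Phase | In rooms | Lights on while present | Dynamic exposure |")
        lines.append("|---|---|---|---|")
        for phase, rec in grp.iterrows():
            lines.append(f"| {phase} | {rec.iloc[0]:.2f} | {rec.iloc[1]:.2f} "
                         f"| {rec.iloc[2]:.2f} |")
    return "\n".join(lines) + "\n"


def write_report(report: StudyReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.rhythm.to_csv(out / "rhythm_metrics.csv", index=False)
    report.sleep_nightly.to_csv(out / "sleep_nightly.csv", index=False)
    report.sleep_phase.to_csv(out / "sleep_phase.csv", index=False)
    report.sundowning.to_csv(out / "sundowning.csv", index=False)
    report.qualidem_weekly.to_csv(out / "qualidem_weekly.csv", index=False)
    report.qualidem_phase.to_csv(out / "qualidem_phase.csv", index=False)
    if report.exposure is not None:
        report.exposure.to_csv(out / "exposure.csv", index=False)
    report.comparisons.to_csv(out / "comparisons.csv", index=False)
    (out / "report.md").write_text(render_markdown(report))
    payload = {"provenance": report.provenance,
               "comparisons": report.comparisons.to_dict("records")}
    (out / "report.json").write_text(json.dumps(payload, indent=2, default=str))
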