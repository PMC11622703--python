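"""Seeded Monte-Carlo oracles shared by module and acceptance tests.

Every function is deterministic and cached, so each simulation campaign runs
once per session regardless of how many tests consult it. Cohort problem
sizes are scaled (two 4-week phases, 5-11 residents) to keep the suite fast
while preserving the estimands under test.
"""

from __future__ import annotations

import datetime as dt
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from circalight import circadian, qualidem, sleep, stats, synthetic
from circalight.phases import PhasePlan

START = dt.date(2023, 3, 6)

# Scaled layout: 4-week baseline, 4-week intervention, 1-week tail.
SHORT_PLAN = PhasePlan(START, phases=(("baseline", 1, 5), ("weeks5_10", 5, 9),
                                      ("weeks10_16", 9, 10)))


def _short_cfg() -> synthetic.CohortConfig:
    return synthetic.CohortConfig(start_date=START, n_weeks=9)


def _phase_metric(df: pd.DataFrame, plan: PhasePlan, phase: str, metric: str) -> float:
    s = plan.slice_phase(df["activity_true"], phase)
    if metric == "RA":
        return circadian.relative_amplitude(s)[0]
    if metric == "IS":
        return circadian.interdaily_stability(s)
    return circadian.intradaily_variability(s)


def _ra_headroom_profiles(n_residents: int) -> list:
    """Cohort with mid-range baseline RA (~0.5) so a +0.1 shift has headroom."""
    return [synthetic.ResidentProfile(f"r{i}", mesor=40.0, amplitude=25.0,
                                      n_disturbances_per_night=1.0)
            for i in range(n_residents)]


@lru_cache(maxsize=None)
def ra_recovery_deltas(n_reps: int = 200, n_residents: int = 11,
                       delta: float = 0.1) -> tuple[float, ...]:
    """Cohort-mean recovered (weeks5_10 - baseline) RA per replicate."""
    profiles = _ra_headroom_profiles(n_residents)
    effects = [synthetic.InterventionEffect("RA", "weeks5_10", delta)]
    out = []
    for rep in range(n_reps):
        epochs, _ = synthetic.simulate_cohort_epochs(profiles, effects,
                                                     _short_cfg(), seed=rep,
                                                     plan=SHORT_PLAN)
        deltas = [
            _phase_metric(df, SHORT_PLAN, "weeks5_10", "RA")
            - _phase_metric(df, SHORT_PLAN, "baseline", "RA")
            for df in epochs.values()
        ]
        out.append(float(np.mean(deltas)))
    return tuple(out)


@lru_cache(maxsize=None)
def null_rejections(n_seeds: int = 100, n_residents: int = 11) -> dict:
    """Per-metric rejection counts for baseline vs weeks5_10 under the null."""
    profiles = [synthetic.ResidentProfile(f"r{i}") for i in range(n_residents)]
    counts = {"IS": 0, "IV": 0, "RA": 0}
    for seedv in range(n_seeds):
        epochs, _ = synthetic.simulate_cohort_epochs(profiles, [], _short_cfg(),
                                                     seed=10_000 + seedv,
                                                     plan=SHORT_PLAN)
        for metric in counts:
            base = [_phase_metric(df, SHORT_PLAN, "baseline", metric)
                    for df in epochs.values()]
            mid = [_phase_metric(df, SHORT_PLAN, "weeks5_10", metric)
                   for df in epochs.values()]
            res = stats.paired_compare(base, mid)
            counts[metric] += bool(res.p_value < 0.05)
    return counts


@lru_cache(maxsize=None)
def ra_effect_rejections(n_seeds: int = 100, n_residents: int = 11,
                         delta: float = 0.1) -> int:
    """RA-contrast rejections with an injected weeks5_10 RA effect."""
    profiles = _ra_headroom_profiles(n_residents)
    effects = [synthetic.InterventionEffect("RA", "weeks5_10", delta)]
    hits = 0
    for seedv in range(n_seeds):
        epochs, _ = synthetic.simulate_cohort_epochs(profiles, effects,
                                                     _short_cfg(),
                                                     seed=20_000 + seedv,
                                                     plan=SHORT_PLAN)
        base = [_phase_metric(df, SHORT_PLAN, "baseline", "RA")
                for df in epochs.values()]
        mid = [_phase_metric(df, SHORT_PLAN, "weeks5_10", "RA")
               for df in epochs.values()]
        hits += bool(stats.paired_compare(base, mid).p_value < 0.05)
    return hits


@lru_cache(maxsize=None)
def gate_type_i_rate(n_draws: int = 2000, n: int = 11) -> float:
    """Rejection rate of the gated paired pipeline on null normal cohorts."""
    rng = np.random.default_rng(2023)
    rejections = 0
    for _ in range(n_draws):
        x = rng.normal(10.0, 2.0, n)
        y = rng.normal(10.0, 2.0, n)
        rejections += bool(stats.paired_compare(x, y).p_value < 0.05)
    return rejections / n_draws


@lru_cache(maxsize=None)
def disturbance_recovery(n_nights: int = 28, rate: float = 2.0) -> dict:
    """Detector median nightly count vs the generating-count MC interval.

    The oracle interval is the central 95% range of the median of
    ``n_nights`` Poisson(rate) draws over 10,000 brute-force simulations of
    the generator's count distribution.
    """
    rng = np.random.default_rng(99)
    medians = np.median(rng.poisson(rate, size=(10_000, n_nights)), axis=1)
    lo, hi = np.percentile(medians, [2.5, 97.5])

    # Quiet plateau covers the whole 22:00-08:00 scoring window (activity 8.4%
    # at the edges), so every generated bout lies inside the rest period and
    # the detector's only loss mechanism is bout merging.
    profile = synthetic.ResidentProfile(
        "r0", mesor=20.0, amplitude=45.0, noise_sd=0.0,
        n_disturbances_per_night=rate,
        bed_window=(dt.time(23, 0), dt.time(7, 0)))
    end = START + dt.timedelta(days=n_nights + 1)
    epochs = synthetic.simulate_activity_epochs(profile, [], (START, end), seed=4)
    counts = []
    for d in sorted({ts.date() for ts in epochs.index})[:n_nights]:
        night = sleep.night_slice(epochs["activity_true"], d)
        rest = sleep.detect_rest_period(night)
        if rest is None:
            continue
        n, _ = sleep.count_disturbances(night, rest)
        counts.append(n)
    return {"median": float(np.median(counts)), "lo": float(lo), "hi": float(hi),
            "n_nights_scored": len(counts)}


@lru_cache(maxsize=None)
def sleep_ordering_fraction(n_reps: int = 200, n_residents: int = 11) -> float:
    """Fraction of replicates where group medians order as the generator
    (baseline mean 2 disturbances vs 1 under the intervention)."""
    profiles = [synthetic.ResidentProfile(f"r{i}", mesor=20.0, amplitude=45.0,
                                          n_disturbances_per_night=2.0,
                                          noise_sd=0.0,
                                          bed_window=(dt.time(23, 0), dt.time(7, 0)))
                for i in range(n_residents)]
    effects = [synthetic.InterventionEffect("sleep_disturbances", "weeks5_10", -1.0)]
    ordered = 0
    for rep in range(n_reps):
        epochs, _ = synthetic.simulate_cohort_epochs(profiles, effects, _short_cfg(),
                                                     seed=30_000 + rep,
                                                     plan=SHORT_PLAN)
        nights_base, nights_mid = {}, {}
        for rid, df in epochs.items():
            nights = sleep.score_nights(df["activity_true"])
            nights["phase"] = [SHORT_PLAN.phase_of(d) for d in nights["night_of"]]
            nights_base[rid] = nights[nights["phase"] == "baseline"]
            nights_mid[rid] = nights[nights["phase"] == "weeks5_10"]
        base = sleep.summarize_sleep(nights_base, "baseline")
        mid = sleep.summarize_sleep(nights_mid, "weeks5_10")
        ordered += bool(base.median_disturbances > mid.median_disturbances)
    return ordered / n_reps


def _phase_mean_scores(panel: pd.DataFrame, subscale: str) -> tuple[np.ndarray, np.ndarray]:
    scored = qualidem.score_panel(panel)
    base = scored[scored["week"].between(1, 4)].groupby("resident_id")[subscale].mean()
    mid = scored[scored["week"].between(5, 8)].groupby("resident_id")[subscale].mean()
    return base.to_numpy(), mid.reindex(base.index).to_numpy()


@lru_cache(maxsize=None)
def qualidem_power_pipeline(n_reps: int = 200, delta: float = 0.5,
                            n_residents: int = 11) -> float:
    """Power of the scored-panel paired test for a latent shift on subscale B."""
    profiles = [synthetic.ResidentProfile(f"r{i}") for i in range(n_residents)]
    effects = [synthetic.InterventionEffect("B", "weeks5_10", delta)]
    hits = 0
    for rep in range(n_reps):
        panel = synthetic.simulate_qualidem_panel(profiles, effects, 8,
                                                  seed=40_000 + rep,
                                                  plan=SHORT_PLAN)
        base, mid = _phase_mean_scores(panel, "B")
        hits += bool(sps.ttest_rel(mid, base).pvalue < 0.05)
    return hits / n_reps


@lru_cache(maxsize=None)
def qualidem_power_oracle(n_reps: int = 200, delta: float = 0.5,
                          n_residents: int = 11) -> float:
    """Brute-force re-simulation of the panel generative chain with plain
    numpy (latents -> truncated item ratings -> subscale sums -> paired t).

    Matches the generator's structure (6 items on subscale B, ratings 0-3,
    week SD 0.25, item SD 0.6, resident SD 0.3 around latent 1.8) without
    using the package's generator or scorer.
    """
    rng = np.random.default_rng(777)
    week_sd, item_sd, res_sd, base_latent = 0.25, 0.6, 0.3, 1.8
    n_items, lo, hi = 6, 0, 3
    weeks_base, weeks_mid = 4, 4
    hits = 0
    for _ in range(n_reps):
        latents = np.clip(base_latent + rng.normal(0, res_sd, n_residents),
                          lo + 0.5, hi - 0.5)
        def phase_scores(n_weeks, shift):
            weekly = (latents[:, None] + rng.normal(0, week_sd, (n_residents, n_weeks))
                      + shift)
            ratings = np.rint(np.clip(
                weekly[:, :, None] + rng.normal(0, item_sd, (n_residents, n_weeks, n_items)),
                lo, hi))
            return ratings.sum(axis=2).mean(axis=1)
        base = phase_scores(weeks_base, 0.0)
        mid = phase_scores(weeks_mid, delta * week_sd)
        hits += bool(sps.ttest_rel(mid, base).pvalue < 0.05)
    return hits / n_reps
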