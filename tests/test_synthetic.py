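"""Synthetic cohort generator: determinism, closure, parameter recovery."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import mc_helpers as mc
from circalight import circadian, ingest, qualidem, synthetic

START = dt.date(2023, 3, 6)


def days(n):
    return (START, START + dt.timedelta(days=n))


class TestValidation:
    def test_date_range_under_one_day_rejected(self):
        p = synthetic.ResidentProfile("r1")
        with pytest.raises(synthetic.SyntheticError):
            synthetic.simulate_resident(p, [], (START, START), seed=0)

    def test_empty_profile_list_rejected(self):
        with pytest.raises(synthetic.SyntheticError):
            synthetic.simulate_cohort([], [], seed=0)

    def test_duplicate_resident_ids_rejected(self):
        profiles = [synthetic.ResidentProfile("r1"), synthetic.ResidentProfile("r1")]
        with pytest.raises(synthetic.SyntheticError):
            synthetic.simulate_cohort_epochs(profiles, [], seed=0)

    def test_bed_window_must_span_evening_to_morning(self):
        with pytest.raises(synthetic.SyntheticError):
            synthetic.ResidentProfile("r1", bed_window=(dt.time(9, 0), dt.time(17, 0)))

    def test_unknown_effect_phase_rejected(self):
        with pytest.raises(synthetic.SyntheticError):
            synthetic.InterventionEffect("RA", "weeks99", 0.1)

    def test_unknown_qualidem_subscale_rejected(self):
        p = [synthetic.ResidentProfile("r1")]
        bad = [synthetic.InterventionEffect("Z", "weeks5_10", 0.5)]
        with pytest.raises(synthetic.SyntheticError):
            synthetic.simulate_qualidem_panel(p, bad, 4, seed=0)


class TestDeterminism:
    def test_same_seed_gives_identical_frames_and_switches(self):
        p = synthetic.ResidentProfile("r1")
        f1, s1 = synthetic.simulate_resident(p, [], days(2), seed=42)
        f2, s2 = synthetic.simulate_resident(p, [], days(2), seed=42)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_different_seeds_differ(self):
        p = synthetic.ResidentProfile("r1")
        f1, _ = synthetic.simulate_resident(p, [], days(2), seed=1)
        f2, _ = synthetic.simulate_resident(p, [], days(2), seed=2)
        assert not f1.equals(f2)

    def test_qualidem_panel_deterministic(self):
        p = [synthetic.ResidentProfile("r1"), synthetic.ResidentProfile("r2")]
        a = synthetic.simulate_qualidem_panel(p, [], 4, seed=9)
        b = synthetic.simulate_qualidem_panel(p, [], 4, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestClosure:
    def test_noiseless_periodic_resident_gives_unit_is_downstream(self):
        """Frames -> ingest -> IS == 1 after the running-max burn-in day."""
        p = synthetic.ResidentProfile("r1", noise_sd=0.0,
                                      n_disturbances_per_night=0.0,
                                      room_occupancy_fraction=1.0)
        frames, _ = synthetic.simulate_resident(p, [], days(8), seed=3)
        act = ingest.activity_series(frames)["activity_pct"]
        act = act[act.index >= act.index[0] + pd.Timedelta(days=1)]
        assert circadian.interdaily_stability(act) == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_ra_matches_cosinor_ground_truth(self):
        p = synthetic.ResidentProfile("r1", noise_sd=0.0,
                                      n_disturbances_per_night=0.0)
        epochs = synthetic.simulate_activity_epochs(p, [], days(7), seed=1)
        ra, _, _ = circadian.relative_amplitude(epochs["activity_true"])
        truth = synthetic.cosinor_ra(p.mesor, p.amplitude, p.acrophase)
        assert ra == pytest.approx(truth, abs=1e-9)

    def test_frame_translation_totals_recover_targets_when_present(self):
        p = synthetic.ResidentProfile("r1", room_occupancy_fraction=1.0)
        frames, _, epochs = synthetic.simulate_resident(p, [], days(2), seed=6,
                                                        return_truth=True)
        raw = ingest.bin_translations(frames)
        joined = pd.concat([raw, epochs["raw_translation"]], axis=1,
                           keys=["rec", "tgt"]).dropna()
        assert (joined["rec"] - joined["tgt"]).abs().max() < 1e-9

    def test_burst_mode_also_preserves_epoch_totals(self):
        p = synthetic.ResidentProfile("r1", room_occupancy_fraction=1.0)
        cfg = synthetic.CohortConfig(frame_mode="burst")
        frames, _, epochs = synthetic.simulate_resident(p, [], days(1), seed=6,
                                                        config=cfg, return_truth=True)
        raw = ingest.bin_translations(frames)
        joined = pd.concat([raw, epochs["raw_translation"]], axis=1,
                           keys=["rec", "tgt"]).dropna()
        assert (joined["rec"] - joined["tgt"]).abs().max() < 1e-9

    def test_activity_bounded_and_nonnegative(self):
        p = synthetic.ResidentProfile("r1", noise_sd=25.0)
        epochs = synthetic.simulate_activity_epochs(p, [], days(3), seed=8)
        assert epochs["activity_true"].between(0, 100).all()
        assert (epochs["raw_translation"] >= 0).all()


class TestCohort:
    def test_eleven_profiles_give_eleven_frame_streams(self):
        profiles = [synthetic.ResidentProfile(f"res{i:02d}") for i in range(11)]
        cfg = synthetic.CohortConfig(n_weeks=2)
        ds = synthetic.simulate_cohort(profiles, [], cfg, seed=0)
        assert len(ds.frames) == 11
        assert set(ds.qualidem_panel["resident_id"]) == {p.resident_id for p in profiles}
        assert len(ds.truth["profiles"]) == 11

    def test_timestamps_span_configured_weeks(self):
        profiles = [synthetic.ResidentProfile("r1")]
        cfg = synthetic.CohortConfig(n_weeks=2)
        ds = synthetic.simulate_cohort(profiles, [], cfg, seed=0)
        f = ds.frames["r1"]
        assert f["timestamp"].min().date() == cfg.start_date
        end = cfg.start_date + dt.timedelta(weeks=2)
        assert f["timestamp"].max() < pd.Timestamp(end, tz=cfg.tz)

    def test_written_cohort_round_trips(self, tmp_path):
        profiles = [synthetic.ResidentProfile("r1")]
        cfg = synthetic.CohortConfig(n_weeks=1)
        ds = synthetic.simulate_cohort(profiles, [], cfg, seed=0)
        synthetic.write_cohort(ds, tmp_path)
        back = ingest.read_frames_jsonl(tmp_path / "frames_r1.jsonl")
        assert len(back) == len(ds.frames["r1"])
        assert (tmp_path / "truth.json").exists()


class TestDisturbanceRecovery:
    def test_detected_median_inside_generating_mc_interval(self):
        """28 nights at mean 2 bouts/night: the sleep detector's median count
        falls in the central 95% interval of the generating count
        distribution (10,000 brute-force draws)."""
        res = mc.disturbance_recovery()
        assert res["n_nights_scored"] == 28
        assert res["lo"] <= res["median"] <= res["hi"]

    def test_summary_ordering_tracks_generator_ordering(self):
        """Generating means 2 vs 1 bouts/night: group median ordering matches
        in >= 95% of 200 seeded replicates."""
        assert mc.sleep_ordering_fraction(200) >= 0.95


class TestEffectInjection:
    def test_ra_effect_recovered_within_mc_interval(self):
        """Injected +0.1 RA shift: the 95% interval of cohort-mean recovered
        deltas over 200 replicates covers 0.1."""
        deltas = np.array(mc.ra_recovery_deltas(200))
        lo, hi = np.percentile(deltas, [2.5, 97.5])
        assert lo <= 0.1 <= hi
        assert deltas.mean() == pytest.approx(0.1, abs=0.02)

    def test_amplitude_solver_exact_on_expected_profile(self):
        p = synthetic.ResidentProfile("r1", mesor=40.0, amplitude=25.0,
                                      n_disturbances_per_night=1.0)
        target = synthetic.expected_ra(p) + 0.1
        a = synthetic.amplitude_for_ra(p, target)
        assert synthetic.expected_ra(p, amplitude=a) == pytest.approx(target, abs=1e-8)

    def test_noise_decreases_is_and_amplitude_increases_ra(self):
        """Generator sensitivity over 50 seeded two-week cohorts."""
        def median_metric(profile, metric, n=50):
            vals = []
            for seedv in range(n):
                ep = synthetic.simulate_activity_epochs(profile, [], days(14),
                                                        seed=500 + seedv)
                s = ep["activity_true"]
                vals.append(circadian.interdaily_stability(s) if metric == "IS"
                            else circadian.relative_amplitude(s)[0])
            return float(np.median(vals))

        is_by_noise = [median_metric(synthetic.ResidentProfile("r", noise_sd=sd), "IS")
                       for sd in (2.0, 10.0, 25.0)]
        assert is_by_noise[0] > is_by_noise[1] > is_by_noise[2]

        ra_by_amp = [median_metric(
            synthetic.ResidentProfile("r", mesor=40.0, amplitude=a), "RA")
            for a in (10.0, 25.0, 38.0)]
        assert ra_by_amp[0] < ra_by_amp[1] < ra_by_amp[2]


class TestQualidemPanel:
    def _noiseless_cfg(self):
        return synthetic.CohortConfig(qualidem_week_sd=0.0, qualidem_item_sd=0.0,
                                      qualidem_resident_sd=0.0)

    def test_zero_noise_zero_effects_identical_weeks(self):
        p = [synthetic.ResidentProfile("r1")]
        panel = synthetic.simulate_qualidem_panel(p, [], 6, seed=1,
                                                  config=self._noiseless_cfg())
        items = [c for c in panel.columns if c.startswith("item_")]
        assert (panel[items].nunique() == 1).all()

    def test_effect_on_one_subscale_leaves_others_untouched(self):
        p = [synthetic.ResidentProfile(f"r{i}") for i in range(4)]
        eff = [synthetic.InterventionEffect("B", "weeks5_10", 1.0)]
        base = synthetic.simulate_qualidem_panel(p, [], 16, seed=2)
        shifted = synthetic.simulate_qualidem_panel(p, eff, 16, seed=2)
        item_map = qualidem.load_item_map()
        b_items = set(item_map.items_of("B"))
        other = [c for c in base.columns if c.startswith("item_") and c not in b_items]
        pd.testing.assert_frame_equal(base[other], shifted[other])
        assert not base[sorted(b_items)].equals(shifted[sorted(b_items)])

    def test_responses_within_legal_range(self):
        p = [synthetic.ResidentProfile("r1")]
        panel = synthetic.simulate_qualidem_panel(p, [], 16, seed=3)
        items = [c for c in panel.columns if c.startswith("item_")]
        assert panel[items].min().min() >= 0
        assert panel[items].max().max() <= 3

    def test_injected_shift_detected_with_mc_calibrated_power(self):
        """+0.5 week-SD latent shift on subscale B at n=11: the scored-panel
        paired-test power matches an independent brute-force simulation of
        the generative chain (binomial-error tolerance)."""
        p_pipeline = mc.qualidem_power_pipeline(200)
        p_oracle = mc.qualidem_power_oracle(200)
        assert p_pipeline == pytest.approx(p_oracle, abs=0.12)
        assert p_pipeline > 0.10  # the shift is genuinely detectable
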