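"""Frame ingestion: translation binning, normalization, occupancy."""

import numpy as np
import pandas as pd
import pytest

from circalight import ingest
from conftest import make_frames


TZ = "Europe/London"


def ts(t):
    return pd.Timestamp(t, tz=TZ)


class TestTotalTranslation:
    def test_stationary_frames_give_zero(self):
        frames = make_frames([f"2023-03-06 10:00:{s:02d}" for s in range(10)],
                             xs=np.ones(10), ys=np.ones(10))
        assert ingest.total_translation(frames, ts("2023-03-06 10:00"),
                                        ts("2023-03-06 10:15")) == 0.0

    def test_three_four_five_triangle(self):
        frames = make_frames(["2023-03-06 10:00:00", "2023-03-06 10:00:01"],
                             xs=[0, 3], ys=[0, 4])
        assert ingest.total_translation(frames, ts("2023-03-06 10:00"),
                                        ts("2023-03-06 10:15")) == 5.0

    def test_hand_summed_fixture(self):
        # displacements: 1,1,2,0,3,1,1,0.5,0.5 -> total 10
        xs = [0, 1, 2, 2, 2, 5, 5, 6, 6, 6]
        ys = [0, 0, 0, 2, 2, 2, 3, 3, 3.5, 4]
        frames = make_frames([f"2023-03-06 10:00:{s:02d}" for s in range(10)], xs, ys)
        assert ingest.total_translation(frames, ts("2023-03-06 10:00"),
                                        ts("2023-03-06 10:15")) == pytest.approx(10.0)

    def test_fewer_than_two_frames_give_zero(self):
        frames = make_frames(["2023-03-06 10:00:00"], xs=[1], ys=[1])
        assert ingest.total_translation(frames, ts("2023-03-06 10:00"),
                                        ts("2023-03-06 10:15")) == 0.0

    def test_pairs_across_long_gaps_discarded(self):
        frames = make_frames(["2023-03-06 10:00:00", "2023-03-06 10:05:00"],
                             xs=[0, 30], ys=[0, 40])
        assert ingest.total_translation(frames, ts("2023-03-06 10:00"),
                                        ts("2023-03-06 10:15")) == 0.0


class TestBinning:
    def test_boundary_pair_credited_to_later_epoch(self):
        frames = make_frames(["2023-03-06 10:14:55", "2023-03-06 10:15:05"],
                             xs=[0, 3], ys=[0, 4])
        raw = ingest.bin_translations(frames)
        assert raw[ts("2023-03-06 10:15")] == 5.0
        assert raw[ts("2023-03-06 10:00")] == 0.0

    def test_conservation_over_epoch_boundaries(self):
        rng = np.random.default_rng(31)
        n = 600
        times = pd.date_range(ts("2023-03-06 09:03"), periods=n, freq="7s")
        frames = make_frames(times, xs=np.cumsum(rng.normal(0, 0.3, n)),
                             ys=np.cumsum(rng.normal(0, 0.3, n)))
        raw = ingest.bin_translations(frames)
        whole = ingest.total_translation(frames, raw.index[0],
                                         raw.index[-1] + pd.Timedelta(minutes=15))
        assert raw.sum() == pytest.approx(whole, rel=1e-12)

    def test_epoch_totals_match_naive_brute_force(self):
        rng = np.random.default_rng(32)
        n = 1000
        times = pd.date_range(ts("2023-03-06 09:00"), periods=n, freq="2s")
        frames = make_frames(times, xs=rng.uniform(0, 5, n), ys=rng.uniform(0, 5, n))
        raw = ingest.bin_translations(frames)
        f = frames.sort_values("timestamp").reset_index(drop=True)
        for epoch_start, total in raw.items():
            expected = 0.0
            for i in range(1, n):
                t = f.loc[i, "timestamp"]
                if epoch_start <= t < epoch_start + pd.Timedelta(minutes=15):
                    expected += np.hypot(f.loc[i, "x"] - f.loc[i - 1, "x"],
                                         f.loc[i, "y"] - f.loc[i - 1, "y"])
            assert total == pytest.approx(expected, rel=1e-12)

    def test_frameless_epochs_are_missing_not_zero(self):
        frames = make_frames(["2023-03-06 10:00:00", "2023-03-06 10:00:10",
                              "2023-03-06 10:40:00", "2023-03-06 10:40:10"],
                             xs=[0, 1, 0, 1], ys=[0, 0, 0, 0])
        raw = ingest.bin_translations(frames)
        assert np.isnan(raw[ts("2023-03-06 10:15")])
        assert raw[ts("2023-03-06 10:00")] == 1.0

    def test_rebinning_aligned_series_is_noop(self):
        frames = make_frames(["2023-03-06 10:00:00", "2023-03-06 10:00:30",
                              "2023-03-06 10:15:00", "2023-03-06 10:15:30"],
                             xs=[0, 1, 1, 3], ys=[0, 0, 0, 0])
        raw1 = ingest.bin_translations(frames)
        raw2 = ingest.bin_translations(frames, epoch_minutes=15)
        pd.testing.assert_series_equal(raw1, raw2)


class TestNormalization:
    def test_running_max_examples(self):
        idx = pd.date_range(ts("2023-03-06 10:00"), periods=2, freq="15min")
        up = ingest.normalize_activity(pd.Series([5.0, 10.0], index=idx))
        assert list(up["activity_pct"]) == [100.0, 100.0]
        down = ingest.normalize_activity(pd.Series([10.0, 5.0], index=idx))
        assert list(down["activity_pct"]) == [100.0, 50.0]

    def test_all_zero_raw_gives_zero_activity(self):
        idx = pd.date_range(ts("2023-03-06 10:00"), periods=4, freq="15min")
        out = ingest.normalize_activity(pd.Series(np.zeros(4), index=idx))
        assert (out["activity_pct"] == 0.0).all()

    def test_maximum_reaches_100_once_nonzero(self):
        rng = np.random.default_rng(33)
        idx = pd.date_range(ts("2023-03-06 00:00"), periods=96, freq="15min")
        out = ingest.normalize_activity(pd.Series(rng.uniform(0, 20, 96), index=idx))
        assert out["activity_pct"].max() == 100.0
        assert ((out["activity_pct"] >= 0) & (out["activity_pct"] <= 100)).all()

    def test_global_max_mode(self):
        idx = pd.date_range(ts("2023-03-06 10:00"), periods=3, freq="15min")
        out = ingest.normalize_activity(pd.Series([5.0, 20.0, 10.0], index=idx),
                                        mode="global_max")
        assert list(out["activity_pct"]) == [25.0, 100.0, 50.0]

    def test_negative_raw_rejected(self):
        idx = pd.date_range(ts("2023-03-06 10:00"), periods=2, freq="15min")
        with pytest.raises(ingest.IngestError):
            ingest.normalize_activity(pd.Series([1.0, -0.5], index=idx))

    def test_missing_epochs_stay_missing(self):
        idx = pd.date_range(ts("2023-03-06 10:00"), periods=3, freq="15min")
        out = ingest.normalize_activity(pd.Series([5.0, np.nan, 10.0], index=idx))
        assert np.isnan(out["activity_pct"].iloc[1])


class TestOccupancy:
    room_map = {"s1": "flat1"}

    def test_continuous_frames_cover_epoch(self):
        times = pd.date_range(ts("2023-03-06 10:00"), ts("2023-03-06 10:15"), freq="30s")
        frames = make_frames(times, xs=np.zeros(len(times)), ys=np.zeros(len(times)))
        occ = ingest.occupancy_fraction(frames, self.room_map)
        assert occ.loc[ts("2023-03-06 10:00"), "present_fraction"] == pytest.approx(1.0)

    def test_half_epoch_presence(self):
        times = pd.date_range(ts("2023-03-06 10:00"), ts("2023-03-06 10:07:30"), freq="15s")
        frames = make_frames(times, xs=np.zeros(len(times)), ys=np.zeros(len(times)))
        occ = ingest.occupancy_fraction(frames, self.room_map, gap_threshold_s=30)
        assert occ.loc[ts("2023-03-06 10:00"), "present_fraction"] == pytest.approx(
            0.5, abs=15 / 900)

    def test_gap_longer_than_threshold_counts_as_absence(self):
        frames = make_frames(["2023-03-06 10:00:00", "2023-03-06 10:14:00"],
                             xs=[0, 0], ys=[0, 0])
        occ = ingest.occupancy_fraction(frames, self.room_map, gap_threshold_s=60)
        assert occ.loc[ts("2023-03-06 10:00"), "present_fraction"] == pytest.approx(0.0)

    def test_unmapped_sensor_rejected(self):
        frames = make_frames(["2023-03-06 10:00:00"], xs=[0], ys=[0], sensor="ghost")
        with pytest.raises(ingest.IngestError):
            ingest.occupancy_fraction(frames, self.room_map)


class TestRoundTrip:
    def test_jsonl_and_csv_round_trip(self, tmp_path):
        frames = make_frames(["2023-03-06 10:00:00", "2023-03-06 10:00:01"],
                             xs=[0.0, 1.5], ys=[2.0, 2.5])
        p1 = tmp_path / "frames.jsonl"
        ingest.write_frames_jsonl(frames, p1)
        back = ingest.read_frames_jsonl(p1)
        assert list(back["x"]) == [0.0, 1.5]
        assert back["timestamp"].iloc[0] == frames["timestamp"].iloc[0]
        p2 = tmp_path / "frames.csv"
        ingest.write_frames_csv(frames, p2)
        back2 = ingest.read_frames_csv(p2)
        assert back2["timestamp"].iloc[1] == frames["timestamp"].iloc[1]
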