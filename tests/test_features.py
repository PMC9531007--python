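import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contextprofile.features import (FEATURES, EventRun, build_feature_series,
                                     collapse_runs, daily_counts, hourly_histogram,
                                     location_durations, wasserstein_1d)
from contextprofile.streams import SensorEventStream


def stream(rows, pid="p"):
    ev = pd.DataFrame(rows, columns=["timestamp", "location"])
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    return SensorEventStream(patient_id=pid, events=ev)


def run(loc, first, last=None, n=1):
    first = pd.Timestamp(first)
    return EventRun(loc, first, pd.Timestamp(last) if last else first, n)


class TestCollapseRuns:
    def test_consecutive_same_sensor_collapsed(self):
        s = stream([("2021-01-01 00:10", "bathroom"), ("2021-01-01 00:11", "bathroom"),
                    ("2021-01-01 00:12", "bathroom"), ("2021-01-01 07:00", "kitchen"),
                    ("2021-01-01 07:30", "kitchen"), ("2021-01-01 08:00", "bathroom")])
        runs = collapse_runs(s)
        got = [(r.location, r.first_firing.strftime("%H:%M"),
                r.last_firing.strftime("%H:%M"), r.n_firings) for r in runs]
        assert got == [("bathroom", "00:10", "00:12", 3),
                       ("kitchen", "07:00", "07:30", 2),
                       ("bathroom", "08:00", "08:00", 1)]

    def test_single_event(self):
        runs = collapse_runs(stream([("2021-01-01 09:00", "lounge")]))
        assert len(runs) == 1 and runs[0].first_firing == runs[0].last_firing

    def test_alternating_locations_untouched(self):
        rows = [(f"2021-01-01 0{h}:00", loc)
                for h, loc in enumerate(["bathroom", "kitchen"] * 3)]
        assert len(collapse_runs(stream(rows))) == 6

    def test_idempotent(self):
        s = stream([("2021-01-01 00:10", "bathroom"), ("2021-01-01 00:11", "bathroom"),
                    ("2021-01-01 01:00", "kitchen")])
        runs = collapse_runs(s)
        again = stream([(r.first_firing, r.location) for r in runs])
        assert [(r.location, r.first_firing) for r in collapse_runs(again)] == \
               [(r.location, r.first_firing) for r in runs]

    def test_unknown_location_dropped_with_warning(self, caplog):
        s = stream([("2021-01-01 00:10", "bathroom"), ("2021-01-01 00:20", "garage")])
        with caplog.at_level("WARNING"):
            runs = collapse_runs(s)
        assert len(runs) == 1
        assert any("garage" in r.message for r in caplog.records)


class TestLocationDurations:
    def test_dwell_until_next_run(self):
        runs = [run("bathroom", "2021-01-01 00:10", "2021-01-01 00:12", 3),
                run("kitchen", "2021-01-01 07:00")]
        d = location_durations(runs)
        assert d.loc[pd.Timestamp("2021-01-01"), "bathroom"] == 408  # 07:00 - 00:12

    def test_single_run_zero_dwell(self):
        assert location_durations([run("bathroom", "2021-01-01 10:00")]).empty

    def test_midnight_split(self):
        runs = [run("bedroom", "2021-01-01 23:50"), run("kitchen", "2021-01-02 00:20")]
        d = location_durations(runs)
        assert d.loc[pd.Timestamp("2021-01-01"), "bedroom"] == 10
        assert d.loc[pd.Timestamp("2021-01-02"), "bedroom"] == 20

    def test_capped_at_1440(self):
        runs = [run("bedroom", "2021-01-01 12:00"), run("kitchen", "2021-01-04 12:00")]
        d = location_durations(runs)
        assert d["bedroom"].max() == 1440

    def test_out_of_order_runs_rejected(self):
        runs = [run("bedroom", "2021-01-02 00:00"), run("kitchen", "2021-01-01 00:00")]
        with pytest.raises(ValueError):
            location_durations(runs)


class TestDailyCounts:
    def test_early_morning_window_half_open(self):
        runs = [run("bathroom", "2021-01-01 00:10"), run("kitchen", "2021-01-01 03:00"),
                run("bathroom", "2021-01-01 05:59"), run("kitchen", "2021-01-01 06:30"),
                run("bathroom", "2021-01-01 06:00")]
        c = daily_counts(runs)
        assert c.loc[pd.Timestamp("2021-01-01"), "bathroom_em"] == 2

    def test_late_evening_attributed_to_next_day(self):
        runs = [run("bedroom", "2021-01-01 23:30"), run("kitchen", "2021-01-02 10:00")]
        c = daily_counts(runs)
        assert c.loc[pd.Timestamp("2021-01-02"), "bedroom_le"] == 1
        assert c.loc[pd.Timestamp("2021-01-01"), "bedroom_le"] == 0

    def test_no_runs_empty(self):
        assert daily_counts([]).empty

    def test_raw_counts_use_firings(self):
        runs = [run("bathroom", "2021-01-01 01:00", "2021-01-01 01:05", n=4)]
        assert daily_counts(runs, counts="raw").loc[
            pd.Timestamp("2021-01-01"), "bathroom_em"] == 4
        assert daily_counts(runs, counts="runs").loc[
            pd.Timestamp("2021-01-01"), "bathroom_em"] == 1


class TestHourlyHistogram:
    def test_point_mass(self):
        runs = [run("lounge", "2021-01-01 02:10"), run("lounge", "2021-01-01 02:30"),
                run("lounge", "2021-01-01 02:50")]
        h = hourly_histogram(runs, "2021-01-01", "lounge")
        assert h[2] == 1.0 and h.sum() == 1.0

    def test_zero_runs_uniform(self):
        h = hourly_histogram([], "2021-01-01", "lounge")
        assert np.allclose(h, 1 / 24)

    def test_two_runs_split(self):
        runs = [run("lounge", "2021-01-01 00:10"), run("lounge", "2021-01-01 12:10")]
        h = hourly_histogram(runs, "2021-01-01", "lounge")
        assert h[0] == 0.5 and h[12] == 0.5


class TestWasserstein:
    def test_identity(self):
        p = np.full(24, 1 / 24)
        assert wasserstein_1d(p, p) == 0.0

    def test_point_masses(self):
        p, q = np.zeros(24), np.zeros(24)
        p[2], q[5] = 1.0, 1.0
        assert wasserstein_1d(p, q) == pytest.approx(3.0)

    def test_half_split(self):
        p, q = np.zeros(24), np.zeros(24)
        p[0] = 1.0
        q[0], q[1] = 0.5, 0.5
        assert wasserstein_1d(p, q) == pytest.approx(0.5)

    def test_rejects_unnormalised(self):
        with pytest.raises(ValueError):
            wasserstein_1d(np.full(24, 1 / 24), np.full(24, 1 / 12))

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0.01, 10), min_size=24, max_size=24),
           st.lists(st.floats(0.01, 10), min_size=24, max_size=24),
           st.lists(st.floats(0.01, 10), min_size=24, max_size=24))
    def test_metric_properties(self, a, b, c):
        p = np.array(a) / np.sum(a)
        q = np.array(b) / np.sum(b)
        r = np.array(c) / np.sum(c)
        dpq = wasserstein_1d(p, q)
        assert dpq >= 0
        assert dpq == pytest.approx(wasserstein_1d(q, p), abs=1e-12)
        assert wasserstein_1d(p, p) == pytest.approx(0.0, abs=1e-12)
        assert dpq <= wasserstein_1d(p, r) + wasserstein_1d(r, q) + 1e-9


class TestBuildFeatureSeries:
    def _daily_stream(self, n_days=10):
        rows = []
        for d in range(n_days):
            base = pd.Timestamp("2021-01-01") + pd.Timedelta(days=d)
            rows += [(base + pd.Timedelta(hours=8), "bathroom"),
                     (base + pd.Timedelta(hours=12), "kitchen"),
                     (base + pd.Timedelta(hours=20), "bedroom")]
        return stream(rows)

    def test_shape_contract(self):
        fs = build_feature_series(self._daily_stream(10))
        assert fs.frame.shape == (10, 11)
        assert list(fs.frame.columns) == list(FEATURES)

    def test_identical_days_zero_wasserstein(self):
        fs = build_feature_series(self._daily_stream(8))
        assert np.allclose(fs.frame["bathroom_wass"].iloc[1:], 0.0)
        assert np.allclose(fs.frame.iloc[0][["bathroom_wass", "hallway_wass",
                                             "lounge_wass"]], 0.0)

    def test_missing_day_masked_and_zero_filled(self):
        rows = [("2021-01-01 08:00", "bathroom"), ("2021-01-03 08:00", "kitchen")]
        fs = build_feature_series(stream(rows))
        day2 = pd.Timestamp("2021-01-02")
        assert bool(fs.missing[day2])
        assert np.allclose(fs.frame.loc[day2], 0.0)
        assert fs.observed_days == 2

    def test_features_finite_and_nonnegative(self, small_features):
        for fs in small_features:
            assert np.isfinite(fs.frame.to_numpy()).all()
            assert (fs.frame.to_numpy() >= 0).all()

    def test_daily_durations_bounded(self, small_features):
        for fs in small_features:
            assert (fs.frame["bedroom_duration"] <= 1440).all()
            assert (fs.frame["bathroom_duration"] <= 1440).all()

    def test_empty_stream_rejected(self):
        ev = pd.DataFrame(columns=["timestamp", "location"])
        with pytest.raises(ValueError):
            build_feature_series(SensorEventStream(patient_id="e", events=ev))

    def test_uti_episode_elevates_night_bathroom_counts(self, small_cfg, small_cohort,
                                                        small_features):
        from contextprofile.synth import simulate_visits
        elevated = 0
        total = 0
        for idx, (fs, (_, lb)) in enumerate(zip(small_features, small_cohort)):
            _, episodes = simulate_visits(small_cfg, idx)
            for ep in episodes:
                if ep.kind != "UTI":
                    continue
                days = fs.frame.index[ep.start_day:ep.start_day + ep.duration]
                inside = fs.frame.loc[days, "bathroom_em"].mean()
                outside_mask = np.ones(len(fs.frame), bool)
                outside_mask[ep.start_day:ep.start_day + ep.duration] = False
                outside = fs.frame.loc[outside_mask, "bathroom_em"].mean()
                total += 1
                if inside > outside:
                    elevated += 1
        assert total >= 1 and elevated == total
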