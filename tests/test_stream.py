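import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cokurt.errors import ConfigurationError, OrderingError
from cokurt.stream import (
    VitalsSeries,
    WindowSpec,
    stream_process,
    window_latent_features,
    window_slices,
)

from .conftest import make_series


class TestWindowSpec:
    def test_slide_exceeding_window_rejected(self):
        with pytest.raises(ConfigurationError):
            WindowSpec(window=3600, slide=7200)

    def test_zero_slide_rejected(self):
        with pytest.raises(ConfigurationError):
            WindowSpec(window=3600, slide=0)

    @pytest.mark.parametrize(
        "w_min,s_min", [(60, 30), (120, 60), (60, 60), (120, 120)]
    )
    def test_standard_configurations_accepted(self, w_min, s_min):
        spec = WindowSpec(window=w_min * 60, slide=s_min * 60)
        assert spec.slide <= spec.window


class TestWindowSlices:
    def test_three_hours_hourly_half_overlap(self, flat_series):
        slices = window_slices(flat_series, WindowSpec(3600, 1800))
        assert len(slices) == 5
        starts = [(s - flat_series.timestamps[0]) / np.timedelta64(60, "s") for s, _ in slices]
        assert starts == [0, 30, 60, 90, 120]

    def test_non_overlapping_partition(self, flat_series):
        slices = window_slices(flat_series, WindowSpec(3600, 3600))
        assert len(slices) == 3
        for (s1, e1), (s2, _) in zip(slices, slices[1:]):
            assert e1 == s2

    def test_span_shorter_than_window_warns_empty(self):
        s = make_series([60.0] * 10, [0] * 10)
        with pytest.warns(UserWarning, match="shorter than window"):
            assert window_slices(s, WindowSpec(3600, 3600)) == []

    @given(
        n_minutes=st.integers(min_value=1, max_value=600),
        w=st.integers(min_value=1, max_value=120),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_count_formula(self, n_minutes, w, data):
        s_min = data.draw(st.integers(min_value=1, max_value=w))
        series = make_series(np.full(n_minutes, 70.0), np.zeros(n_minutes, int))
        T = n_minutes * 60
        spec = WindowSpec(w * 60, s_min * 60)
        if T < spec.window:
            with pytest.warns(UserWarning):
                slices = window_slices(series, spec)
            assert slices == []
        else:
            slices = window_slices(series, spec)
            assert len(slices) == (T - spec.window) // spec.slide + 1


class TestLatentFeatures:
    def test_all_resting_constant(self, flat_series):
        start = flat_series.timestamps[0]
        f = window_latent_features(flat_series, start, start + np.timedelta64(3600, "s"))
        assert f.rhr == f.ohr == 65.0
        assert f.ahr is None
        assert f.step_total == 0
        assert f.degenerate

    def test_two_record_hand_computation(self):
        s = make_series([60.0, 120.0], [0, 100])
        f = window_latent_features(s, s.timestamps[0], s.timestamps[0] + np.timedelta64(120, "s"))
        assert f.rhr == 60.0
        assert f.ahr == 120.0
        assert f.ohr == 90.0
        assert f.step_total == 100
        assert f.n_minutes == 2

    def test_empty_window_is_gap(self, flat_series):
        start = flat_series.timestamps[-1] + np.timedelta64(3600, "s")
        assert window_latent_features(flat_series, start, start + np.timedelta64(60, "s")) is None

    def test_rhr_imputed_when_no_resting_minute(self):
        hr = np.linspace(90.0, 120.0, 20)
        s = make_series(hr, np.full(20, 80))
        f = window_latent_features(s, s.timestamps[0], s.timestamps[0] + np.timedelta64(1200, "s"))
        assert f.rhr_imputed
        assert f.rhr == pytest.approx(np.sort(hr)[:2].mean())

    def test_low_coverage_flagged(self):
        # 10 records inside a 60-minute window -> < 50% coverage
        s = make_series(np.full(10, 70.0), np.zeros(10, int))
        f = window_latent_features(s, s.timestamps[0], s.timestamps[0] + np.timedelta64(3600, "s"))
        assert f.low_coverage

    def test_bounds_invariant(self):
        rng = np.random.default_rng(0)
        hr = rng.uniform(55, 150, size=60)
        steps = rng.integers(0, 100, size=60)
        s = make_series(hr, steps)
        f = window_latent_features(s, s.timestamps[0], s.timestamps[0] + np.timedelta64(3600, "s"))
        assert hr.min() <= f.rhr <= hr.max()
        assert hr.min() <= f.ohr <= hr.max()
        if f.ahr is not None:
            assert hr.min() <= f.ahr <= hr.max()


class TestStreamProcess:
    def test_matches_batch_path(self, small_cohort):
        series = small_cohort[0].series
        spec = WindowSpec(3600, 1800)
        streamed = stream_process(series, spec)
        batch = [
            f
            for start, end in window_slices(series, spec)
            if (f := window_latent_features(series, start, end)) is not None
        ]
        assert len(streamed) == len(batch)
        for a, b in zip(streamed, batch):
            assert a.window_start == b.window_start
            assert a.rhr == pytest.approx(b.rhr)
            assert a.step_total == b.step_total

    def test_deterministic_replay(self, flat_series):
        spec = WindowSpec(3600, 1800)
        r1 = stream_process(flat_series, spec)
        r2 = stream_process(flat_series, spec)
        assert [(f.window_start, f.rhr, f.step_total) for f in r1] == [
            (f.window_start, f.rhr, f.step_total) for f in r2
        ]

    def test_series_of_exactly_one_window(self):
        s = make_series(np.full(60, 70.0), np.zeros(60, int))
        assert len(stream_process(s, WindowSpec(3600, 3600))) == 1

    def test_memory_contract(self):
        rng = np.random.default_rng(1)
        n = 1440  # 24 h
        s = make_series(rng.uniform(55, 90, n), rng.integers(0, 50, n))
        trace: list[int] = []
        spec = WindowSpec(3600, 1800)
        stream_process(s, spec, queue_trace=trace)
        assert max(trace) <= int(np.ceil(spec.window / s.cadence))

    def test_consumer_callback(self, flat_series):
        seen = []
        out = stream_process(flat_series, WindowSpec(3600, 3600), consumer=seen.append)
        assert seen == out

    def test_out_of_order_raises(self, flat_series):
        flat_series = make_series(np.full(120, 65.0), np.zeros(120, int))
        # corrupt the series post-validation to simulate a bad stream
        flat_series.timestamps = flat_series.timestamps.copy()
        flat_series.timestamps[50] = flat_series.timestamps[10]
        with pytest.raises(OrderingError):
            stream_process(flat_series, WindowSpec(3600, 1800))

    def test_overlap_is_union_of_two_interleaved_passes(self, small_cohort):
        series = small_cohort[1].series
        w = 7200
        overlapped = stream_process(series, WindowSpec(w, w // 2))
        pass_a = stream_process(series, WindowSpec(w, w))
        # second pass offset by w/2: trim the head of the series
        mask = series.timestamps >= series.timestamps[0] + np.timedelta64(w // 2, "s")
        shifted = VitalsSeries(
            user_id=series.user_id,
            timestamps=series.timestamps[mask],
            heart_rate=series.heart_rate[mask],
            steps=series.steps[mask],
            cadence=series.cadence,
        )
        pass_b = stream_process(shifted, WindowSpec(w, w))
        union = sorted(pass_a + pass_b, key=lambda f: f.window_start.astype("int64"))
        starts_union = [f.window_start for f in union]
        starts_overlap = [f.window_start for f in overlapped]
        assert starts_overlap[: len(starts_union)] == starts_union

    def test_order_insensitive_after_sort(self):
        rng = np.random.default_rng(2)
        n = 240
        hr = rng.uniform(55, 90, n)
        steps = rng.integers(0, 60, n)
        s1 = make_series(hr, steps)
        perm = rng.permutation(n)
        order = np.argsort(perm, kind="stable")
        # shuffle then sort back: identical stream
        s2 = make_series(hr[perm][order], steps[perm][order])
        f1 = stream_process(s1, WindowSpec(3600, 1800))
        f2 = stream_process(s2, WindowSpec(3600, 1800))
        assert [(f.rhr, f.step_total) for f in f1] == [(f.rhr, f.step_total) for f in f2]


class TestVitalsSeriesValidation:
    def test_rejects_duplicate_timestamps(self):
        ts = np.array(["2024-01-01T00:00:00"] * 2, dtype="datetime64[s]")
        with pytest.raises(OrderingError):
            VitalsSeries("u", ts, np.array([60.0, 61.0]), np.array([0, 0]))

    def test_rejects_out_of_range_heart_rate(self):
        with pytest.raises(Exception):
            make_series([10.0, 60.0], [0, 0])
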