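import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lasersprint import (
    ArtifactMask,
    CalibratedTrace,
    SimConfig,
    StartEndConfig,
    apply_calibration,
    crop,
    detect_artifacts,
    detect_end,
    detect_start,
    moving_average,
    repair_artifacts,
    synthesize_trace,
)
from lasersprint.errors import (
    ConfigError,
    EndNotReached,
    NoStartDetected,
    RepairError,
)


def brute_force_moving_average(y, n, m):
    """Independent O(len*n) oracle: clipped centered window mean."""
    y = np.asarray(y, dtype=float)
    left, right = (n - 1) // 2, n // 2
    out = y.copy()
    for _ in range(m):
        nxt = np.empty_like(out)
        for i in range(len(out)):
            lo = max(0, i - left)
            hi = min(len(out), i + right + 1)
            nxt[i] = np.mean(out[lo:hi])
        out = nxt
    return out


def make_trace(x, rate=100.0):
    x = np.asarray(x, dtype=float)
    return CalibratedTrace(t=np.arange(x.size) / rate, x=x, L1=7.3,
                           nominal_rate=rate)


class TestMovingAverage:
    def test_constant_preserved(self):
        for n in (1, 2, 3, 10):
            np.testing.assert_array_equal(
                moving_average([5.0, 5, 5, 5], n), [5.0, 5, 5, 5]
            )

    def test_window_one_is_identity(self):
        y = np.array([1.0, -2.0, 3.5])
        np.testing.assert_array_equal(moving_average(y, 1), y)

    def test_edge_truncation(self):
        np.testing.assert_allclose(
            moving_average([0.0, 1, 2, 3, 4], 3), [0.5, 1, 2, 3, 3.5]
        )

    def test_window_spans_tenth_second_at_100hz(self):
        # n=10 covers 10 samples = 0.1 s at 100 Hz
        t = np.arange(100) / 100.0
        y = np.zeros(100)
        y[50] = 1.0
        out = moving_average(y, 10)
        assert np.count_nonzero(out) == 10

    def test_invalid_window(self):
        with pytest.raises(ConfigError):
            moving_average([1.0, 2.0], 0)
        with pytest.raises(ConfigError):
            moving_average([1.0, 2.0], 3, passes_m=0)

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=60,
        ),
        st.integers(min_value=1, max_value=12),
        st.integers(min_value=1, max_value=3),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, y, n, m):
        np.testing.assert_allclose(
            moving_average(y, n, m),
            brute_force_moving_average(y, n, m),
            rtol=1e-9,
            atol=1e-9,
        )

    @given(
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
            min_size=1,
            max_size=50,
        ),
        st.integers(min_value=1, max_value=15),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_input_range(self, y, n):
        out = moving_average(y, n)
        assert np.min(out) >= np.min(y) - 1e-9
        assert np.max(out) <= np.max(y) + 1e-9


class TestArtifacts:
    def test_clean_trace_empty_mask(self, clean_sim_config):
        raw, _ = synthesize_trace(clean_sim_config)
        cal = apply_calibration(raw, clean_sim_config.L1)
        mask = detect_artifacts(cal)
        assert mask.n_segments == 0

    def test_single_spike_flagged(self):
        # 10 m/s run; one sample displaced by +2 m implies 200 m/s in/out
        x = 10.0 * np.arange(200) / 100.0
        x[100] += 2.0
        mask = detect_artifacts(make_trace(x))
        assert mask.segments == [(100, 101)]
        assert mask.causes == ["spike"]

    def test_nan_run_flagged_as_dropout(self):
        x = 10.0 * np.arange(200) / 100.0
        x[50:55] = np.nan
        mask = detect_artifacts(make_trace(x))
        assert mask.segments == [(50, 55)]
        assert mask.causes == ["dropout"]

    def test_spike_repaired_to_neighbour_midpoint(self):
        x = 10.0 * np.arange(200) / 100.0
        clean = x.copy()
        x[100] += 2.0
        trace = make_trace(x)
        repaired = repair_artifacts(trace, detect_artifacts(trace))
        assert repaired.x[100] == pytest.approx(
            0.5 * (clean[99] + clean[101]), abs=1e-12
        )

    def test_empty_mask_identity(self):
        trace = make_trace(np.linspace(0, 10, 50))
        out = repair_artifacts(trace, ArtifactMask())
        np.testing.assert_array_equal(out.x, trace.x)

    def test_dropout_on_constant_velocity_lies_on_line(self):
        x = 8.0 * np.arange(300) / 100.0
        clean = x.copy()
        x[120:125] = np.nan
        trace = make_trace(x)
        repaired = repair_artifacts(trace, detect_artifacts(trace))
        np.testing.assert_allclose(repaired.x[120:125], clean[120:125],
                                   atol=1e-9)

    def test_unflagged_samples_bit_identical(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(0.05, 0.01, 400))
        x[200:203] = np.nan
        trace = make_trace(x)
        mask = detect_artifacts(trace)
        repaired = repair_artifacts(trace, mask)
        flagged = mask.indices(trace.n)
        np.testing.assert_array_equal(repaired.x[~flagged],
                                      trace.x[~flagged])

    def test_full_mask_rejected(self):
        trace = make_trace(np.full(20, np.nan))
        with pytest.raises(RepairError):
            repair_artifacts(trace, detect_artifacts(trace))

    def test_edge_segment_cropped(self):
        x = 10.0 * np.arange(100) / 100.0
        x[:5] = np.nan
        trace = make_trace(x)
        mask = detect_artifacts(trace)
        assert mask.causes[0] == "edge"
        repaired = repair_artifacts(trace, mask)
        assert repaired.n == 95
        assert repaired.t[0] == trace.t[5]


class TestStartDetection:
    def test_ramp_start_at_first_hold(self):
        x = np.concatenate([np.zeros(100), 0.05 * np.arange(1, 101)])
        start = detect_start(make_trace(x), StartEndConfig())
        assert start == 100

    def test_pure_noise_no_start(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 0.005, 500)
        with pytest.raises(NoStartDetected):
            detect_start(make_trace(x), StartEndConfig())

    def test_simulated_start_within_tolerance(self, noisy_sim_config):
        raw, gt = synthesize_trace(noisy_sim_config)
        cal = apply_calibration(raw, noisy_sim_config.L1)
        start = detect_start(cal, StartEndConfig(start_smooth_n=10))
        t_detected = cal.t[start]
        assert gt.start_time - 0.05 <= t_detected <= gt.start_time + 0.10

    def test_translation_equivariance(self):
        x = np.concatenate([np.zeros(100), 0.05 * np.arange(1, 101)])
        cfg = StartEndConfig()
        base = detect_start(make_trace(x), cfg)
        for shift in (-3.0, 2.5, 100.0):
            assert detect_start(make_trace(x + shift), cfg) == base

    def test_pre_window_longer_than_trace(self):
        with pytest.raises(ConfigError):
            detect_start(make_trace(np.zeros(50)), StartEndConfig())


class TestEndDetection:
    def test_ramp_end_rule(self):
        # 0.1 m per sample from zero: first x > 6 at index 61
        x = np.arange(200) / 10.0
        cfg = StartEndConfig(end_distance=6.0, end_extra_points=5)
        assert detect_end(make_trace(x), cfg) == 66

    def test_zero_extension(self):
        x = np.arange(200) / 10.0
        cfg = StartEndConfig(end_distance=6.0, end_extra_points=0)
        assert detect_end(make_trace(x), cfg) == 61

    def test_end_not_reached(self):
        x = np.arange(200) / 10.0  # tops out at 19.9 m
        with pytest.raises(EndNotReached):
            detect_end(make_trace(x), StartEndConfig(end_distance=200.0))

    def test_clipped_to_last_sample(self):
        x = np.arange(100) / 10.0
        cfg = StartEndConfig(end_distance=9.8, end_extra_points=50)
        assert detect_end(make_trace(x), cfg) == 99


class TestCrop:
    def test_pad_window(self):
        trace = make_trace(np.arange(2000) / 10.0)
        cfg = StartEndConfig(crop_pad=1.0, rezero_time=False)
        out = crop(trace, 200, 1300, cfg)
        assert out.n == 1301
        assert out.t[0] == trace.t[100]
        assert out.t[-1] == trace.t[1400]

    def test_zero_pad(self):
        trace = make_trace(np.arange(500) / 10.0)
        cfg = StartEndConfig(crop_pad=0.0, rezero_time=False)
        out = crop(trace, 100, 300, cfg)
        assert out.n == 201
        assert out.t[0] == trace.t[100]

    def test_clip_at_bounds(self):
        trace = make_trace(np.arange(500) / 10.0)
        cfg = StartEndConfig(crop_pad=1.0, rezero_time=False)
        out = crop(trace, 50, 300, cfg)
        assert out.t[0] == trace.t[0]

    def test_rezero(self):
        trace = make_trace(np.arange(500) / 10.0)
        out = crop(trace, 200, 400, StartEndConfig(crop_pad=0.5))
        assert out.t[np.argmin(np.abs(out.t))] == pytest.approx(0.0)

    def test_invalid_order(self):
        trace = make_trace(np.arange(100) / 10.0)
        with pytest.raises(ConfigError):
            crop(trace, 50, 50, StartEndConfig())
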