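"""Baseline fitting, peak detection and dF/F response-call tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import uniform_filter1d

import dffpipe as dp
from dffpipe.synthetic import render_movie, transient_kernel
from dffpipe.traces import response_window_mask

from conftest import all_respond_class, fast_config


def _empty_schedule(n_frames, frame_interval=1.0):
    return dp.StimulusSchedule(events=[], frame_interval=frame_interval, n_frames=n_frames)


def _one_event_schedule(onset, offset, n_frames, frame_interval=1.0, label="SE"):
    return dp.StimulusSchedule(
        events=[dp.StimulusEvent(label, None, onset, offset)],
        frame_interval=frame_interval,
        n_frames=n_frames,
    )


def _synthetic_cell_trace(amplitude, onset_s, n_frames, fi, b0=2000.0,
                          bleach_tau=600.0, noise=0.0, rng=None):
    """Forward-model ROI trace: bleaching baseline plus one transient."""
    t = np.arange(n_frames) * fi
    k = transient_kernel(t - onset_s, 1.0, 8.0)
    values = b0 * np.exp(-t / bleach_tau) * (1.0 + amplitude * k)
    if noise > 0:
        values = values + rng.normal(0, noise, size=n_frames)
    return dp.Trace(values=values, frame_interval=fi)


class TestExtractTrace:
    def test_uniform_frames(self):
        movie = dp.Movie(np.full((5, 8, 8), 7.0), frame_interval=1.0)
        roi = dp.ROI(pixels=np.array([[2, 2], [2, 3], [3, 2]]), source_stimulus="SE")
        trace = dp.extract_trace(movie, roi)
        np.testing.assert_allclose(trace.values, 7.0)

    def test_single_pixel_roi_equals_pixel_series(self, rng):
        data = rng.uniform(0, 100, size=(10, 6, 6))
        movie = dp.Movie(data, frame_interval=1.0)
        roi = dp.ROI(pixels=np.array([[4, 1]]), source_stimulus="SE")
        trace = dp.extract_trace(movie, roi)
        np.testing.assert_allclose(trace.values, data[:, 4, 1])

    def test_out_of_frame_roi_rejected(self):
        movie = dp.Movie(np.zeros((3, 4, 4)), frame_interval=1.0)
        roi = dp.ROI(pixels=np.array([[5, 5]]), source_stimulus="SE")
        with pytest.raises(ValueError):
            dp.extract_trace(movie, roi)

    def test_noiseless_synthetic_trace_matches_forward_model(self):
        cfg = fast_config(n_cells=1, noise_sigma=0.0, drift_per_frame=0.0,
                          frame_interval=0.5, tuning_classes=all_respond_class(0.6))
        sched = dp.generate_stimulus_schedule(cfg, [("SE", None)])
        movie, truth = dp.generate_slice_movie(cfg, sched)
        rr, cc = dp.synthetic.cell_pixels(tuple(truth.cell_centers[0]),
                                          truth.cell_radii[0], cfg.image_shape)
        roi = dp.ROI(pixels=np.column_stack([rr, cc]), source_stimulus="SE")
        trace = dp.extract_trace(movie, roi)
        t = movie.times
        k = transient_kernel(t - sched.onset_seconds(sched.events[0]),
                             cfg.transient_rise_tau, cfg.transient_decay_tau)
        expected = truth.cell_baselines[0] * np.exp(-t / cfg.bleach_tau) * (1 + 0.6 * k)
        np.testing.assert_allclose(trace.values, expected, rtol=1e-5)


class TestFitBaseline:
    def test_noiseless_exponential_recovered_within_1pct(self):
        t = np.arange(1200) * 0.5
        trace = dp.Trace(values=200.0 * np.exp(-t / 300.0), frame_interval=0.5)
        model = dp.fit_baseline(trace, _empty_schedule(1200, 0.5))
        assert model.model_kind == "exponential"
        b0, tau = model.parameters
        assert b0 == pytest.approx(200.0, rel=0.01)
        assert tau == pytest.approx(300.0, rel=0.01)

    def test_constant_trace_constant_model(self):
        trace = dp.Trace(values=np.full(50, 100.0), frame_interval=1.0)
        model = dp.fit_baseline(trace, _empty_schedule(50))
        assert model.model_kind == "constant"
        assert model.parameters == (100.0,)

    def test_masked_transient_leaves_tau_unchanged_within_2pct(self):
        n, fi = 600, 1.0
        onset = 200
        sched = _one_event_schedule(onset, onset + 30, n, fi)
        clean = _synthetic_cell_trace(0.0, onset, n, fi, bleach_tau=400.0)
        bumpy = _synthetic_cell_trace(1.0, onset, n, fi, bleach_tau=400.0)
        tau_clean = dp.fit_baseline(clean, sched, response_window_s=60.0).parameters[1]
        tau_bumpy = dp.fit_baseline(bumpy, sched, response_window_s=60.0).parameters[1]
        assert tau_bumpy == pytest.approx(tau_clean, rel=0.02)

    def test_too_few_free_frames_is_an_error(self):
        sched = _one_event_schedule(2, 10, 20)
        trace = dp.Trace(values=np.ones(20) * 5, frame_interval=1.0)
        with pytest.raises(ValueError, match="10 frames"):
            dp.fit_baseline(trace, sched, response_window_s=15.0)

    def test_rising_trace_falls_back_to_linear(self):
        t = np.arange(100, dtype=float)
        trace = dp.Trace(values=100.0 + 2.0 * t, frame_interval=1.0)
        model = dp.fit_baseline(trace, _empty_schedule(100))
        assert model.model_kind == "linear"
        assert model.predict(50.0) == pytest.approx(200.0, rel=1e-6)

    def test_baseline_strictly_positive_even_for_sign_crossing_input(self):
        t = np.arange(100, dtype=float)
        # linear trend would cross zero inside the trace; fluorescence stays positive
        trace = dp.Trace(values=np.maximum(50.0 - 2.0 * t, 1.0), frame_interval=1.0)
        model = dp.fit_baseline(trace, _empty_schedule(100))
        pred = model.predict(trace.times)
        assert np.all(pred > 0)  # the invariant the fallback chain guarantees


class TestDetectPeak:
    def test_triangular_bump_peak_frame(self):
        values = np.zeros(300)
        values[110:151] = np.concatenate([np.linspace(0, 1, 20),
                                          [1.05], np.linspace(1, 0, 20)])
        values += 100.0
        trace = dp.Trace(values=values, frame_interval=1.0)
        ev = dp.StimulusEvent("SE", None, 100, 140)
        model = dp.BaselineModel("constant", (100.0,))
        _, peak_frame = dp.detect_peak(trace, model, ev, response_window_s=80.0)
        assert abs(peak_frame - 130) <= 1

    def test_flat_trace_peak_equals_baseline(self):
        trace = dp.Trace(values=np.full(100, 42.0), frame_interval=1.0)
        ev = dp.StimulusEvent("SE", None, 30, 60)
        model = dp.BaselineModel("constant", (42.0,))
        peak_value, _ = dp.detect_peak(trace, model, ev, response_window_s=30.0)
        assert peak_value == pytest.approx(42.0)
        call = dp.call_response(trace, model, ev, response_window_s=30.0)
        assert call.delta_f_over_f == pytest.approx(0.0)
        assert not call.responder

    def test_larger_of_two_bumps_wins_and_matches_brute_force(self):
        values = np.full(200, 100.0)
        k = transient_kernel(np.arange(200, dtype=float) - 60, 1.0, 8.0)
        values += 30.0 * k  # 0.3 amplitude bump
        k2 = transient_kernel(np.arange(200, dtype=float) - 110, 1.0, 8.0)
        values += 60.0 * k2  # 0.6 amplitude bump
        trace = dp.Trace(values=values, frame_interval=1.0)
        ev = dp.StimulusEvent("SE", None, 55, 150)
        model = dp.BaselineModel("constant", (100.0,))
        peak_value, peak_frame = dp.detect_peak(trace, model, ev, response_window_s=100.0)
        # brute-force scan of the smoothed trace over the window
        smoothed = uniform_filter1d(values, size=3, mode="nearest")
        window = smoothed[55:155]
        assert peak_value == pytest.approx(window.max())
        assert peak_frame == 55 + int(np.argmax(window))
        assert 105 <= peak_frame <= 118

    def test_window_shorter_than_3_frames_is_an_error(self):
        trace = dp.Trace(values=np.zeros(50) + 10, frame_interval=1.0)
        ev = dp.StimulusEvent("SE", None, 10, 20)
        with pytest.raises(ValueError, match="3 frames"):
            dp.detect_peak(trace, dp.BaselineModel("constant", (10.0,)), ev,
                           response_window_s=2.0)

    def test_window_beyond_trace_is_an_error(self):
        trace = dp.Trace(values=np.zeros(50) + 10, frame_interval=1.0)
        ev = dp.StimulusEvent("SE", None, 40, 45)
        with pytest.raises(ValueError, match="beyond"):
            dp.detect_peak(trace, dp.BaselineModel("constant", (10.0,)), ev,
                           response_window_s=20.0)


class TestCallResponse:
    def test_simple_arithmetic(self):
        values = np.full(100, 100.0)
        values[48:53] = 140.0  # plateau so smoothing keeps the peak value
        trace = dp.Trace(values=values, frame_interval=1.0)
        ev = dp.StimulusEvent("SE", None, 45, 60)
        call = dp.call_response(trace, dp.BaselineModel("constant", (100.0,)), ev,
                                response_window_s=20.0)
        assert call.delta_f_over_f == pytest.approx(0.40)
        assert call.responder

    def test_threshold_is_inclusive_at_030(self):
        values = np.full(100, 100.0)
        values[48:53] = 130.0
        trace = dp.Trace(values=values, frame_interval=1.0)
        ev = dp.StimulusEvent("SE", None, 45, 60)
        call = dp.call_response(trace, dp.BaselineModel("constant", (100.0,)), ev,
                                response_window_s=20.0)
        assert call.delta_f_over_f == pytest.approx(0.30)
        assert call.responder  # >= is inclusive

    def test_non_positive_baseline_is_an_error(self):
        trace = dp.Trace(values=np.full(100, 10.0), frame_interval=1.0)
        ev = dp.StimulusEvent("SE", None, 45, 60)
        with pytest.raises(ValueError, match="non-positive"):
            dp.call_response(trace, dp.BaselineModel("constant", (0.0,)), ev,
                             response_window_s=20.0)

    def test_subthreshold_amplitude_rarely_called(self):
        # a=0.25 under realistic trace noise: responder in < 5% of 100 seeds
        n, fi, onset = 200, 0.5, 50.0
        sched = _one_event_schedule(100, 140, n, fi)
        false_calls = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trace = _synthetic_cell_trace(0.25, onset, n, fi, noise=2.0, rng=rng)
            model = dp.fit_baseline(trace, sched, response_window_s=30.0)
            call = dp.call_response(trace, model, sched.events[0],
                                    response_window_s=30.0)
            if call.responder:
                false_calls += 1
        assert false_calls <= 5

    def test_estimates_unbiased_at_amplitude_05(self):
        # 200 noisy forward-model traces at a=0.5: mean estimate within 5%
        n, fi, onset = 240, 0.5, 60.0
        sched = _one_event_schedule(120, 180, n, fi)
        rng = np.random.default_rng(42)
        dffs = []
        for _ in range(200):
            trace = _synthetic_cell_trace(0.5, onset, n, fi, noise=2.0, rng=rng)
            model = dp.fit_baseline(trace, sched, response_window_s=40.0)
            call = dp.call_response(trace, model, sched.events[0],
                                    response_window_s=40.0)
            dffs.append(call.delta_f_over_f)
        assert np.mean(dffs) == pytest.approx(0.5, rel=0.05)


class TestProperties:
    @given(scale=st.floats(min_value=1e-2, max_value=1e2,
                           allow_nan=False, allow_infinity=False))
    @settings(max_examples=25, deadline=None)
    def test_dff_scale_invariance(self, scale):
        n, fi = 200, 0.5
        sched = _one_event_schedule(100, 140, n, fi)
        trace = _synthetic_cell_trace(0.6, 50.0, n, fi)
        scaled = dp.Trace(values=trace.values * scale, frame_interval=fi)
        def dff(tr):
            model = dp.fit_baseline(tr, sched, response_window_s=30.0)
            return dp.call_response(tr, model, sched.events[0],
                                    response_window_s=30.0).delta_f_over_f
        assert dff(scaled) == pytest.approx(dff(trace), rel=1e-6)

    def test_monotonicity_on_noiseless_traces(self):
        n, fi = 200, 0.5
        sched = _one_event_schedule(100, 140, n, fi)
        estimates = []
        for a in [0.1, 0.2, 0.4, 0.6, 0.8, 1.0]:
            trace = _synthetic_cell_trace(a, 50.0, n, fi)
            model = dp.fit_baseline(trace, sched, response_window_s=30.0)
            estimates.append(dp.call_response(trace, model, sched.events[0],
                                              response_window_s=30.0).delta_f_over_f)
        assert np.all(np.diff(estimates) > 0)


class TestResponseWindowMask:
    def test_mask_covers_only_response_windows(self):
        sched = _one_event_schedule(10, 20, 60)
        mask = response_window_mask(sched, 60, 1.0, response_window_s=15.0)
        assert mask[10] and mask[24]
        assert not mask[9] and not mask[25]
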