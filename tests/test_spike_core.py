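"""Spike-shape pipeline: normalization, detrending, gradient, bounds, calls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caspike import (
    DetectionParams,
    SimulationConfig,
    SpikeSpec,
    compute_gradient,
    detect_spikes,
    detrend,
    locate_peak,
    locate_pulse_bounds,
    measure_spike,
    normalize_dff,
    simulate_trace,
)
from caspike.spike_core import BaselineError, GradientSeries, robust_scale

from conftest import make_trace


class TestNormalizeDff:
    def test_constant_trace_is_zero(self):
        norm = normalize_dff(make_trace(np.full(30, 100.0)), n_baseline=20)
        np.testing.assert_allclose(norm.values, 0.0, atol=1e-12)
        assert norm.f0 == 100.0

    def test_half_rise_over_baseline(self):
        values = np.full(30, 10.0)
        values[25] = 15.0
        norm = normalize_dff(make_trace(values), n_baseline=20)
        assert norm.values[25] == pytest.approx(0.5)

    @given(scale=st.floats(min_value=1e-3, max_value=1e4))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(0)
        base = 100.0 + rng.normal(0, 5, size=40) ** 2
        a = normalize_dff(make_trace(base), n_baseline=20)
        b = normalize_dff(make_trace(base * scale), n_baseline=20)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9, atol=1e-12)

    def test_baseline_mean_is_zero(self, rng):
        values = 50.0 + rng.random(60) * 10
        norm = normalize_dff(make_trace(values), n_baseline=20)
        assert abs(np.mean(norm.values[:20])) < 1e-9

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="baseline window"):
            normalize_dff(make_trace(np.ones(20)), n_baseline=20)

    def test_zero_baseline_rejected(self):
        values = np.concatenate([np.zeros(20), np.full(10, 5.0)])
        with pytest.raises(BaselineError):
            normalize_dff(make_trace(values), n_baseline=20)


def _normal_equations_polyfit(times, values, order):
    """Independent OLS solve via explicit normal equations (test oracle)."""
    # scale time for conditioning; the fitted values are scale-invariant
    t = (times - times.mean()) / (np.ptp(times) / 2)
    X = np.vander(t, order + 1, increasing=True)
    beta = np.linalg.solve(X.T @ X, X.T @ values)
    return X @ beta


class TestDetrend:
    @given(
        coeffs=st.lists(st.floats(min_value=-2, max_value=2), min_size=1, max_size=4),
    )
    def test_polynomial_annihilation(self, coeffs):
        times = np.arange(50) * 2.0
        values = np.polynomial.polynomial.polyval(times / 100.0, np.array(coeffs))
        det = detrend(values, poly_order=3, times=times)
        scale = max(np.max(np.abs(values)), 1.0)
        assert np.max(np.abs(det.values)) < 1e-9 * scale

    def test_constant_input_order_zero(self):
        times = np.arange(10) * 2.0
        det = detrend(np.full(10, 3.3), poly_order=0, times=times)
        np.testing.assert_allclose(det.values, 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle_on_poly_plus_tent(self):
        times = np.arange(200) * 2.0
        tent = np.clip(1 - np.abs(times - 200.0) / 30.0, 0, None)
        values = 0.5 + 1e-3 * times - 2e-6 * times**2 + tent
        det = detrend(values, poly_order=3, times=times)
        expected = values - _normal_equations_polyfit(times, values, 3)
        np.testing.assert_allclose(det.values, expected, atol=1e-9)

    def test_coefficients_reproduce_source(self, rng):
        times = np.arange(120) * 2.0
        values = rng.normal(0, 1, size=120)
        det = detrend(values, poly_order=3, times=times)
        np.testing.assert_allclose(det.values + det.fitted(), values, atol=1e-9)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            detrend(np.ones(3), poly_order=3, times=np.arange(3.0))


class TestComputeGradient:
    def test_linear_ramp_constant_slope(self):
        values = 0.1 * np.arange(20) * 2.0
        grad = compute_gradient(values, frame_interval=2.0)
        np.testing.assert_allclose(grad.values, 0.1, atol=1e-12)

    def test_constant_series_zero(self):
        grad = compute_gradient(np.full(10, 5.0), frame_interval=2.0)
        np.testing.assert_allclose(grad.values, 0.0, atol=1e-12)

    def test_hand_computed_central_and_one_sided(self):
        grad = compute_gradient(np.array([0.0, 1.0, 0.0]), frame_interval=2.0)
        np.testing.assert_allclose(grad.values, [0.5, 0.0, -0.5])

    def test_forward_scheme(self):
        grad = compute_gradient(np.array([0.0, 2.0, 2.0]), frame_interval=2.0, scheme="forward")
        np.testing.assert_allclose(grad.values, [1.0, 0.0, 0.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            compute_gradient(np.array([1.0]), frame_interval=2.0)


class TestLocatePeak:
    @pytest.mark.parametrize(
        "values, expected",
        [([0, 0.2, 1.0, 0.4], 2), ([0, 1.0, 1.0, 0], 1)],
    )
    def test_examples_and_earliest_tie(self, values, expected):
        assert locate_peak(np.array(values, dtype=float)) == expected

    def test_agrees_with_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            values = rng.normal(size=rng.integers(2, 60))
            best, best_idx = -np.inf, -1
            for i, v in enumerate(values):  # brute-force scan oracle
                if v > best:
                    best, best_idx = v, i
            assert locate_peak(values) == best_idx

    def test_window_restricts_search(self):
        values = np.array([5.0, 0.0, 1.0, 3.0, 0.0])
        assert locate_peak(values, window=(1, 4)) == 3

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            locate_peak(np.arange(4.0), window=(2, 2))


def scan_bounds_oracle(det, grad, peak, theta_s, theta_g, times):
    """Independent index-by-index boundary scan (test oracle)."""
    ok = lambda i: det[i] <= theta_s and abs(grad[i]) <= theta_g
    if ok(peak):
        return peak, peak, False, False
    on, c_on = 0, True
    i = peak - 1
    while i >= 0:
        if ok(i):
            on, c_on = i, False
            break
        i -= 1
    off, c_off = len(det) - 1, True
    i = peak + 1
    while i < len(det):
        if ok(i):
            off, c_off = i, False
            break
        i += 1
    return on, off, c_on, c_off


def _as_detrended(values, frame_interval=1.0):
    from caspike.spike_core import DetrendedTrace

    values = np.asarray(values, dtype=float)
    return DetrendedTrace(
        values=values,
        times=np.arange(values.size) * frame_interval,
        poly_order=0,
        poly_coeffs=np.zeros(1),
        source="dff",
        frame_interval=frame_interval,
    )


class TestLocatePulseBounds:
    def test_hand_scanned_example(self):
        det = _as_detrended([0, 0, 0.1, 0.5, 1.0, 0.6, 0.2, 0.05, 0])
        grad = compute_gradient(det)
        bounds = locate_pulse_bounds(det, grad, peak=4, theta_s=0.15, theta_g=0.15)
        on, off, c_on, c_off = scan_bounds_oracle(
            det.values, grad.values, 4, 0.15, 0.15, det.times
        )
        assert (bounds.onset_index, bounds.offset_index) == (on, off) == (1, 7)
        assert not bounds.censored_onset and not bounds.censored_offset

    def test_rising_limb_at_first_frame_censors_onset(self):
        det = _as_detrended([0.5, 0.8, 1.0, 0.4, 0.0, 0.0])
        grad = compute_gradient(det)
        bounds = locate_pulse_bounds(det, grad, peak=2, theta_s=0.15, theta_g=0.15)
        assert bounds.censored_onset and bounds.t_on == det.times[0]
        assert not bounds.censored_offset

    def test_all_zero_series_degenerates_to_zero_width(self):
        det = _as_detrended(np.zeros(9))
        grad = compute_gradient(det)
        bounds = locate_pulse_bounds(det, grad, peak=4, theta_s=0.0, theta_g=0.0)
        assert bounds.t_on == bounds.t_off == det.times[4]

    def test_matches_oracle_on_seeded_noisy_spikes(self):
        rng = np.random.default_rng(321)
        for _ in range(60):
            n = 120
            times = np.arange(n) * 2.0
            centre = rng.uniform(60, 180)
            tent = np.clip(1 - np.abs(times - centre) / rng.uniform(10, 40), 0, None)
            values = tent + rng.normal(0, 0.08, size=n)
            det = _as_detrended(values, frame_interval=2.0)
            grad = compute_gradient(det)
            peak = locate_peak(det)
            theta_s = robust_scale(det.values)
            theta_g = 1.5 * robust_scale(grad.values)
            bounds = locate_pulse_bounds(det, grad, peak, theta_s=theta_s, theta_g=theta_g)
            on, off, c_on, c_off = scan_bounds_oracle(
                det.values, grad.values, peak, theta_s, theta_g, det.times
            )
            assert (bounds.onset_index, bounds.offset_index) == (on, off)
            assert (bounds.censored_onset, bounds.censored_offset) == (c_on, c_off)


class TestMeasureSpike:
    def test_simple_arithmetic(self):
        call = measure_spike(2.0, 4.0, 7.0, amplitude_dff=1.0)
        assert (call.rise_s, call.fall_s, call.duration_s) == (2.0, 3.0, 5.0)

    def test_reported_wildtype_signature_sums(self):
        call = measure_spike(0.0, 15.4, 39.5, amplitude_dff=1.0)
        assert call.rise_s == pytest.approx(15.4)
        assert call.fall_s == pytest.approx(24.1)
        assert call.duration_s == pytest.approx(39.5)

    def test_degenerate_zero_width(self):
        call = measure_spike(5.0, 5.0, 5.0, amplitude_dff=0.0)
        assert call.rise_s == call.fall_s == call.duration_s == 0.0

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError, match="t_on <= t_peak"):
            measure_spike(5.0, 4.0, 7.0, amplitude_dff=1.0)

    @given(
        t_on=st.floats(0, 100),
        rise=st.floats(0, 50),
        fall=st.floats(0, 50),
    )
    def test_duration_identity_exact(self, t_on, rise, fall):
        call = measure_spike(t_on, t_on + rise, t_on + rise + fall, amplitude_dff=1.0)
        assert call.duration_s == call.rise_s + call.fall_s
        assert call.t_on <= call.t_peak <= call.t_off


class TestDetectSpikes:
    def test_pure_noise_trace_yields_no_calls(self):
        cfg = SimulationConfig(seed=1111)
        trace, truth = simulate_trace(cfg, [])
        assert truth == []
        assert len(detect_spikes(trace)) == 0

    def test_noiseless_tent_recovered_within_one_frame(self):
        cfg = SimulationConfig(seed=2, noise_sigma=0.0)
        trace, truth = simulate_trace(cfg, [SpikeSpec(1000.0, 15.0, 24.0, 0.5)])
        calls = [r.call for r in detect_spikes(trace)]
        assert len(calls) == 1
        gt = truth[0]
        assert abs(calls[0].t_on - gt.true_t_on) <= trace.frame_interval
        assert abs(calls[0].t_peak - gt.true_t_peak) <= trace.frame_interval
        assert abs(calls[0].t_off - gt.true_t_off) <= trace.frame_interval

    def test_two_separated_spikes_in_onset_order(self):
        cfg = SimulationConfig(seed=3)
        trace, truth = simulate_trace(
            cfg, [SpikeSpec(3000.0, 12.0, 20.0, 0.5), SpikeSpec(800.0, 15.0, 25.0, 0.5)]
        )
        calls = [r.call for r in detect_spikes(trace) if not r.call.censored]
        assert len(calls) == 2
        assert calls[0].t_on < calls[1].t_on
        assert abs(calls[0].t_on - 800.0) < 3 * trace.frame_interval
        assert abs(calls[1].t_on - 3000.0) < 3 * trace.frame_interval

    def test_raising_amp_mult_never_adds_calls(self):
        cfg = SimulationConfig(seed=4)
        trace, _ = simulate_trace(cfg, [SpikeSpec(1500.0, 15.0, 24.0, 0.5)])
        counts = []
        for amp in (3.0, 4.0, 5.0, 7.0, 10.0):
            counts.append(len(detect_spikes(trace, DetectionParams(amp_mult=amp))))
        assert counts == sorted(counts, reverse=True)

    def test_raw_detrend_target_matches_dff_detection(self):
        cfg = SimulationConfig(seed=5)
        trace, _ = simulate_trace(cfg, [SpikeSpec(1200.0, 14.0, 22.0, 0.5)])
        a = [r.call for r in detect_spikes(trace, DetectionParams(detrend_target="dff"))]
        b = [r.call for r in detect_spikes(trace, DetectionParams(detrend_target="raw"))]
        assert len(a) == len(b) == 1
        # identical up to the affine-equivalence of the two detrend orders
        assert a[0].t_on == pytest.approx(b[0].t_on, abs=1e-6)
        assert a[0].t_off == pytest.approx(b[0].t_off, abs=1e-6)

    def test_constant_trace_yields_no_calls(self):
        cfg = SimulationConfig(seed=6, noise_sigma=0.0, drift_coeffs=())
        trace, _ = simulate_trace(cfg, [])
        assert len(detect_spikes(trace)) == 0
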