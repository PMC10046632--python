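"""Unit and property tests for the cycle-averaging analysis pipeline."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rdcsense.analyze import (
    AnalysisWindow,
    CycleSet,
    MeasurementSummary,
    analyze_trace,
    average_cycles,
    baseline_correct,
    cycle_convergence,
    difference_trace,
    extract_window,
    noise_level,
    propagate_difference_noise,
    segment_cycles,
    signal_intensity,
    snr_summary,
    theoretical_noise,
)
from rdcsense.simulate import SensorTrace

from conftest import make_trace


def brute_force_line_rms(t, y):
    """Independent least-squares oracle via the normal equations."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = t.size
    sx, sy, sxx, sxy = t.sum(), y.sum(), (t * t).sum(), (t * y).sum()
    det = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / det
    intercept = (sy * sxx - sx * sxy) / det
    resid = y - slope * t - intercept
    return math.sqrt(float(np.mean(resid**2)))


class TestExtractWindow:
    def test_default_window_yields_6000_samples(self, periodic_trace):
        w = extract_window(periodic_trace, AnalysisWindow(55.0, 115.0))
        assert len(w) == 6000
        assert w.time[0] == 0.0

    def test_full_window_is_identity_on_samples(self, periodic_trace):
        w = extract_window(periodic_trace, AnalysisWindow(0.0, 120.0))
        np.testing.assert_array_equal(w.output, periodic_trace.output[:12000])

    def test_window_not_multiple_of_cycle_rejected(self, periodic_trace):
        with pytest.raises(ValueError, match="integer multiple"):
            extract_window(periodic_trace, AnalysisWindow(55.0, 116.0), cycle_duration_s=10.0)

    def test_window_outside_trace_rejected(self, periodic_trace):
        with pytest.raises(ValueError, match="outside"):
            extract_window(periodic_trace, AnalysisWindow(55.0, 125.0))

    def test_off_grid_boundary_rejected(self, periodic_trace):
        with pytest.raises(ValueError, match="grid"):
            extract_window(periodic_trace, AnalysisWindow(55.0015, 115.0015))


class TestSegmentation:
    def test_six_by_thousand_matrix(self, periodic_trace):
        w = extract_window(periodic_trace, AnalysisWindow(55.0, 115.0))
        cs = segment_cycles(w, 10.0, expected_n=6)
        assert cs.cycles.shape == (6, 1000)

    def test_single_cycle(self):
        trace = make_trace(np.arange(1000.0))
        cs = segment_cycles(trace, 10.0)
        assert cs.cycles.shape == (1, 1000)

    def test_periodic_input_gives_identical_rows(self, periodic_trace):
        w = extract_window(periodic_trace, AnalysisWindow(50.0, 110.0))
        cs = segment_cycles(w, 10.0)
        for row in cs.cycles[1:]:
            np.testing.assert_array_equal(row, cs.cycles[0])

    def test_reconstruction_is_bit_exact(self, periodic_trace):
        w = extract_window(periodic_trace, AnalysisWindow(55.0, 115.0))
        cs = segment_cycles(w, 10.0)
        np.testing.assert_array_equal(cs.cycles.reshape(-1), w.output)

    def test_non_dividing_window_rejected(self):
        trace = make_trace(np.arange(1100.0))
        with pytest.raises(ValueError, match="does not divide"):
            segment_cycles(trace, 10.0)


class TestBaselineCorrection:
    def test_offset_removal(self):
        cs = CycleSet(np.array([[3.0, 4.0, 5.0]]), 0.03, 100.0)
        out = baseline_correct(cs)
        np.testing.assert_array_equal(out.cycles, [[0.0, 1.0, 2.0]])
        assert out.baseline_corrected

    def test_idempotence_on_anchored_cycle(self):
        cs = CycleSet(np.array([[0.0, 1.0, 2.0], [0.0, -1.0, 4.0]]), 0.03, 100.0)
        out = baseline_correct(cs)
        np.testing.assert_array_equal(out.cycles, cs.cycles)

    def test_linear_drift_leaves_slope_not_offset(self):
        # pure ramp b*t: corrected cycles are all identical ramps b*t_local
        b, fs = 0.2, 100.0
        t = np.arange(3000) / fs
        cs = segment_cycles(make_trace(b * t), 10.0)
        out = baseline_correct(cs)
        local = b * np.arange(1000) / fs
        for row in out.cycles:
            np.testing.assert_allclose(row, local, atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        arrays(
            np.float64,
            (3, 50),
            elements=st.floats(-1e6, 1e6, allow_nan=False, width=64),
        )
    )
    def test_idempotence_property(self, mat):
        cs = CycleSet(mat, 0.5, 100.0)
        once = baseline_correct(cs)
        twice = baseline_correct(once)
        np.testing.assert_array_equal(once.cycles, twice.cycles)
        assert np.all(once.cycles[:, 0] == 0.0)


class TestAveraging:
    def test_mean_of_identical_cycles_is_that_cycle(self):
        row = np.array([0.0, 2.0, 1.0])
        cs = CycleSet(np.tile(row, (6, 1)), 0.03, 100.0)
        np.testing.assert_array_equal(average_cycles(cs), row)

    def test_two_cycle_mean(self):
        cs = CycleSet(np.array([[0.0, 2.0], [0.0, 4.0]]), 0.02, 100.0)
        np.testing.assert_array_equal(average_cycles(cs), [0.0, 3.0])

    def test_noise_reduction_by_sqrt_six(self):
        rng = np.random.default_rng(123)
        clean = np.sin(np.linspace(0, 2 * np.pi, 1000))
        fs = 100.0
        levels = []
        for _ in range(50):
            noisy = np.tile(clean, (6, 1)) + rng.normal(0, 1.0, (6, 1000))
            avg = average_cycles(CycleSet(noisy, 10.0, fs))
            levels.append(noise_level(avg, fs))
        assert 0.35 <= np.mean(levels) <= 0.47  # ~ 1/sqrt(6) = 0.408

    @settings(deadline=None, derandomize=True)
    @given(
        arrays(np.float64, (4, 20), elements=st.floats(-1e3, 1e3, width=64)),
        arrays(np.float64, (4, 20), elements=st.floats(-1e3, 1e3, width=64)),
        st.floats(-10, 10, allow_nan=False),
    )
    def test_averaging_is_linear(self, a, b, alpha):
        cs_a = CycleSet(a, 0.2, 100.0)
        cs_b = CycleSet(b, 0.2, 100.0)
        combined = CycleSet(alpha * a + b, 0.2, 100.0)
        np.testing.assert_allclose(
            average_cycles(combined),
            alpha * average_cycles(cs_a) + average_cycles(cs_b),
            rtol=1e-9,
            atol=1e-9,
        )


class TestNoiseLevel:
    def test_exact_line_has_zero_noise(self):
        t = np.arange(1000) / 100.0
        cycle = 2.0 + 0.5 * t
        assert noise_level(cycle, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_three_point_worked_example(self):
        # residuals of [0, 1, 0] about its OLS line: RMS = sqrt(2/9)
        y = np.array([0.0, 1.0, 0.0])
        got = noise_level(y, 100.0, fit_window_s=(0.0, 0.03))
        assert got == pytest.approx(math.sqrt(2.0 / 9.0), rel=1e-12)
        t = np.arange(3) / 100.0
        assert got == pytest.approx(brute_force_line_rms(t, y), rel=1e-12)

    def test_gaussian_noise_rms_expectation(self):
        # E[RMS] ~ sigma * sqrt((n-2)/n) for an OLS line fit
        rng = np.random.default_rng(7)
        sigma, n, fs = 1.5, 100, 100.0
        estimates = [
            noise_level(rng.normal(0, sigma, n), fs, fit_window_s=(0.0, 1.0))
            for _ in range(400)
        ]
        assert np.mean(estimates) == pytest.approx(sigma * math.sqrt((n - 2) / n), rel=0.03)

    def test_offset_and_ramp_invariance(self):
        rng = np.random.default_rng(5)
        cycle = rng.normal(0, 1, 1000)
        base = noise_level(cycle, 100.0)
        t = np.arange(1000) / 100.0
        shifted = noise_level(cycle + 17.0 + 3.0 * t, 100.0)
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_unbiased_divisor_option(self):
        y = np.array([0.0, 1.0, 0.0])
        got = noise_level(y, 100.0, fit_window_s=(0.0, 0.03), residual_dof=2)
        assert got == pytest.approx(math.sqrt(6.0 / 9.0), rel=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            noise_level(np.array([1.0, 2.0]), 100.0, fit_window_s=(0.0, 0.02))


class TestSignalIntensity:
    def test_intensity_is_the_five_second_sample_when_corrected(self):
        cycle = np.zeros(1000)
        cycle[500] = 10.6
        assert signal_intensity(cycle, 100.0) == pytest.approx(10.6)

    def test_flat_zero_cycle(self):
        assert signal_intensity(np.zeros(1000), 100.0) == 0.0

    def test_off_grid_peak_time_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            signal_intensity(np.zeros(1000), 100.0, peak_time_s=5.0015)

    @settings(deadline=None, derandomize=True)
    @given(
        arrays(np.float64, 1000, elements=st.floats(-1e3, 1e3, width=64)),
        st.floats(-100, 100, allow_nan=False),
    )
    def test_invariant_to_constant_offset_before_correction(self, raw, offset):
        cs = CycleSet(raw.reshape(1, -1), 10.0, 100.0)
        cs_off = CycleSet(raw.reshape(1, -1) + offset, 10.0, 100.0)
        a = signal_intensity(average_cycles(baseline_correct(cs)), 100.0)
        b = signal_intensity(average_cycles(baseline_correct(cs_off)), 100.0)
        assert a == pytest.approx(b, abs=1e-9)


class TestNoiseScalingLaws:
    def test_theoretical_noise_closed_forms(self):
        assert theoretical_noise(1.0, 1) == 1.0
        assert theoretical_noise(1.2, 4) == pytest.approx(0.6)
        assert theoretical_noise(2.0, 6) == pytest.approx(2.0 / math.sqrt(6))
        with pytest.raises(ValueError):
            theoretical_noise(1.0, 0)

    def test_difference_noise_closed_forms(self):
        assert propagate_difference_noise(3.0, 4.0) == pytest.approx(5.0)
        assert propagate_difference_noise(1.7, 0.0) == pytest.approx(1.7)


class TestDifferenceTrace:
    def test_trace_minus_itself_is_zero(self, periodic_trace):
        d = difference_trace(periodic_trace, periodic_trace)
        assert np.all(d.output == 0.0)

    def test_subtracting_zero_is_identity(self, periodic_trace):
        zero = SensorTrace(periodic_trace.time, np.zeros(len(periodic_trace)))
        d = difference_trace(periodic_trace, zero)
        np.testing.assert_array_equal(d.output, periodic_trace.output)

    def test_grid_mismatch_rejected(self, periodic_trace):
        other = make_trace(np.zeros(500), fs=50.0)
        with pytest.raises(ValueError, match="grids"):
            difference_trace(periodic_trace, other)

    def test_difference_noise_approaches_sqrt_two(self):
        rng = np.random.default_rng(11)
        fs = 100.0
        ratios = []
        for _ in range(100):
            a = rng.normal(0, 1.0, 1000)
            b = rng.normal(0, 1.0, 1000)
            ratios.append(noise_level(a - b, fs) / noise_level(a, fs))
        assert 1.30 <= np.mean(ratios) <= 1.53


class TestSummaries:
    def test_constant_snr_replicates(self):
        s = [
            MeasurementSummary("c", "rdc", 10.0, 2.0, 2.0, 2.0, 5.0)
            for _ in range(3)
        ]
        stats = snr_summary(s)
        assert stats.loc["snr", "mean"] == pytest.approx(5.0)
        assert stats.loc["snr", "std"] == pytest.approx(0.0)

    def test_two_point_sample_std(self):
        s = [
            MeasurementSummary("c", "rdc", 8.0, 2.0, 2.0, 2.0, 4.0),
            MeasurementSummary("c", "rdc", 12.0, 2.0, 2.0, 2.0, 6.0),
        ]
        stats = snr_summary(s)
        assert stats.loc["snr", "mean"] == pytest.approx(5.0)
        assert stats.loc["snr", "std"] == pytest.approx(math.sqrt(2.0))

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="two replicate"):
            snr_summary([MeasurementSummary("c", "rdc", 1.0, 1.0, 1.0, 1.0, 1.0)])

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            MeasurementSummary("c", "rdc", 1.0, -1.0, 1.0, 1.0, 1.0)


class TestAnalyzeTrace:
    def test_zero_noise_floor_flagged(self):
        t = np.arange(12001) / 100.0
        flat = SensorTrace(t, np.zeros(12001), channel="flat")
        with pytest.warns(UserWarning, match="zero noise floor"):
            summary = analyze_trace(flat, measurement_type="rdc")
        assert summary.noise_avg_uv == 0.0
        assert math.isnan(summary.snr)

    def test_pipeline_reconstruction_invariants(self, periodic_trace):
        # exactly periodic sawtooth: the window starts mid-period, so the
        # anchored cycle goes 5 -> 9.99 then wraps to 0 -> 4.99; after
        # baseline correction the 5 s sample reads 0 - 5 = -5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = analyze_trace(periodic_trace, measurement_type="rdc")
        assert summary.signal_intensity_uv == pytest.approx(-5.0)
        assert summary.noise_raw_uv == pytest.approx(0.0, abs=1e-9)


class TestCycleConvergence:
    def test_periodic_trace_converges_immediately(self, periodic_trace):
        res = cycle_convergence(periodic_trace)
        assert res.converged_at == 1

    def test_exponential_settling_time(self):
        # single decaying exponential: deltas shrink by exp(-10/tau) per cycle
        tau = 30.0
        t = np.arange(12001) / 100.0
        trace = SensorTrace(t, 100.0 * (1 - np.exp(-t / tau)))
        res = cycle_convergence(trace, 10.0)
        ratios = res.deltas[1:] / res.deltas[:-1]
        np.testing.assert_allclose(ratios, math.exp(-10.0 / tau), rtol=1e-6)
        assert res.converged_at == math.ceil(3 * tau / 10.0)

    def test_non_convergence_warns(self):
        t = np.arange(3001) / 100.0
        trace = SensorTrace(t, t**2)  # accelerating drift never settles
        with pytest.warns(UserWarning, match="steady state"):
            res = cycle_convergence(trace, 10.0)
        assert res.converged_at is None
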