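"""Peak-detection counter: thresholding, counting, rates, alpha calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chewmeter import (
    ChewSegment,
    SensorSignal,
    calibrate_alpha,
    chewing_rate,
    count_chews,
    count_visit_semi_automatic,
    default_alpha_grid,
    generate_alpha_probe_visit,
    generate_bout,
    percentile_threshold,
    preprocess,
)

FS = 1000.0


def _conditioned_bout(n_chews, freq, amp_jitter=0.0, seed=0, noise_sd=0.0):
    bout, _ = generate_bout(n_chews, freq, FS, amp_jitter=amp_jitter, seed=seed)
    if noise_sd > 0:
        bout = bout + np.random.default_rng(seed).normal(0, noise_sd, len(bout))
    return preprocess(SensorSignal(bout, FS)).samples


class TestPercentileThreshold:
    def test_constant_sequence(self):
        assert percentile_threshold(np.full(40, 3.7), 0.9) == pytest.approx(3.7)

    def test_matches_brute_force_interpolation(self):
        # brute-force oracle: sort, locate rank alpha*(n-1), linear interpolation
        rng = np.random.default_rng(5)
        for alpha in (0.80, 0.9, 0.95, 0.97):
            x = rng.normal(size=257)
            s = np.sort(x)
            pos = alpha * (len(x) - 1)
            lo, frac = int(np.floor(pos)), pos - np.floor(pos)
            expected = s[lo] + frac * (s[min(lo + 1, len(x) - 1)] - s[lo])
            assert percentile_threshold(x, alpha) == pytest.approx(expected, abs=1e-12)

    def test_linear_ramp_value(self):
        assert percentile_threshold(np.arange(100.0), 0.90) == pytest.approx(89.1)

    def test_two_value_sequence(self):
        x = np.array([0.0] * 90 + [1.0] * 10)
        t = percentile_threshold(x, 0.95)
        assert 0.0 < t <= 1.0

    def test_upper_tail_fraction(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        for alpha in (0.8, 0.9):
            t = percentile_threshold(x, alpha)
            assert np.mean(x >= t) >= (1 - alpha) - 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            percentile_threshold(np.empty(0), 0.9)
        with pytest.raises(ValueError):
            percentile_threshold(np.ones(5), 1.5)


class TestCountChews:
    def test_sinusoid_cycle_count(self, sine_signal):
        result = count_chews(sine_signal.samples, FS, alpha=0.9)
        assert result.n_peaks == 15
        assert result.rate == pytest.approx(1.5)

    def test_zero_segment_counts_nothing(self):
        assert count_chews(np.zeros(5000), FS, 0.9).n_peaks == 0

    def test_noisy_jittered_bout_recovered(self):
        y = _conditioned_bout(20, 1.2, seed=11, noise_sd=0.05)
        assert count_chews(y, FS, 0.9).n_peaks == 20

    @pytest.mark.parametrize("n_chews", [5, 10, 20, 30])
    @pytest.mark.parametrize("freq", [0.94, 1.2, 1.5, 2.0])
    def test_noise_free_counts_exact(self, n_chews, freq):
        y = _conditioned_bout(n_chews, freq)
        assert count_chews(y, FS, 0.9).n_peaks == n_chews

    def test_peak_times_respect_min_separation(self):
        y = _conditioned_bout(25, 2.0, amp_jitter=0.2, seed=3, noise_sd=0.1)
        result = count_chews(y, FS, 0.85, min_separation_s=0.3)
        assert np.all(np.diff(result.peak_times) >= 0.3 - 1e-9)
        assert result.n_peaks == len(result.peak_times)

    def test_rate_times_duration_is_count(self):
        y = _conditioned_bout(17, 1.3, amp_jitter=0.1, seed=9)
        result = count_chews(y, FS, 0.85)
        duration = len(y) / FS
        assert result.rate * duration == pytest.approx(result.n_peaks, abs=1e-9)

    def test_empty_and_bad_args(self):
        with pytest.raises(ValueError):
            count_chews(np.empty(0), FS, 0.9)
        with pytest.raises(ValueError):
            count_chews(np.ones(10), FS, 0.9, min_separation_s=0.0)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(gain=st.floats(min_value=0.1, max_value=10.0))
def test_count_is_scale_invariant(gain):
    """Percentile thresholding makes the count independent of signal gain."""
    bout, _ = generate_bout(20, 1.2, FS, amp_jitter=0.2, seed=11)
    bout = bout + np.random.default_rng(2).normal(0, 0.05, len(bout))
    y = preprocess(SensorSignal(bout, FS)).samples
    base = count_chews(y, FS, 0.9)
    scaled = count_chews(gain * y, FS, 0.9)
    assert scaled.n_peaks == base.n_peaks
    # float rounding at the threshold can shift nearly-flat smoothed maxima
    # by tens of ms; the count and coarse peak positions are invariant
    np.testing.assert_allclose(scaled.peak_times, base.peak_times, atol=0.1)


class TestChewingRate:
    def test_direct_division(self):
        assert chewing_rate(10, 5.0) == pytest.approx(2.0)
        assert chewing_rate(0, 3.0) == 0.0
        assert chewing_rate(11, 7.5) == pytest.approx(1.4667, abs=1e-4)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            chewing_rate(5, 0.0)


class TestSemiAutomatic:
    def test_zero_intake_visit(self):
        sig = SensorSignal(np.zeros(10_000), FS)
        segs = [ChewSegment(0.0, 5.0, "non-intake", None)]
        summary = count_visit_semi_automatic(sig, segs)
        assert summary.ecnt == 0
        assert summary.ecr == 0.0

    def test_signed_error_arithmetic_single_visit(self):
        # ACNT=50, ECNT=45 -> signed error +10%
        from chewmeter import error_report

        report = error_report([50], [45])
        assert report.mean_signed == pytest.approx(10.0)

    def test_segment_outside_signal_rejected(self):
        sig = SensorSignal(np.zeros(1000), FS)  # 1 s
        with pytest.raises(ValueError, match="extent"):
            count_visit_semi_automatic(sig, [ChewSegment(0.5, 2.0, "intake", 3)])


class TestCalibrateAlpha:
    def test_single_alpha_grid_forced_choice(self, probe_cohort):
        result = calibrate_alpha(probe_cohort[:3], grid=[0.85], n_subset=3, seed=0)
        assert result.alpha == pytest.approx(0.85)

    def test_two_visit_exhaustive_enumeration(self):
        grid = default_alpha_grid()
        visits = [generate_alpha_probe_visit(n_periods=n) for n in (26, 31)]
        result = calibrate_alpha(visits, grid=grid, n_subset=2, seed=0)
        # oracle: with two visits each fold's optimum is the other visit's
        # argmin, computed here by direct per-alpha counting
        expected_folds = []
        for other in (1, 0):
            sig, segs = visits[other]
            acnt = sum(s.chew_count for s in segs)
            errors = [
                abs(acnt - count_visit_semi_automatic(sig, segs, alpha=float(a)).ecnt)
                / acnt
                for a in grid
            ]
            expected_folds.append(grid[int(np.argmin(errors))])
        assert result.alpha == pytest.approx(np.mean(expected_folds))

    def test_common_minimum_recovered(self, probe_cohort):
        result = calibrate_alpha(probe_cohort, n_subset=20, seed=0)
        assert result.alpha == pytest.approx(0.90, abs=0.01)

    def test_too_few_visits_rejected(self, probe_cohort):
        with pytest.raises(ValueError):
            calibrate_alpha(probe_cohort[:5], n_subset=20)
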