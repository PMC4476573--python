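"""Interference tests: beat oracle, sectioned measurement, power-law fit,
periodicity contrast, group statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import FS, make_tone, masked_tone_recording, two_tone_overlap
from vibroduet import (
    NoBeatError,
    OverlapRegion,
    PulseSpec,
    Trace,
    anova_oneway,
    beat_period_ms,
    compare_groups,
    envelope_periodicity,
    envelope_spectrum,
    estimate_noise_level,
    fit_power_law,
    measure_interference,
    mix,
    predict_beat_envelope,
    synthesize_pulse,
)


class TestBeatPeriod:
    @pytest.mark.parametrize("fa,fb,expected", [
        (100.0, 150.0, 20.0),
        (106.0, 112.0, 1000.0 / 6.0),
        (150.0, 100.0, 20.0),
    ])
    def test_known_periods(self, fa, fb, expected):
        assert beat_period_ms(fa, fb) == pytest.approx(expected)

    def test_equal_frequencies_signalled(self):
        """Overlapped tones of the same frequency induce no beat pattern."""
        with pytest.raises(NoBeatError):
            beat_period_ms(125.0, 125.0)


class TestPredictBeatEnvelope:
    def test_single_tone_is_constant(self):
        t = np.linspace(0, 1, 100)
        assert np.allclose(predict_beat_envelope(0.7, 100, 0.0, 150, t), 0.7)

    def test_equal_amplitudes_cancel_at_half_period(self):
        period_s = beat_period_ms(100, 150) / 1000.0
        env = predict_beat_envelope(1.0, 100, 1.0, 150,
                                    np.array([period_s / 2]))
        assert env[0] == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(min_value=0.1, max_value=2.0),
           st.floats(min_value=0.1, max_value=2.0))
    def test_bounds(self, a1, a2):
        t = np.linspace(0, 0.5, 257)
        env = predict_beat_envelope(a1, 100, a2, 130, t)
        assert np.all(env <= a1 + a2 + 1e-12)
        assert np.all(env >= abs(a1 - a2) - 1e-12)

    def test_matches_measured_envelope_of_mixed_tones(self):
        from vibroduet import envelope
        mixed = two_tone_overlap(100.0, 130.0, 3.0)
        env = envelope(mixed, smooth_ms=0.5)
        pred = predict_beat_envelope(1.0, 100.0, 1.0, 130.0, env.times())
        sl = slice(int(0.1 * FS), int(2.9 * FS))
        err = np.sqrt(np.mean((env.samples[sl] - pred[sl]) ** 2))
        assert err / np.sqrt(np.mean(pred[sl] ** 2)) < 0.02


class TestMeasureInterference:
    def test_sections_at_25hz_difference(self):
        """A 6-s masked region of equal tones 25 Hz apart yields 6 sections
        whose mean pulse duration tracks the 40-ms beat period."""
        trace, t0, t1 = masked_tone_recording(100.0, 125.0, 6.0, 0.05, seed=3)
        thr = estimate_noise_level(trace, (0.05, 0.95), k=3.0)
        region = OverlapRegion(t0, t1, 100.0, 125.0)
        sections = measure_interference(trace, region, thr)
        assert len(sections) == 6
        for s in sections:
            assert s.mean_duration == pytest.approx(40.0, rel=0.12)
            assert s.delta_f == 25.0

    def test_silent_region_empty(self):
        silent = Trace(np.zeros(int(4 * FS)), FS)
        region = OverlapRegion(0.5, 3.5, 100.0, 125.0)
        assert measure_interference(silent, region, 0.1) == []

    def test_section_counts_conserve_pulses(self):
        from vibroduet import segment_pulses
        trace, t0, t1 = masked_tone_recording(100.0, 150.0, 4.0, 0.05, seed=5)
        thr = estimate_noise_level(trace, (0.05, 0.95), k=3.0)
        region = OverlapRegion(t0, t1, 100.0, 150.0)
        sections = measure_interference(trace, region, thr)
        pulses = segment_pulses(trace.crop(t0, t1), thr, min_gap_ms=0.3,
                                min_duration_ms=5.0, smooth_ms=0.5)
        assert sum(s.n_pulses for s in sections) == len(pulses)

    def test_mean_duration_decreases_with_delta_f(self):
        means = []
        for i, df in enumerate([10.0, 25.0, 50.0]):
            trace, t0, t1 = masked_tone_recording(100.0, 100.0 + df, 4.0,
                                                  0.05, seed=10 + i)
            thr = estimate_noise_level(trace, (0.05, 0.95), k=3.0)
            secs = measure_interference(
                trace, OverlapRegion(t0, t1, 100.0, 100.0 + df), thr)
            means.append(np.mean([s.mean_duration for s in secs]))
        assert means[0] > means[1] > means[2]

    def test_invariance_to_masker_placement(self):
        """At fixed Δf = 25 Hz, moving the masker across 100/125/150 Hz
        leaves section means within 5% of each other."""
        means = []
        for i, f_mask in enumerate([100.0, 125.0, 150.0]):
            trace, t0, t1 = masked_tone_recording(f_mask, f_mask + 25.0, 4.0,
                                                  0.05, seed=20 + i)
            thr = estimate_noise_level(trace, (0.05, 0.95), k=3.0)
            secs = measure_interference(
                trace, OverlapRegion(t0, t1, f_mask, f_mask + 25.0), thr)
            means.append(np.mean([s.mean_duration for s in secs]))
        assert np.ptp(means) / np.mean(means) < 0.05

    def test_invariance_to_recording_gain(self):
        """Recording gain (signal and noise scaled together, threshold from
        the recording itself) does not move section means."""
        means = []
        for vel in (0.2, 1.0, 1.9):
            trace, t0, t1 = masked_tone_recording(100.0, 125.0, 4.0,
                                                  0.05 * vel, seed=31,
                                                  velocity=vel)
            thr = estimate_noise_level(trace, (0.05, 0.95), k=3.0)
            secs = measure_interference(
                trace, OverlapRegion(t0, t1, 100.0, 125.0), thr)
            means.append(np.mean([s.mean_duration for s in secs]))
        assert np.ptp(means) / np.mean(means) < 0.05


class TestFitPowerLaw:
    def test_exact_inverse_law(self):
        x = [5.0, 10.0, 20.0, 50.0, 100.0]
        fit = fit_power_law([(xi, 1000.0 / xi) for xi in x])
        assert fit.coefficient == pytest.approx(1000.0)
        assert fit.exponent == pytest.approx(-1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_printed_durations(self):
        """The two text-reported durations (202.7 ms at 6 Hz, 19.7 ms at
        50 Hz) give the closed-form two-point fit b = log(y2/y1)/log(x2/x1)
        = -1.099, a = y1·x1^-b = 1453.4."""
        fit = fit_power_law([(6.0, 202.7), (50.0, 19.7)])
        b = np.log10(19.7 / 202.7) / np.log10(50.0 / 6.0)
        a = 202.7 / 6.0 ** b
        assert fit.exponent == pytest.approx(b)
        assert fit.coefficient == pytest.approx(a)
        assert fit.exponent == pytest.approx(-1.099, abs=5e-4)
        assert fit.coefficient == pytest.approx(1453.4, abs=0.1)
        assert fit.r_squared == pytest.approx(1.0)

    @given(st.floats(min_value=0.5, max_value=4.0))
    def test_scaling_y_moves_only_coefficient(self, lam):
        pts = [(6.0, 160.0), (10.0, 96.0), (25.0, 38.0), (50.0, 19.0)]
        base = fit_power_law(pts)
        scaled = fit_power_law([(x, lam * y) for x, y in pts])
        assert scaled.exponent == pytest.approx(base.exponent)
        assert scaled.coefficient == pytest.approx(lam * base.coefficient)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([(6.0, -1.0), (50.0, 19.7)])


class TestEnvelopePeriodicity:
    def test_tone_pair_peaks_at_delta_f(self):
        mixed = two_tone_overlap(100.0, 150.0, 4.0)
        region = OverlapRegion(0.2, 3.8, 100.0, 150.0)
        peak, depth = envelope_periodicity(mixed, region)
        assert peak == pytest.approx(50.0, abs=1.0)
        assert depth > 0.8

    def test_broadband_masking_has_no_peak(self):
        """A tone overlapped by broadband courtship-like noise shows no
        envelope-spectrum peak above 3x the median level."""
        spec = PulseSpec(duration=4000.0, peak_velocity=1.0, f_dominant=105.0,
                         f_start=105.0, f_end=105.0, fm_shape="broadband",
                         bandwidth=200.0)
        noise = synthesize_pulse(spec, FS, rng=9)
        noise = Trace(noise.samples / np.sqrt(np.mean(noise.samples ** 2))
                      * np.sqrt(0.5), FS)
        mixed = mix([(make_tone(111.0, 4000.0), 0.0, 1.0),
                     (noise, 0.0, 1.0)], 4.0)
        region = OverlapRegion(0.2, 3.8, 111.0, 105.0)
        _, mag = envelope_spectrum(mixed, region)
        assert np.max(mag) < 3.0 * np.median(mag)

    def test_constant_tone_has_negligible_depth(self):
        solo = mix([(make_tone(150.0, 4000.0), 0.0, 1.0)], 4.0)
        _, depth = envelope_periodicity(solo, OverlapRegion(0.2, 3.8, 150, 150))
        assert depth < 0.1


class TestGroupStatistics:
    def test_identical_samples(self):
        t, p = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_matches_hand_computed_three_vs_three(self):
        """Pooled-variance t on {1,2,3} vs {2,4,6}: sp² = (2·1 + 2·4)/4 =
        2.5, t = -2/sqrt(2.5·(2/3)) = -1.549."""
        t, p = compare_groups([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        sp2 = (2 * 1.0 + 2 * 4.0) / 4.0
        t_manual = (2.0 - 4.0) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_manual)
        assert t == pytest.approx(-1.5492, abs=1e-4)
        assert 0.19 < p < 0.20

    def test_published_control_vs_overlapped_magnitudes(self):
        """Synthetic samples at the 100-Hz masking row's (mean, sd) separate
        at p < 0.0001."""
        rng = np.random.default_rng(0)
        control = rng.normal(1281.7, 308.3, 60)
        overlapped = rng.normal(2745.5, 1326.0, 60)
        _, p = compare_groups(list(control), list(overlapped))
        assert p < 1e-4

    def test_anova_consistent_with_t_for_two_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 4.0, 5.0, 7.0]
        t, pt = compare_groups(a, b)
        f, pf = anova_oneway([a, b])
        assert f == pytest.approx(t ** 2)
        assert pf == pytest.approx(pt)

    def test_degenerate_variance_flagged(self):
        t, p = compare_groups([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and p == 0.0
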