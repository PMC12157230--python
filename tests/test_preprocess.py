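"""Signal-conditioning oracles: outliers, interpolation, filtering, jerk,
smoothing, resampling and the assembled per-recording pipeline."""

import numpy as np
import pytest
from scipy import signal as sps

from gaitfatigue.preprocess import (
    FilterSpec, PreprocessConfig, AllMaskedError,
    remove_outliers, interpolate_missing, bandpass, rectify, moving_average,
    smoothing_window_samples, linear_jerk, angular_jerk, resample_to_common,
    preprocess_recording,
)


class TestRemoveOutliers:
    def test_single_extreme_sample_masked(self):
        x = np.zeros(100)
        x[42] = 10.0
        # z-score of the spike under single-pass mean/SD is ≈ 9.9 > 3
        _, mask = remove_outliers(x, k=3.0)
        assert mask[42]
        assert mask.sum() == 1

    def test_constant_series_untouched(self):
        x = np.full(50, 3.3)
        _, mask = remove_outliers(x)
        assert not mask.any()

    def test_gaussian_tail_fraction(self):
        # P(|z| > 3) = 2Φ(−3) ≈ 0.0027
        x = np.random.default_rng(0).standard_normal(1_000_000)
        _, mask = remove_outliers(x, k=3.0)
        assert 0.0024 < mask.mean() < 0.0030

    def test_all_masked_is_an_error(self):
        with pytest.raises(AllMaskedError):
            remove_outliers(np.ones(5), np.ones(5, dtype=bool))


class TestInterpolateMissing:
    def test_midpoint(self):
        x = np.array([1.0, 0.0, 3.0])
        mask = np.array([False, True, False])
        np.testing.assert_allclose(interpolate_missing(x, mask), [1, 2, 3])

    def test_edge_extension(self):
        x = np.array([0.0, 5.0, 5.0, 0.0])
        mask = np.array([True, False, False, True])
        np.testing.assert_allclose(interpolate_missing(x, mask), [5, 5, 5, 5])

    def test_linear_data_recovered_exactly(self, rng):
        x = np.linspace(0, 10, 50)
        mask = np.zeros(50, dtype=bool)
        mask[rng.choice(np.arange(1, 49), size=3, replace=False)] = True
        np.testing.assert_allclose(interpolate_missing(x, mask), x, atol=1e-12)

    def test_idempotent(self, rng):
        x = rng.standard_normal(40)
        mask = rng.random(40) < 0.2
        once = interpolate_missing(x, mask)
        np.testing.assert_array_equal(
            interpolate_missing(once, np.zeros(40, dtype=bool)), once
        )

    def test_fully_masked_is_an_error(self):
        with pytest.raises(AllMaskedError):
            interpolate_missing(np.ones(5), np.ones(5, dtype=bool))


class TestBandpass:
    ACCEL = FilterSpec(1.0, 20.0)

    def test_dc_rejected(self):
        y = bandpass(np.full(2000, 5.0), self.ACCEL, fs=148.0)
        assert np.abs(y).max() < 5.0 * 1e-6

    def test_midband_tone_passes(self):
        # evaluate the designed two-pass response at 10 Hz
        sos = self.ACCEL.sos(148.0)
        w, h = sps.sosfreqz(sos, worN=[10.0], fs=148.0)
        gain = np.abs(h[0]) ** 2  # forward-backward
        assert 0.95 <= gain <= 1.0
        t = np.arange(4000) / 148.0
        y = bandpass(np.sin(2 * np.pi * 10 * t), self.ACCEL, fs=148.0)
        amp = np.abs(y[500:-500]).max()
        assert 0.95 <= amp <= 1.0

    def test_stopband_attenuation_at_60hz(self):
        sos = self.ACCEL.sos(148.0)
        _, h = sps.sosfreqz(sos, worN=[60.0], fs=148.0)
        atten_db = -20 * np.log10(np.abs(h[0]) ** 2)
        assert atten_db >= 20.0

    def test_response_contract_across_bands(self):
        # ≥ −3 dB inside the band (with margin), ≤ −20 dB at DC-adjacent and 2× high edge
        for spec, fs in ((FilterSpec(0.25, 30.0), 148.0),
                         (FilterSpec(1.0, 20.0), 148.0),
                         (FilterSpec(20.0, 500.0), 1259.0)):
            sos = spec.sos(fs)
            low_m, high_m = spec.low_hz * 2.0, spec.high_hz * 0.5
            _, h = sps.sosfreqz(sos, worN=[low_m, high_m], fs=fs)
            assert (np.abs(h) ** 2 >= 10 ** (-3 / 20)).all()
            edges = [0.01, min(2 * spec.high_hz, fs / 2 * 0.999)]
            _, h = sps.sosfreqz(sos, worN=edges, fs=fs)
            assert (np.abs(h) ** 2 <= 10 ** (-20 / 20)).all()

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(100), FilterSpec(20.0, 500.0), fs=148.0)


class TestRectifyAndSmooth:
    def test_rectify_examples_and_idempotence(self):
        x = np.array([-1.0, 2.0, -3.0])
        np.testing.assert_array_equal(rectify(x), [1, 2, 3])
        y = np.array([0.0, 1.5, 2.0])
        np.testing.assert_array_equal(rectify(y), y)
        np.testing.assert_array_equal(rectify(rectify(x)), rectify(x))

    def test_window_arithmetic_at_148hz(self):
        # round(0.1 × 148) = 15, already odd
        assert smoothing_window_samples(100.0, 148.0) == 15
        # round(0.1 × 1259) = 126 → bumped to 127
        assert smoothing_window_samples(100.0, 1259.0) == 127

    def test_impulse_spreads_to_plateau(self):
        x = np.zeros(301)
        x[150] = 1.0
        y = moving_average(x, 100.0, 148.0)
        plateau = y[143:158]
        np.testing.assert_allclose(plateau, 1.0 / 15, atol=1e-12)
        assert y[142] == 0.0 and y[158] == 0.0

    def test_constant_and_ramp_invariance(self):
        c = np.full(100, 2.5)
        np.testing.assert_allclose(moving_average(c, 100.0, 148.0), c)
        ramp = np.arange(100.0)
        y = moving_average(ramp, 100.0, 148.0)
        np.testing.assert_allclose(y[7:-7], ramp[7:-7], atol=1e-9)

    def test_window_longer_than_series_is_an_error(self):
        with pytest.raises(ValueError, match="longer"):
            moving_average(np.zeros(10), 100.0, 148.0)


class TestJerk:
    def test_constant_acceleration_gives_zero_jerk(self):
        a = np.tile([2.0, -1.0, 0.5], (50, 1))
        np.testing.assert_allclose(linear_jerk(a, 148.0), 0.0, atol=1e-12)

    def test_unit_slope(self):
        a = np.array([[0.0], [1.0], [2.0], [3.0]])
        np.testing.assert_allclose(linear_jerk(a, 1.0), 1.0)

    def test_quadratic_forward_difference_closed_form(self):
        # a(t) = t² → ((t+dt)² − t²)/dt = 2t + dt exactly
        fs = 100.0
        t = np.arange(200) / fs
        a = (t ** 2).reshape(-1, 1)
        j = linear_jerk(a, fs)[:-1, 0]
        expected = 2 * t[:-1] + 1 / fs
        assert np.abs(j - expected).max() < 1e-9

    def test_polynomial_oracle_degree_le_2(self, rng):
        # forward difference equals the closed-form difference quotient
        fs = 148.0
        t = np.arange(100) / fs
        for _ in range(5):
            c0, c1, c2 = rng.standard_normal(3)
            a = (c0 + c1 * t + c2 * t ** 2).reshape(-1, 1)
            j = linear_jerk(a, fs)[:-1, 0]
            dt = 1 / fs
            expected = c1 + c2 * (2 * t[:-1] + dt)
            np.testing.assert_allclose(j, expected, atol=1e-9)

    def test_angular_jerk_sinusoid_within_forward_difference_bound(self):
        fs = 148.0
        t = np.arange(1000) / fs
        w = np.sin(2 * np.pi * 2 * t).reshape(-1, 1)
        j = angular_jerk(w, fs)[:-1, 0]
        analytic = 2 * np.pi * 2 * np.cos(2 * np.pi * 2 * t[:-1])
        # |error| ≤ (dt/2)·max|ω''| for the forward difference
        bound = (1 / fs) / 2 * (2 * np.pi * 2) ** 2 * 1.01
        assert np.abs(j - analytic).max() <= bound

    def test_angular_jerk_second_order_switch(self):
        fs = 10.0
        t = np.arange(50) / fs
        w = (t ** 2).reshape(-1, 1)  # dω/dt = 2t, d²ω/dt² = 2
        j2 = angular_jerk(w, fs, order=2)[:-2, 0]
        np.testing.assert_allclose(j2, 2.0, atol=1e-9)

    def test_too_short_input_is_an_error(self):
        with pytest.raises(ValueError):
            linear_jerk(np.zeros((1, 3)), 148.0)


class TestResample:
    def test_identity_rate_passthrough(self, rng):
        x = rng.standard_normal(500)
        np.testing.assert_array_equal(resample_to_common(x, 148.0, 148.0), x)

    def test_emg_length_arithmetic(self):
        y = resample_to_common(np.zeros(18900), 1259.0, 148.0)
        assert abs(len(y) - round(18900 * 148 / 1259)) <= 1

    def test_inband_amplitude_preserved(self):
        t = np.arange(12590) / 1259.0
        x = np.sin(2 * np.pi * 5 * t)
        y = resample_to_common(x, 1259.0, 148.0)
        amp = np.abs(y[100:-100]).max()
        assert abs(amp - 1.0) < 0.01

    def test_nonpositive_rate_is_an_error(self):
        with pytest.raises(ValueError):
            resample_to_common(np.zeros(10), 0.0, 148.0)


class TestPreprocessRecording:
    def test_shapes_finiteness_and_channel_layout(self, tiny_cohort):
        key = sorted(tiny_cohort.recordings)[0]
        rec = preprocess_recording(tiny_cohort.recordings[key])
        # 16 s × 148 Hz = 2368 IMU frames; EMG resamples to within ±1
        assert abs(rec.n_frames - 2368) <= 1
        assert rec.data.shape[1] == 42
        assert np.isfinite(rec.data).all()
        assert rec.channel_names[0] == "TAL.linjerk.x"
        assert rec.channel_names[6] == "TAL.emg_env"
        assert "GLL.emg_env" in rec.channel_names

    def test_every_channel_same_frame_count(self, tiny_cohort):
        key = sorted(tiny_cohort.recordings)[0]
        rec = preprocess_recording(tiny_cohort.recordings[key])
        assert rec.data.ndim == 2  # single matrix → identical length by construction

    def test_deterministic(self, tiny_cohort):
        key = sorted(tiny_cohort.recordings)[0]
        a = preprocess_recording(tiny_cohort.recordings[key])
        b = preprocess_recording(tiny_cohort.recordings[key])
        np.testing.assert_array_equal(a.data, b.data)

    def test_dropout_gaps_are_filled(self, tiny_params):
        from dataclasses import replace
        from gaitfatigue.synthetic_gait import simulate_cohort

        params = replace(tiny_params, n_subjects=2, dropout_frac=0.01, seed=11)
        cohort = simulate_cohort(params)
        key = sorted(cohort.recordings)[0]
        group = cohort.recordings[key]
        assert any(group[s].emg_mask.any() for s in group)
        rec = preprocess_recording(group)
        assert np.isfinite(rec.data).all()

    def test_incomplete_group_rejected(self, tiny_cohort):
        key = sorted(tiny_cohort.recordings)[0]
        group = dict(tiny_cohort.recordings[key])
        group.pop("GLR")
        with pytest.raises(ValueError, match="GLR"):
            preprocess_recording(group)
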