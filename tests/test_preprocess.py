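"""Filtering, event detection, feature assembly, discrete variables."""

import numpy as np
import pytest

from gaitsig.cohort import CohortConfig, G, draw_subject_params, generate_trial
from gaitsig.preprocess import (
    FEATURE_SET_SIZES,
    GaitEvents,
    assemble_feature_set,
    compute_discrete_variables,
    compute_spatiotemporal,
    detect_gait_events,
    downsample,
    lowpass_filter,
)


def make_trial(**kw):
    defaults = dict(
        n_subjects=1, speeds_per_subject=1, speed_min=0.5, speed_max=1.5,
        duration_s=10.0, data_type="combined", noise_sd=0.0, jitter_sd=0.0,
        seed=2,
    )
    defaults.update(kw)
    cfg = CohortConfig(**defaults)
    p = draw_subject_params(cfg, 0)
    trial, truth = generate_trial(p, 1.0, cfg)
    return cfg, trial, truth


class TestLowpassFilter:
    def test_dc_passthrough(self):
        x = np.full((500, 2), 3.7)
        y = lowpass_filter(x, cutoff=6.0, fs=100.0)
        np.testing.assert_allclose(y, x, atol=1e-9)

    def test_attenuates_high_preserves_low(self):
        fs, T = 100.0, 2000
        t = np.arange(T) / fs
        low = np.sin(2 * np.pi * 1.0 * t)
        high = np.sin(2 * np.pi * 40.0 * t)
        y = lowpass_filter((low + high)[:, None], cutoff=6.0, fs=fs)[:, 0]
        freqs = np.fft.rfftfreq(T, 1 / fs)
        spec_in = np.abs(np.fft.rfft(low + high)) / T * 2
        spec_out = np.abs(np.fft.rfft(y)) / T * 2
        i1 = np.argmin(np.abs(freqs - 1.0))
        i40 = np.argmin(np.abs(freqs - 40.0))
        assert spec_out[i40] < spec_in[i40] / 20.0
        assert abs(spec_out[i1] - spec_in[i1]) / spec_in[i1] < 0.02

    def test_double_filtering_squares_response(self):
        # amplitude response measured at exact FFT bins of a multi-sine:
        # filtering twice squares the single-pass magnitude response
        fs, T = 100.0, 4000
        t = np.arange(T) / fs
        freqs_hz = [1.0, 3.0, 5.0, 8.0, 12.0]  # exact bins (0.025 Hz grid)
        x = sum(np.sin(2 * np.pi * f * t) for f in freqs_hz)
        once = lowpass_filter(x[:, None], 6.0, fs)[:, 0]
        twice = lowpass_filter(once[:, None], 6.0, fs)[:, 0]
        fgrid = np.fft.rfftfreq(T, 1 / fs)
        fx = np.abs(np.fft.rfft(x))
        f1 = np.abs(np.fft.rfft(once))
        f2 = np.abs(np.fft.rfft(twice))
        for f in freqs_hz:
            i = np.argmin(np.abs(fgrid - f))
            h1 = f1[i] / fx[i]
            h2 = f2[i] / fx[i]
            assert h2 == pytest.approx(h1**2, rel=0.05, abs=5e-3)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(np.zeros(100), cutoff=50.0, fs=100.0)


class TestDownsample:
    def test_2000_to_100_length(self):
        x = np.zeros(4000)  # 2 s at 2000 Hz
        y = downsample(x, 2000.0, 100.0)
        assert len(y) == 200

    def test_identity_factor(self):
        x = np.arange(50.0)
        np.testing.assert_array_equal(downsample(x, 100.0, 100.0), x)

    def test_amplitude_preserved_below_cutoff(self):
        t = np.arange(20000) / 2000.0
        x = np.sin(2 * np.pi * 3.0 * t)
        y = downsample(x, 2000.0, 100.0)
        assert abs(np.max(np.abs(y)) - 1.0) < 0.01

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            downsample(np.zeros(100), 150.0, 100.0)


class TestDetectGaitEvents:
    def test_exact_recovery_on_noise_free_vgrf(self):
        _, trial, truth = make_trial()
        ev = detect_gait_events(trial.vgrf_right, trial.vgrf_left, trial.fs)
        np.testing.assert_array_equal(
            ev.heel_strikes_right, truth.true_heel_strikes_right)
        np.testing.assert_array_equal(
            ev.heel_strikes_left, truth.true_heel_strikes_left)
        np.testing.assert_array_equal(
            ev.toe_offs_right, truth.true_toe_offs_right)
        np.testing.assert_array_equal(
            ev.toe_offs_left, truth.true_toe_offs_left)

    def test_all_zero_vgrf_raises(self):
        with pytest.raises(ValueError, match="insufficient strides"):
            detect_gait_events(np.zeros(1000), np.zeros(1000), 100.0)

    def test_negative_vgrf_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            detect_gait_events(np.full(100, -1.0), np.zeros(100), 100.0)

    def test_threshold_zero_close_to_threshold_twenty(self):
        _, trial, _ = make_trial()
        ev20 = detect_gait_events(trial.vgrf_right, trial.vgrf_left,
                                  trial.fs, threshold=20.0)
        ev_small = detect_gait_events(trial.vgrf_right, trial.vgrf_left,
                                      trial.fs, threshold=1e-9)
        # stance onsets may differ only by samples where 0 < vgrf < 20
        shift = ev20.heel_strikes_right - ev_small.heel_strikes_right
        assert np.all(shift >= 0) and np.all(shift <= 3)

    def test_noisy_vgrf_after_filtering_recovers_cadence(self):
        _, trial, truth = make_trial(duration_s=20.0)
        rng = np.random.default_rng(4)
        noisy_r = np.maximum(trial.vgrf_right + 5.0 * rng.standard_normal(
            trial.vgrf_right.shape), 0.0)
        noisy_l = np.maximum(trial.vgrf_left + 5.0 * rng.standard_normal(
            trial.vgrf_left.shape), 0.0)
        filt_r = np.maximum(lowpass_filter(noisy_r, 30.0, trial.fs), 0.0)
        filt_l = np.maximum(lowpass_filter(noisy_l, 30.0, trial.fs), 0.0)
        ev = detect_gait_events(filt_r, filt_l, trial.fs)
        st = compute_spatiotemporal(trial, ev)
        assert abs(st.cadence_r - truth.true_cadence) / truth.true_cadence < 0.01


class TestAssembleFeatureSet:
    @pytest.mark.parametrize("data_type,n_channels",
                             [("kin2d", 6), ("kin3d", 18),
                              ("kinetics3d", 42), ("combined", 60)])
    def test_channel_counts(self, data_type, n_channels):
        _, trial, _ = make_trial()
        x, labels = assemble_feature_set(trial, data_type)
        assert x.shape[1] == n_channels and len(labels) == n_channels

    def test_grf_in_body_weight_units(self):
        _, trial, _ = make_trial()
        x, labels = assemble_feature_set(trial, "kinetics3d")
        j = labels.index("grf_vertical_r")
        raw = trial.samples[:, trial.channel_labels.index("grf_vertical_r")]
        np.testing.assert_allclose(x[:, j] * trial.body_mass * G, raw)

    def test_missing_channel_named(self):
        cfg = CohortConfig(n_subjects=1, speeds_per_subject=1,
                           duration_s=2.0, data_type="kin2d", seed=0)
        p = draw_subject_params(cfg, 0)
        trial, _ = generate_trial(p, cfg.mid_speed, cfg)
        with pytest.raises(ValueError, match="grf_vertical_r"):
            assemble_feature_set(trial, "kinetics3d")


class TestSpatiotemporal:
    def test_matches_ground_truth_on_jitter_free_trial(self):
        _, trial, truth = make_trial()
        ev = detect_gait_events(trial.vgrf_right, trial.vgrf_left, trial.fs)
        st = compute_spatiotemporal(trial, ev, step_width=truth.true_step_width)
        # sample quantization bounds the residual error
        assert st.cadence_r == pytest.approx(truth.true_cadence, rel=0.01)
        assert st.stance_duration_r == pytest.approx(
            truth.true_stance_duration, abs=2 / trial.fs)
        assert st.swing_duration_r == pytest.approx(
            truth.true_swing_duration, abs=2 / trial.fs)
        assert st.step_length_r == pytest.approx(truth.true_step_length,
                                                 rel=0.01)
        assert st.step_width_r == truth.true_step_width

    def test_step_length_cadence_speed_identity(self):
        _, trial, _ = make_trial()
        ev = detect_gait_events(trial.vgrf_right, trial.vgrf_left, trial.fs)
        st = compute_spatiotemporal(trial, ev)
        assert st.step_length_r * st.cadence_r / 60.0 == pytest.approx(
            trial.speed, rel=1e-9)

    def test_stance_plus_swing_equals_stride(self):
        _, trial, _ = make_trial()
        ev = detect_gait_events(trial.vgrf_right, trial.vgrf_left, trial.fs)
        st = compute_spatiotemporal(trial, ev)
        stride = np.mean(np.diff(ev.heel_strikes_right)) / trial.fs
        assert st.stance_duration_r + st.swing_duration_r == pytest.approx(
            stride, abs=1e-9)

    def test_insufficient_strides_raises(self):
        _, trial, _ = make_trial()
        ev = GaitEvents(
            heel_strikes_right=np.array([0, 100]),
            heel_strikes_left=np.array([50, 150]),
            toe_offs_right=np.array([60]),
            toe_offs_left=np.array([110]),
        )
        with pytest.raises(ValueError, match="insufficient"):
            compute_spatiotemporal(trial, ev)


class TestDiscreteVariables:
    def test_row_lengths(self):
        _, trial, truth = make_trial()
        ev = detect_gait_events(trial.vgrf_right, trial.vgrf_left, trial.fs)
        for name, size in FEATURE_SET_SIZES.items():
            row = compute_discrete_variables(
                trial, ev, name, step_width=truth.true_step_width)
            assert len(row) == size

    def test_constant_channel_zero_excursion(self):
        _, trial, _ = make_trial()
        trial.samples[:, trial.channel_labels.index(
            "hip_sagittal_angle_r")] = 4.2
        ev = detect_gait_events(trial.vgrf_right, trial.vgrf_left, trial.fs)
        row = compute_discrete_variables(trial, ev, "kinematic18")
        assert row["hip_peak_r"] == row["hip_min_r"] == pytest.approx(4.2)
        assert row["hip_excursion_r"] == pytest.approx(0.0)

    def test_single_cosine_excursion_is_twice_amplitude(self):
        _, trial, _ = make_trial(n_harmonics=1, duration_s=20.0)
        ev = detect_gait_events(trial.vgrf_right, trial.vgrf_left, trial.fs)
        idx = trial.channel_labels.index("knee_sagittal_angle_r")
        amp = (trial.samples[:, idx].max() - trial.samples[:, idx].min()) / 2
        row = compute_discrete_variables(trial, ev, "kinematic18")
        assert row["knee_excursion_r"] == pytest.approx(2 * amp, rel=1e-3)

    def test_unknown_set_rejected(self):
        _, trial, _ = make_trial()
        with pytest.raises(ValueError, match="unknown feature set"):
            compute_discrete_variables(trial, None, "everything")
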