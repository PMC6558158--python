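"""Synthetic session generator: reproducibility, truth consistency."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import periodogram

import headgait as hg
from headgait import quat
from headgait.errors import ConfigError


def _plain_params(**kw):
    """Params that keep sensors un-mounted, un-drifted and noise-free so the
    sensor output equals gravity + the designed inertial signal."""
    base = dict(
        mounting_head=(0.0, 0.0, 0.0),
        mounting_trunk=(0.0, 0.0, 0.0),
        clock_offset=0.0,
        clock_drift=0.0,
        head_pitch_amp=0.0,
        trunk_pitch_amp=0.0,
        p_cycling=0.0,
    )
    base.update(kw)
    return hg.GaitGeneratorParams(**base).noiseless()


class TestReproducibility:
    def test_identical_seed_bit_identical(self):
        p = hg.GaitGeneratorParams(seed=9)
        h1, t1, _ = hg.generate_session(p, 90.0)
        h2, t2, _ = hg.generate_session(p, 90.0)
        assert np.array_equal(h1.accel, h2.accel)
        assert np.array_equal(h1.gyro, h2.gyro)
        assert np.array_equal(t1.accel, t2.accel)

    def test_different_seed_differs(self):
        h1, _, _ = hg.generate_session(hg.GaitGeneratorParams(seed=9), 90.0)
        h2, _, _ = hg.generate_session(hg.GaitGeneratorParams(seed=10), 90.0)
        assert not np.array_equal(h1.accel, h2.accel)


class TestGroundTruthStructure:
    def test_step_times_strictly_increasing(self, noiseless_session):
        _, _, _, truth = noiseless_session
        assert np.all(np.diff(truth.true_step_times) > 0)

    def test_labels_partition_timeline(self, noiseless_session):
        _, _, trunk, truth = noiseless_session
        assert truth.segment_labels.size == trunk.n_samples
        assert set(np.unique(truth.segment_labels)) <= {
            "gait", "cycling", "rest", "knock",
            "calibration-static", "calibration-nod",
        }

    def test_orientation_unit_norm(self, noiseless_session):
        _, _, _, truth = noiseless_session
        for q in truth.true_orientation.values():
            np.testing.assert_allclose(
                np.linalg.norm(q, axis=1), 1.0, atol=1e-9
            )

    def test_gravity_consistent_with_orientation(self, noiseless_session):
        _, _, _, truth = noiseless_session
        for placement in ("head", "trunk"):
            g = quat.rotate_inverse(
                truth.true_orientation[placement], [0.0, 0.0, 1.0]
            )
            np.testing.assert_allclose(
                g, truth.true_gravity[placement], atol=1e-9
            )

    def test_too_short_duration_rejected(self):
        with pytest.raises(ConfigError, match="60 s"):
            hg.generate_session(hg.GaitGeneratorParams(), 30.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            hg.GaitGeneratorParams(ac_targets=(0.3, 0.2, 1.5))
        with pytest.raises(ConfigError):
            hg.GaitGeneratorParams(step_freq_mean=-1.0)
        with pytest.raises(ConfigError):
            hg.GaitGeneratorParams(accel_noise_sd=-0.1)


class TestGaitSignalStructure:
    def test_deterministic_cadence_spacing(self):
        p = _plain_params(
            seed=1, step_freq_mean=2.0, step_freq_sd=0.0,
            bout_min=1200, bout_max=1200,
        )
        _, _, truth = hg.generate_session(p, 600.0)
        assert len(truth.true_bout_boundaries) == 1
        np.testing.assert_allclose(np.diff(truth.true_step_times), 0.5,
                                   atol=1e-9)

    def test_ac_target_is_exact_rms_ratio(self):
        p = _plain_params(seed=2, ac_targets=(0.3, 0.2, 0.5))
        head, trunk, truth = hg.generate_session(p, 120.0)
        gait = truth.segment_labels == "gait"
        hv = head.accel[gait, 2] - 1.0  # inertial V (no mounting, no tilt)
        tv = trunk.accel[gait, 2] - 1.0
        ratio = np.sqrt(np.mean(hv**2) / np.mean(tv**2))
        assert ratio == pytest.approx(0.5, abs=1e-9)

    def test_step_frequency_draws_match_population(self):
        # many bouts: the drawn per-bout frequencies estimate N(1.86, 0.23)
        _, _, truth = hg.generate_session(hg.GaitGeneratorParams(seed=7), 3600.0)
        draws = truth.bout_freqs
        se = 0.23 / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(1.86, abs=3 * se)

    def test_spectral_self_consistency(self):
        # periodogram peak of trunk V during a bout = drawn frequency ± 1 bin
        p = _plain_params(seed=3, bout_min=200, bout_max=200)
        _, trunk, truth = hg.generate_session(p, 300.0)
        i0, i1 = truth.true_bout_boundaries[0]
        v = trunk.accel[i0:i1, 2] - 1.0
        f, pxx = periodogram(v, fs=100.0)
        peak = f[np.argmax(pxx)]
        assert abs(peak - truth.bout_freqs[0]) < 100.0 / v.size + 1e-9

    def test_phase_self_consistency(self):
        # corrected displacement-vs-angle phase equals head_pitch_phase
        p = dataclasses.replace(
            _plain_params(seed=4, bout_min=400, bout_max=400),
            head_pitch_amp=0.5,
        )
        head, _, truth = hg.generate_session(p, 400.0)
        i0, i1 = truth.true_bout_boundaries[0]
        center = (i0 + i1) // 2
        x = head.accel[:, 2] - np.cos(  # vertical inertial accel
            np.arccos(np.clip(truth.true_gravity["head"][:, 2], -1, 1))
        )
        y = head.gyro[:, 1]
        got = hg.phase_difference(x, y, center)
        assert np.rad2deg(abs(got - p.head_pitch_phase)) < 1.0


class TestOrientationTrajectories:
    def test_zero_rate_constant_orientation(self):
        accel, gyro, q = hg.generate_orientation_trajectory(
            1, 10.0, rate=0.0, inertial_amp=0.0
        )
        assert np.abs(gyro).max() < 1e-12
        np.testing.assert_allclose(accel, np.tile([0, 0, 1.0], (1000, 1)),
                                   atol=1e-12)

    def test_pure_pitch_gravity_geometry(self):
        amp = np.deg2rad(20.0)
        accel, _, _ = hg.pitch_oscillation_trajectory(30.0, amp=amp, freq=0.2)
        t = np.arange(3000) / 100.0
        pitch = amp * np.sin(2 * np.pi * 0.2 * t)
        np.testing.assert_allclose(accel[:, 2], np.cos(pitch), atol=1e-12)

    def test_gyro_integrates_to_truth(self):
        # independent oracle: brute-force small-step rotation composition
        accel, gyro, q = hg.generate_orientation_trajectory(
            3, 10.0, sample_rate=2000.0, inertial_amp=0.0
        )
        qi = q[0].copy()
        dt = 1.0 / 2000.0
        for i in range(1, gyro.shape[0]):
            w = 0.5 * (gyro[i - 1] + gyro[i])
            ang = np.linalg.norm(w) * dt
            if ang > 0:
                qi = quat.normalize(
                    quat.multiply(qi, quat.from_axis_angle(w / np.linalg.norm(w), ang))
                )
        assert hg.geodesic_distance(qi, q[-1]) < 1e-6

    def test_max_tilt_respected(self):
        max_tilt = np.deg2rad(15.0)
        accel, _, q = hg.generate_orientation_trajectory(
            5, 60.0, max_tilt=max_tilt, rate=2.0, inertial_amp=0.0
        )
        tilt = np.arccos(np.clip(accel[:, 2], -1, 1))
        assert tilt.max() <= max_tilt + 1e-9

    def test_excessive_tilt_rejected(self):
        with pytest.raises(ConfigError):
            hg.generate_orientation_trajectory(1, 10.0, max_tilt=2.0)
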