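"""Gravity filter, geodesic metric, and aligned-frame transform."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import headgait as hg
from headgait import io as hio
from headgait import orientation as ho
from headgait import quat
from headgait.errors import ConfigError


def _recording_from(accel, gyro):
    n = accel.shape[0]
    return hio.ImuRecording(np.arange(n) / 100.0, accel, gyro, "head")


class TestPrefilter:
    def test_gyro_bias_removed(self):
        n = 6000
        rec = _recording_from(
            np.tile([0.0, 0.0, 1.0], (n, 1)),
            np.tile([0.05, -0.02, 0.01], (n, 1)),
        )
        _, gyro_f = ho.prefilter(rec)
        assert np.abs(gyro_f.mean(axis=0)).max() < 1e-4

    def test_accel_tone_attenuated_beyond_cutoff(self):
        n = 6000
        t = np.arange(n) / 100.0
        f_lp = 0.5
        tone = np.sin(2 * np.pi * 10 * f_lp * t)
        accel = np.column_stack([tone, np.zeros(n), np.ones(n)])
        rec = _recording_from(accel, np.zeros((n, 3)))
        accel_f, _ = ho.prefilter(rec, f_lp=f_lp)
        # zero-phase 5th-order Butterworth: > 40 dB per pass at 10× cut-off
        atten = np.max(np.abs(accel_f[1000:-1000, 0]))
        assert atten < 10 ** (-40 / 20)

    def test_zero_in_zero_out(self):
        rec = _recording_from(np.zeros((2000, 3)), np.zeros((2000, 3)))
        accel_f, gyro_f = ho.prefilter(rec)
        assert np.abs(accel_f).max() < 1e-12
        assert np.abs(gyro_f).max() < 1e-12

    @pytest.mark.parametrize("f_lp", [0.05, 60.0])
    def test_cutoff_out_of_range(self, f_lp):
        rec = _recording_from(np.zeros((2000, 3)), np.zeros((2000, 3)))
        with pytest.raises(ConfigError):
            ho.prefilter(rec, f_lp=f_lp)


class TestGravityFilter:
    def test_static_sensor_any_alpha(self):
        n = 1000
        accel = np.tile([0.0, 0.0, 1.0], (n, 1))
        gyro = np.zeros((n, 3))
        for alpha in (0.0, 0.5, 1.0):
            est = ho.gravity_filter(accel, gyro, alpha=alpha)
            np.testing.assert_allclose(est.gravity, accel, atol=1e-12)
            np.testing.assert_allclose(
                est.orientation, np.tile(quat.IDENTITY, (n, 1)), atol=1e-12
            )

    def test_alpha_zero_tracks_normalized_accel(self, rng):
        accel = rng.normal([0, 0, 1], 0.05, size=(500, 3))
        gyro = rng.normal(0, 0.2, size=(500, 3))
        est = ho.gravity_filter(accel, gyro, alpha=0.0)
        expected = accel / np.linalg.norm(accel, axis=1, keepdims=True)
        np.testing.assert_allclose(est.gravity, expected, atol=1e-12)

    def test_gyro_only_pure_pitch_accuracy(self):
        accel, gyro, q_true = hg.pitch_oscillation_trajectory(60.0)
        est = ho.gravity_filter(accel, gyro, alpha=1.0)
        err = np.rad2deg(hg.geodesic_distance(est.orientation, q_true))
        assert err.max() < 0.5

    def test_alpha_out_of_range(self):
        with pytest.raises(ConfigError):
            ho.gravity_filter(np.zeros((10, 3)), np.zeros((10, 3)), alpha=1.5)

    def test_unit_norm_outputs(self, noisy_session):
        _, _, trunk, _ = noisy_session
        accel_f, gyro_f = ho.prefilter(trunk)
        est = ho.gravity_filter(accel_f[:20000], gyro_f[:20000])
        np.testing.assert_allclose(
            np.linalg.norm(est.gravity, axis=1), 1.0, atol=1e-9
        )
        np.testing.assert_allclose(
            np.linalg.norm(est.orientation, axis=1), 1.0, atol=1e-9
        )

    def test_yaw_free_contract(self, noisy_session):
        _, _, trunk, _ = noisy_session
        accel_f, gyro_f = ho.prefilter(trunk)
        est = ho.gravity_filter(accel_f[:20000], gyro_f[:20000])
        # rotation axis = vector part; must be horizontal
        assert np.abs(est.orientation[:, 3]).max() < 1e-9

    def test_monotone_degradation_with_noise(self):
        medians = []
        for noise in (0.0, 0.05, 0.2):
            accel, gyro, q_true = hg.generate_orientation_trajectory(
                21, 60.0, noise_sd=noise
            )
            rec = _recording_from(accel, gyro)
            accel_f, gyro_f = ho.prefilter(rec)
            est = ho.gravity_filter(accel_f, gyro_f)
            medians.append(
                np.median(hg.geodesic_distance(est.orientation, q_true))
            )
        assert medians[0] <= medians[1] <= medians[2]


class TestGeodesicDistance:
    def test_identical_quaternions(self):
        q = quat.normalize(np.array([0.3, 0.2, -0.5, 0.7]))
        assert hg.geodesic_distance(q, q) == pytest.approx(0.0, abs=1e-7)

    def test_half_turn_any_axis(self, rng):
        for _ in range(5):
            axis = rng.normal(size=3)
            q = quat.from_axis_angle(axis, np.pi)
            assert hg.geodesic_distance(quat.IDENTITY, q) == pytest.approx(np.pi)

    def test_sign_flip_invariance(self, rng):
        q1 = quat.normalize(rng.normal(size=4))
        q2 = quat.normalize(rng.normal(size=4))
        d = hg.geodesic_distance(q1, q2)
        assert hg.geodesic_distance(-q1, q2) == pytest.approx(d, abs=1e-12)
        assert hg.geodesic_distance(q1, -q2) == pytest.approx(d, abs=1e-12)

    def test_matches_relative_rotation_oracle(self, rng):
        # independent oracle: angle from the trace of the relative matrix
        for _ in range(100):
            r1, r2 = Rotation.random(2, random_state=rng.integers(2**31))
            q1, q2 = quat.from_scipy(r1), quat.from_scipy(r2)
            rel = r1.inv() * r2
            angle = np.arccos(np.clip((np.trace(rel.as_matrix()) - 1) / 2, -1, 1))
            assert hg.geodesic_distance(q1, q2) == pytest.approx(angle, abs=1e-9)


class TestToAligned:
    def test_accel_equals_gravity_gives_zero(self):
        n = 100
        accel = np.tile([0.0, 0.0, 1.0], (n, 1))
        est = ho.gravity_filter(accel, np.zeros((n, 3)), alpha=0.5)
        aligned = ho.to_aligned(accel, est)
        assert np.abs(aligned.inertial_accel).max() < 1e-12

    def test_identity_orientation_componentwise(self, rng):
        n = 50
        accel = np.tile([0.0, 0.0, 1.0], (n, 1))
        est = ho.gravity_filter(accel, np.zeros((n, 3)), alpha=0.5)
        raw = rng.normal(size=(n, 3))
        aligned = ho.to_aligned(raw, est)
        np.testing.assert_allclose(
            aligned.inertial_accel, raw - accel, atol=1e-12
        )

    def test_static_segment_inertial_small(self, noiseless_result, noiseless_session):
        _, _, _, truth = noiseless_session
        tr = noiseless_result.aligned["trunk"]
        static = truth.segment_labels == "calibration-static"
        mean_mag = np.linalg.norm(tr.inertial_accel[static].mean(axis=0))
        assert mean_mag < 0.02

    def test_session_vertical_recovery(self, noiseless_result, noiseless_session):
        _, _, _, truth = noiseless_session
        tr = noiseless_result.aligned["trunk"]
        gait = truth.segment_labels == "gait"
        # vertical inertial RMS during gait should match the generator's
        # harmonic series; rest segments should be near zero
        rest = truth.segment_labels == "rest"
        assert np.sqrt(np.mean(tr.v[rest] ** 2)) < 0.02
        assert np.sqrt(np.mean(tr.v[gait] ** 2)) > 0.2
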