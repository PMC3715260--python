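"""Calibration, spherical features, derivatives, placement checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from wimotion import motion_features as mf

DOWN = np.array([0.0, 0.0, -1.0])


def static_window(direction, n=200, noise=0.0, rng=None):
    w = np.tile(np.asarray(direction, dtype=float), (n, 1))
    if noise and rng is not None:
        w = w + rng.normal(0, noise, w.shape)
    return w


class TestSpherical:
    @pytest.mark.parametrize("vec,theta", [
        ((0, 0, -1), 180.0),   # gravity to the floor in standing
        ((0, 0, 1), 0.0),
        ((1, 0, 0), 90.0),
        ((0, 1, 0), 90.0),
    ])
    def test_polar_angle(self, vec, theta):
        sph = mf.to_spherical(np.array([vec], dtype=float))
        assert sph.theta_deg[0] == pytest.approx(theta, abs=1e-9)
        assert sph.r[0] == pytest.approx(1.0)

    def test_zero_vector_propagates_nan(self):
        sph = mf.to_spherical(np.zeros((1, 3)))
        assert np.isnan(sph.theta_deg[0]) and np.isnan(sph.phi_deg[0])

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_cartesian(self, v):
        v = np.array([v])
        if np.linalg.norm(v) < 1e-6 or abs(v[0, 2]) > 0.99 * np.linalg.norm(v):
            return  # poles and origin excluded
        sph = mf.to_spherical(v)
        back = mf.spherical_to_cartesian(sph.r, sph.theta_deg, sph.phi_deg)
        np.testing.assert_allclose(back, v, atol=1e-9)

    def test_theta_bounds_for_random_inputs(self, rng):
        v = rng.normal(size=(500, 3))
        sph = mf.to_spherical(v)
        assert ((sph.theta_deg >= 0) & (sph.theta_deg <= 180)).all()

    def test_r_conserved_under_rotation(self, rng):
        v = rng.normal(size=(100, 3))
        R = Rotation.random(random_state=1).as_matrix()
        np.testing.assert_allclose(
            mf.to_spherical(v @ R.T).r, mf.to_spherical(v).r, rtol=1e-9)


class TestCalibration:
    def test_identity_mounting(self):
        cal = mf.calibrate(static_window(DOWN))
        np.testing.assert_allclose(cal.rotation, np.eye(3), atol=1e-9)
        assert cal.residual_deg == pytest.approx(0.0, abs=1e-9)

    def test_known_rotation_recovered_to_theta_180(self, rng):
        R0 = Rotation.from_euler("xyz", [40, -25, 110], degrees=True).as_matrix()
        window = static_window(R0 @ DOWN, noise=0.02, rng=rng)
        cal = mf.calibrate(window)
        theta = mf.to_spherical(cal.apply(window).mean(axis=0, keepdims=True))
        assert theta.theta_deg[0] == pytest.approx(180.0, abs=0.5)

    def test_monte_carlo_random_mountings(self, rng):
        errs = []
        for k in range(100):
            R0 = Rotation.random(random_state=k).as_matrix()
            window = static_window(R0 @ DOWN, noise=0.02, rng=rng)
            cal = mf.calibrate(window)
            sph = mf.to_spherical(cal.apply(window).mean(axis=0, keepdims=True))
            errs.append(abs(sph.theta_deg[0] - 180.0))
        assert np.mean(errs) < 2.0

    def test_rotation_is_proper_orthonormal(self, rng):
        for k in range(10):
            R0 = Rotation.random(random_state=k).as_matrix()
            cal = mf.calibrate(static_window(R0 @ DOWN, noise=0.01, rng=rng))
            np.testing.assert_allclose(
                cal.rotation @ cal.rotation.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(cal.rotation) == pytest.approx(1.0)

    def test_non_static_window_rejected_with_motion_level(self):
        # a slow orientation sweep is motion, not noise, and must be
        # rejected with the measured level in the message
        t = np.linspace(0, np.pi / 2, 320)
        w = np.column_stack([np.sin(t), np.zeros_like(t), -np.cos(t)])
        with pytest.raises(mf.CalibrationError, match="not static"):
            mf.calibrate(w)

    def test_noisy_but_still_window_accepted(self, rng):
        # white sensor noise at the static threshold is not motion
        w = static_window(DOWN, noise=0.05, rng=rng)
        cal = mf.calibrate(w)
        assert cal.residual_deg < 1e-6

    def test_short_window_rejected(self):
        with pytest.raises(mf.CalibrationError, match="shorter"):
            mf.calibrate(static_window(DOWN, n=50))

    def test_rotation_invariance_of_features(self, rng):
        # calibrating away a mounting rotation must restore θ of the
        # original body-frame series for all vectors
        t = np.linspace(0, np.pi, 100)
        body = np.column_stack([np.sin(t), np.zeros_like(t), np.cos(t)])
        R0 = Rotation.random(random_state=7).as_matrix()
        cal = mf.CalibrationResult(np.linalg.inv(R0), 0.0)
        np.testing.assert_allclose(
            mf.to_spherical(cal.apply(body @ R0.T)).theta_deg,
            mf.to_spherical(body).theta_deg, atol=1e-9)


class TestDerivative:
    def test_constant_series_zero(self):
        d = mf.derivative(np.full(400, 120.0))
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_linear_ramp_slope(self):
        t = np.arange(800) / 160.0
        theta = 180.0 - 30.0 * t
        d = mf.derivative(theta)
        assert np.allclose(d[100:-100], -30.0, atol=0.1)

    def test_smoothing_beats_raw_on_noisy_ramp(self, rng):
        t = np.arange(1600) / 160.0
        theta = 180.0 - 30.0 * t + rng.normal(0, 0.5, t.size)
        d_smooth = mf.derivative(theta, smooth_window_s=0.25)
        d_raw = mf.derivative(theta, smooth_window_s=0.0)
        rmse = lambda d: np.sqrt(np.mean((d[100:-100] + 30.0) ** 2))
        assert rmse(d_smooth) < rmse(d_raw)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            mf.derivative(np.zeros(10), smooth_window_s=1.0)


class TestStaticDetector:
    def test_static_window_detected(self, rng):
        assert mf.is_static(static_window(DOWN, noise=0.01, rng=rng))

    def test_moving_window_rejected(self):
        t = np.linspace(0, 1, 160)
        w = np.column_stack([np.sin(6 * t), np.zeros_like(t), -np.ones_like(t)])
        assert not mf.is_static(w)


class TestPlacement:
    REFS = np.array([
        [0, 0, -1],   # standing
        [0, -1, 0],   # supine-equivalent
        [1, 0, 0],    # lateral left
        [-1, 0, 0],   # lateral right
    ], dtype=float)

    def test_correct_mounting_passes(self, rng):
        windows = {s: self.REFS + rng.normal(0, 0.02, self.REFS.shape)
                   for s in range(1, 6)}
        res = mf.verify_placement(windows, self.REFS)
        assert all(r.passed for r in res.values())
        for r in res.values():
            np.testing.assert_array_equal(r.suspected_mounting, np.eye(3))

    def test_flipped_sensor_flagged_with_flip_identified(self, rng):
        flip_x = np.diag([1.0, -1.0, -1.0])  # 180° about X
        windows = {1: self.REFS + rng.normal(0, 0.01, self.REFS.shape),
                   2: self.REFS @ flip_x.T}
        res = mf.verify_placement(windows, self.REFS)
        assert res[1].passed
        assert not res[2].passed
        # correcting with the suspected permutation must fix the data
        corrected = (self.REFS @ flip_x.T) @ res[2].suspected_mounting.T
        np.testing.assert_allclose(corrected, self.REFS, atol=1e-9)
        assert "mis-mounting" in res[2].description

    def test_boundary_tilt_decision_is_deterministic(self):
        tol = 25.0
        tilt = Rotation.from_euler("y", tol - 0.2, degrees=True).as_matrix()
        just_inside = {1: self.REFS @ tilt.T}
        tilt2 = Rotation.from_euler("y", tol + 0.2, degrees=True).as_matrix()
        just_outside = {1: self.REFS @ tilt2.T}
        assert mf.verify_placement(just_inside, self.REFS, tol)[1].passed
        assert not mf.verify_placement(just_outside, self.REFS, tol)[1].passed

    def test_missing_posture_rejected(self):
        with pytest.raises(ValueError, match="four"):
            mf.verify_placement({1: self.REFS[:3]}, self.REFS)
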