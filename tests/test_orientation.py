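"""Quaternion algebra, complementary filter, and joint-angle extraction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitcoord.imu_io import GRAVITY, ImuRecording
from gaitcoord.orientation import (
    WORLD_MAG,
    WORLD_UP,
    OrientationSeries,
    complementary_fuse,
    compute_joint_angles,
    qconj,
    qmul,
    qrotate,
    quat_from_rotvec,
    relative_orientation,
    rotvec_from_quat,
    to_euler_zyx,
)

FS = 200.0


def _sf(q):  # scalar-first -> scipy scalar-last
    q = np.asarray(q)
    return np.concatenate([q[..., 1:], q[..., :1]], axis=-1)


def _random_quats(n, seed):
    r = Rotation.random(n, rng=np.random.default_rng(seed))
    q = r.as_quat()
    return np.concatenate([q[:, 3:], q[:, :3]], axis=1)  # to scalar-first


def _static_recording(n=400, quat=None):
    """Noise-free recording of a static sensor with the given orientation."""
    t = np.arange(n) / FS
    q = np.array([1.0, 0, 0, 0]) if quat is None else np.asarray(quat, dtype=float)
    accel = np.tile(qrotate(qconj(q), GRAVITY * WORLD_UP), (n, 1))
    mag = np.tile(qrotate(qconj(q), WORLD_MAG), (n, 1))
    return ImuRecording("pelvis", FS, t, accel, np.zeros((n, 3)), mag)


class TestQuaternionAlgebra:
    def test_multiply_matches_rotation_composition(self):
        """Hand-written Hamilton product vs scipy rotation composition."""
        qa, qb = _random_quats(50, 1), _random_quats(50, 2)
        ours = qmul(qa, qb)
        theirs = (Rotation.from_quat(_sf(qa)) * Rotation.from_quat(_sf(qb))).as_quat()
        for o, s in zip(ours, theirs):
            expect = np.array([s[3], s[0], s[1], s[2]])
            assert np.allclose(o, expect) or np.allclose(o, -expect)

    def test_rotvec_round_trip(self, rng):
        rv = rng.normal(0, 1.0, (40, 3))
        np.testing.assert_allclose(rotvec_from_quat(quat_from_rotvec(rv)), rv, atol=1e-12)

    def test_rotate_matches_scipy(self):
        q = _random_quats(20, 4)
        v = np.random.default_rng(5).normal(size=(20, 3))
        np.testing.assert_allclose(
            qrotate(q, v), Rotation.from_quat(_sf(q)).apply(v), atol=1e-12
        )


class TestComplementaryFuse:
    def test_static_sensor_holds_identity(self):
        rec = _static_recording()
        out = complementary_fuse(rec)
        # tilt angle of every estimate relative to identity
        ang = 2 * np.degrees(np.arccos(np.clip(np.abs(out.quat[:, 0]), -1, 1)))
        assert np.max(ang) < 1e-6

    def test_constant_vertical_rotation_rate_recovered(self):
        """Sensor spinning at 90 deg/s about world vertical; rate recovered <1%."""
        n = int(3 * FS)
        t = np.arange(n) / FS
        rate = np.deg2rad(90.0)
        angles = rate * t
        quats = np.column_stack(
            [np.cos(angles / 2), np.zeros(n), np.sin(angles / 2), np.zeros(n)]
        )  # rotation about world Y (vertical)
        accel = qrotate(qconj(quats), np.tile(GRAVITY * WORLD_UP, (n, 1)))
        mag = qrotate(qconj(quats), np.tile(WORLD_MAG, (n, 1)))
        gyro = np.tile([0.0, rate, 0.0], (n, 1))  # axis fixed in both frames
        rec = ImuRecording("pelvis", FS, t, accel, gyro, mag)
        out = complementary_fuse(rec)
        # rate from the relative rotation across a 1 s window (avoids the
        # gimbal ambiguity a vertical rotation creates for Euler angles)
        i0, i1 = int(1 * FS), int(2 * FS)
        rel = qmul(qconj(out.quat[i0]), out.quat[i1])
        measured = np.degrees(np.linalg.norm(rotvec_from_quat(rel))) / ((i1 - i0) / FS)
        assert measured == pytest.approx(90.0, rel=0.01)

    def test_gain_zero_is_pure_gyro_integration(self, rng):
        """gain=0 must match a brute-force scipy quaternion integration oracle."""
        n = 200
        t = np.arange(n) / FS
        gyro = rng.normal(0, 1.0, (n, 3))
        rec = ImuRecording(
            "pelvis", FS, t, np.tile(GRAVITY * WORLD_UP, (n, 1)), gyro, np.tile(WORLD_MAG, (n, 1))
        )
        out = complementary_fuse(rec, gain=0.0)
        # oracle: independent integration with scipy Rotation objects
        r = Rotation.identity()
        oracle = [r.as_quat()]
        for i in range(1, n):
            w = 0.5 * (gyro[i - 1] + gyro[i]) / FS
            r = r * Rotation.from_rotvec(w)
            oracle.append(r.as_quat())
        oracle = np.asarray(oracle)
        for q_est, q_ref in zip(out.quat, oracle):
            ref = np.array([q_ref[3], q_ref[0], q_ref[1], q_ref[2]])
            err = min(np.abs(q_est - ref).max(), np.abs(q_est + ref).max())
            assert err < 1e-6

    def test_norm_preserved(self, rng):
        n = 300
        gyro = rng.normal(0, 2.0, (n, 3))
        rec = ImuRecording(
            "pelvis", FS, np.arange(n) / FS,
            np.tile(GRAVITY * WORLD_UP, (n, 1)), gyro, np.tile(WORLD_MAG, (n, 1)),
        )
        out = complementary_fuse(rec)
        np.testing.assert_allclose(np.linalg.norm(out.quat, axis=1), 1.0, atol=1e-9)


class TestRelativeOrientation:
    def test_self_relative_is_identity(self):
        q = _random_quats(30, 6)
        s = OrientationSeries(np.arange(30) / FS, q)
        rel = relative_orientation(s, s)
        assert np.allclose(np.abs(rel.quat[:, 0]), 1.0, atol=1e-12)

    def test_algebraic_round_trip(self):
        """proximal * relative recovers distal for random orientation pairs."""
        qp, qd = _random_quats(30, 7), _random_quats(30, 8)
        tp = np.arange(30) / FS
        rel = relative_orientation(OrientationSeries(tp, qp), OrientationSeries(tp, qd))
        recovered = qmul(qp, rel.quat)
        err = np.minimum(
            np.abs(recovered - qd).max(axis=1), np.abs(recovered + qd).max(axis=1)
        )
        assert err.max() < 1e-12

    def test_length_mismatch_rejected(self):
        a = OrientationSeries(np.arange(5) / FS, _random_quats(5, 9))
        b = OrientationSeries(np.arange(6) / FS, _random_quats(6, 9))
        with pytest.raises(ValueError, match="mismatch"):
            relative_orientation(a, b)


class TestEulerZyx:
    def test_identity_and_axis_aligned(self):
        t = np.zeros(1)
        ident = OrientationSeries(t, np.array([[1.0, 0, 0, 0]]))
        np.testing.assert_allclose(to_euler_zyx(ident), 0.0, atol=1e-12)
        q90 = np.array([[np.cos(np.pi / 4), 0, 0, np.sin(np.pi / 4)]])
        ang = to_euler_zyx(OrientationSeries(t, q90))
        np.testing.assert_allclose(ang[0], [90.0, 0.0, 0.0], atol=1e-9)

    def test_recompose_round_trip(self):
        q = _random_quats(50, 11)
        s = OrientationSeries(np.arange(50) / FS, q)
        ang = to_euler_zyx(s, unwrap=False)
        back = Rotation.from_euler("ZYX", ang, degrees=True).as_quat()
        for qi, bi in zip(s.quat, back):
            ref = np.array([bi[3], bi[0], bi[1], bi[2]])
            err = min(np.abs(qi - ref).max(), np.abs(qi + ref).max())
            assert err < 1e-9


class TestComputeJointAngles:
    @staticmethod
    def _series_about_z(deg, n=10):
        half = np.deg2rad(np.full(n, deg)) / 2
        q = np.column_stack([np.cos(half), np.zeros(n), np.zeros(n), np.sin(half)])
        return OrientationSeries(np.arange(n) / FS, q)

    def test_identical_sensors_give_zero_angles(self):
        s = self._series_about_z(37.0)
        out = compute_joint_angles(s, s, s)
        np.testing.assert_allclose(out.hip_deg, 0.0, atol=1e-9)
        np.testing.assert_allclose(out.knee_deg, 0.0, atol=1e-9)

    def test_thigh_flexed_30(self):
        pelvis = self._series_about_z(0.0)
        thigh = self._series_about_z(30.0)
        out = compute_joint_angles(pelvis, thigh, thigh)
        np.testing.assert_allclose(out.hip_deg, 30.0, atol=1e-9)
        np.testing.assert_allclose(out.knee_deg, 0.0, atol=1e-9)

    def test_common_world_rotation_invariance(self):
        """Rotating every sensor by one world rotation leaves joint angles unchanged."""
        rng = np.random.default_rng(13)
        n = 40
        t = np.arange(n) / FS
        series = [OrientationSeries(t, _random_quats(n, s)) for s in (21, 22, 23)]
        base = compute_joint_angles(*series)
        q_common = _random_quats(1, 99)[0]
        moved = [OrientationSeries(t, qmul(q_common, s.quat)) for s in series]
        out = compute_joint_angles(*moved)
        np.testing.assert_allclose(out.hip_deg, base.hip_deg, atol=1e-6)
        np.testing.assert_allclose(out.knee_deg, base.knee_deg, atol=1e-6)
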