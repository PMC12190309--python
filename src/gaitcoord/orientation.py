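"""Sensor-fusion orientation estimation and sagittal joint angles.

Quaternions are Hamilton, scalar-first, and encode the sensor-to-world
rotation.  The world frame is X anterior, Y vertical (up), Z medio-lateral
(to the subject's right), so sagittal-plane rotations are rotations about
Z and appear as the first angle of an intrinsic Z-Y-X Euler decomposition.

A static, level accelerometer reads specific force +g on its Y axis; the
reference magnetic field points along anterior X with a downward dip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .imu_io import ImuRecording
from .series import JointAngleSeries

__all__ = [
    "OrientationSeries",
    "WORLD_UP",
    "WORLD_MAG",
    "qmul",
    "qconj",
    "qrotate",
    "quat_from_rotvec",
    "rotvec_from_quat",
    "complementary_fuse",
    "relative_orientation",
    "to_euler_zyx",
    "sagittal_angle",
    "compute_joint_angles",
]

log = logging.getLogger(__name__)

WORLD_UP = np.array([0.0, 1.0, 0.0])
# Reference geomagnetic field in uT: anterior component plus downward dip.
WORLD_MAG = np.array([20.0, -43.0, 0.0])


# ---------------------------------------------------------------------------
# Quaternion algebra (Hamilton convention, scalar first).  Hand-written and
# vectorised; scipy's Rotation is used only for Euler decomposition and as an
# independent oracle in the tests.
# ---------------------------------------------------------------------------

def qmul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 * q2; broadcasts over leading axes."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qnormalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by quaternion(s) q (sensor->world if q is)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qv = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    return qmul(qmul(q, qv), qconj(q))[..., 1:]


def quat_from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Axis-angle (rotation vector, radians) to unit quaternion."""
    rv = np.asarray(rv, dtype=float)
    angle = np.linalg.norm(rv, axis=-1, keepdims=True)
    half = angle / 2.0
    # sin(x)/x, stable near zero
    small = angle < 1e-12
    k = np.where(small, 0.5, np.sin(half) / np.where(small, 1.0, angle))
    return np.concatenate([np.cos(half), k * rv], axis=-1)


def rotvec_from_quat(q: np.ndarray) -> np.ndarray:
    """Unit quaternion to rotation vector (radians); shortest arc."""
    q = np.asarray(q, dtype=float)
    q = np.where(q[..., :1] < 0, -q, q)
    vnorm = np.linalg.norm(q[..., 1:], axis=-1, keepdims=True)
    angle = 2.0 * np.arctan2(vnorm, q[..., :1])
    small = vnorm < 1e-12
    k = np.where(small, 2.0, angle / np.where(small, 1.0, vnorm))
    return k * q[..., 1:]


def _triad(u_s: np.ndarray, m_s: np.ndarray, mag_world: np.ndarray) -> np.ndarray:
    """Sensor->world quaternion from one 'up' and one magnetic observation."""
    def basis(up, mag):
        b1 = up / np.linalg.norm(up)
        c = np.cross(b1, mag)
        n = np.linalg.norm(c)
        if n < 1e-12:
            raise ValueError("magnetic field parallel to gravity; attitude unobservable")
        b2 = c / n
        b3 = np.cross(b1, b2)
        return np.column_stack([b1, b2, b3])

    R = basis(WORLD_UP, mag_world) @ basis(u_s, m_s).T
    q = Rotation.from_matrix(R).as_quat()  # scalar-last
    return np.array([q[3], q[0], q[1], q[2]])


@dataclass
class OrientationSeries:
    """Unit sensor-to-world quaternions on a time base.

    Hemisphere continuity is enforced on construction: consecutive
    quaternions satisfy dot(q_t, q_{t+1}) >= 0.
    """

    time: np.ndarray
    quat: np.ndarray  # (n, 4) scalar-first

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        q = np.asarray(self.quat, dtype=float)
        if q.ndim != 2 or q.shape[1] != 4 or q.shape[0] != len(self.time):
            raise ValueError("quat must have shape (n_samples, 4)")
        norms = np.linalg.norm(q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions must be unit norm")
        q = q / norms[:, None]
        # enforce hemisphere continuity
        flips = np.cumprod(np.where(np.sum(q[1:] * q[:-1], axis=1) < 0, -1.0, 1.0))
        q[1:] *= flips[:, None]
        self.quat = q

    @property
    def n_samples(self) -> int:
        return len(self.time)


def complementary_fuse(
    recording: ImuRecording,
    gain: float = 0.02,
    mag_world: np.ndarray = WORLD_MAG,
) -> OrientationSeries:
    """Estimate orientation by complementary filtering.

    Gyroscope integration carries the high-frequency attitude; each step is
    pulled a fraction ``gain`` of the way toward the accelerometer +
    magnetometer (TRIAD) attitude, which anchors the low frequencies.  The
    default gain of 0.02 corresponds to a 0.98 gyroscope weight per sample;
    ``gain=0`` is pure gyroscope dead-reckoning.  The first sample is
    initialised from accelerometer and magnetometer alone.

    Samples with a near-zero accelerometer norm contribute no correction
    (logged once per recording).
    """
    if not 0.0 <= gain < 1.0:
        raise ValueError("gain must be in [0, 1)")
    n = recording.n_samples
    dt = 1.0 / recording.fs
    quats = np.empty((n, 4))
    quats[0] = _triad(recording.accel[0], recording.mag[0], mag_world)
    q = quats[0]
    skipped = 0
    for i in range(1, n):
        # trapezoidal body rate over the step
        w = 0.5 * (recording.gyro[i - 1] + recording.gyro[i])
        q = qmul(q, quat_from_rotvec(w * dt))
        q = q / np.linalg.norm(q)
        if gain > 0.0:
            a = recording.accel[i]
            if np.linalg.norm(a) < 1e-9:
                skipped += 1
            else:
                q_am = _triad(a, recording.mag[i], mag_world)
                if np.dot(q_am, q) < 0:
                    q_am = -q_am
                # geodesic step of fraction `gain` toward the measured attitude
                delta = rotvec_from_quat(qmul(qconj(q), q_am))
                q = qmul(q, quat_from_rotvec(gain * delta))
                q = q / np.linalg.norm(q)
        quats[i] = q
    if skipped:
        log.warning(
            "%s: skipped accelerometer correction on %d zero-norm sample(s)",
            recording.placement,
            skipped,
        )
    return OrientationSeries(recording.time, quats)


def relative_orientation(proximal: OrientationSeries, distal: OrientationSeries) -> OrientationSeries:
    """Joint orientation q_joint = conj(q_proximal) * q_distal per sample."""
    if proximal.n_samples != distal.n_samples:
        raise ValueError(
            f"length mismatch: proximal {proximal.n_samples} vs distal {distal.n_samples}"
        )
    q = qmul(qconj(proximal.quat), distal.quat)
    return OrientationSeries(proximal.time, qnormalize(q))


def to_euler_zyx(joint: OrientationSeries, unwrap: bool = True) -> np.ndarray:
    """Intrinsic Z-Y-X Euler angles in degrees, shape (n, 3).

    Column 0 is the rotation about the medio-lateral Z axis (the
    sagittal-plane angle), column 1 about vertical Y, column 2 about
    anterior X.  The Z angle is unwrapped over time so it never jumps by
    +/-360 deg.  Gimbal proximity (|Y| within 1 deg of 90 deg) is logged;
    values are retained.
    """
    q = joint.quat
    r = Rotation.from_quat(np.column_stack([q[:, 1], q[:, 2], q[:, 3], q[:, 0]]))
    ang = r.as_euler("ZYX", degrees=True)
    if np.any(np.abs(np.abs(ang[:, 1]) - 90.0) < 1.0):
        log.warning("gimbal proximity: |Y angle| within 1 deg of 90 deg; values retained")
    if unwrap:
        ang[:, 0] = np.rad2deg(np.unwrap(np.deg2rad(ang[:, 0])))
    return ang


def sagittal_angle(joint: OrientationSeries, sign: float = 1.0) -> np.ndarray:
    """Sagittal-plane joint angle in degrees (first angle of the Z-Y-X sequence)."""
    return sign * to_euler_zyx(joint)[:, 0]


def compute_joint_angles(
    pelvis: OrientationSeries,
    thigh: OrientationSeries,
    shank: OrientationSeries,
    calibration_window_s: float | None = None,
    hip_sign: float = 1.0,
    knee_sign: float = 1.0,
) -> JointAngleSeries:
    """Sagittal hip and knee angles from three segment orientation series.

    hip = sagittal angle of conj(pelvis) * thigh; knee = sagittal angle of
    conj(thigh) * shank.  Flexion is positive under the documented
    sensor-mounting convention; ``hip_sign``/``knee_sign`` flip it for other
    mountings.  If ``calibration_window_s`` is given, the mean angle over
    that initial window (assumed quiet standing) is subtracted from each
    joint to remove mounting offsets.
    """
    if not (pelvis.n_samples == thigh.n_samples == shank.n_samples):
        raise ValueError("pelvis, thigh and shank series must be aligned")
    hip = sagittal_angle(relative_orientation(pelvis, thigh), hip_sign)
    knee = sagittal_angle(relative_orientation(thigh, shank), knee_sign)
    if calibration_window_s is not None:
        m = pelvis.time <= pelvis.time[0] + calibration_window_s
        hip = hip - hip[m].mean()
        knee = knee - knee[m].mean()
    return JointAngleSeries(pelvis.time, hip, knee)
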