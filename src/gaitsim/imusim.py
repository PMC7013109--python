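"""Virtual IMU simulation from segment pose time series.

A body segment's trajectory is a series of global orientations (unit
quaternions, global <- segment) and joint-center origins.  A sensor rigidly
attached to the segment sits at a constant 6-DoF offset: a translation ``x``
expressed in the segment frame and a rotation ``q_phi`` built from three
angles composed intrinsically X-Y-Z.  From the sensor's pose trajectory the
gyroscope signal is obtained by numerical quaternion differentiation and the
accelerometer signal by double finite differencing of the position plus the
gravity reaction.

Accelerometer sign convention: a proof mass deflects opposite to the case
acceleration, so the reading in the global frame is ``a_g = -a + g`` with
``g = (0, 0, +9.81)`` m/s^2 (Z-up global frame); at rest a sensor therefore
reads +9.81 along the axis pointing up, and in free fall it reads zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from . import quatkin as qk

__all__ = [
    "SegmentPoseSeries",
    "SensorPose",
    "IMUSignal",
    "GRAVITY",
    "place_sensor",
    "angular_rate",
    "finite_diff",
    "sensor_acceleration",
    "simulate_imu",
    "resample",
]

#: Gravity vector in the global frame (Z up), m/s^2.
GRAVITY = np.array([0.0, 0.0, 9.81])


@dataclass
class SegmentPoseSeries:
    """Per-frame orientation + origin of one body segment at a fixed rate.

    Attributes
    ----------
    q_seg : (n, 4) array
        Unit quaternions (global <- segment), scalar-first.
    x0 : (n, 3) array
        Segment origin (joint center) in the global frame, metres.
    dt : float
        Seconds per frame (constant).
    """

    q_seg: np.ndarray
    x0: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.q_seg = np.asarray(self.q_seg, dtype=float)
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.q_seg.ndim != 2 or self.q_seg.shape[1] != 4:
            raise ValueError(f"q_seg must be (n, 4), got {self.q_seg.shape}")
        if self.x0.shape != (self.q_seg.shape[0], 3):
            raise ValueError(f"x0 must be (n, 3) matching q_seg, got {self.x0.shape}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        norms = np.linalg.norm(self.q_seg, axis=1)
        if np.any(np.abs(norms - 1.0) > qk.NORM_TOL):
            raise ValueError("segment quaternions must be unit within 1e-6")

    @property
    def n_frames(self) -> int:
        return self.q_seg.shape[0]

    @property
    def rate(self) -> float:
        return 1.0 / self.dt


@dataclass
class SensorPose:
    """Constant 6-DoF segment-to-sensor offset.

    ``x`` is the sensor position in the segment frame (metres);
    ``phi`` holds three angles (radians) composed intrinsically X-Y-Z into
    the segment-to-sensor rotation ``q_phi``.
    """

    x: np.ndarray = field(default_factory=lambda: np.zeros(3))
    phi: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).reshape(3)
        self.phi = np.asarray(self.phi, dtype=float).reshape(3)

    @property
    def z(self) -> np.ndarray:
        """Stacked 6-vector (x1, x2, x3, phi1, phi2, phi3) for optimization."""
        return np.concatenate([self.x, self.phi])

    @classmethod
    def from_z(cls, z: np.ndarray) -> "SensorPose":
        z = np.asarray(z, dtype=float).reshape(6)
        return cls(x=z[:3], phi=z[3:])

    @property
    def q_phi(self) -> np.ndarray:
        """Offset rotation from the intrinsic X-Y-Z angle composition."""
        qx = qk.from_axis_angle(np.array([1.0, 0.0, 0.0]), self.phi[0])
        qy = qk.from_axis_angle(np.array([0.0, 1.0, 0.0]), self.phi[1])
        qz = qk.from_axis_angle(np.array([0.0, 0.0, 1.0]), self.phi[2])
        return qk.qmul(qk.qmul(qx, qy), qz)


@dataclass
class IMUSignal:
    """Tri-axial gyroscope + accelerometer series in the sensor frame."""

    omega: np.ndarray  # (n, 3) rad/s
    accel: np.ndarray  # (n, 3) m/s^2
    rate: float  # Hz

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.omega.shape != self.accel.shape or self.omega.ndim != 2:
            raise ValueError("omega and accel must be (n, 3) of equal length")
        if not (np.all(np.isfinite(self.omega)) and np.all(np.isfinite(self.accel))):
            raise ValueError("IMU channels must be finite")

    @property
    def n_frames(self) -> int:
        return self.omega.shape[0]

    def channels(self) -> np.ndarray:
        """Stacked (n, 6) array: gyroscope xyz then accelerometer xyz."""
        return np.hstack([self.omega, self.accel])


def place_sensor(seg: SegmentPoseSeries, pose: SensorPose) -> tuple[np.ndarray, np.ndarray]:
    """Transform a segment trajectory to the attached sensor's trajectory.

    Returns the sensor orientation series ``q_sensor = q_seg ⊗ q_phi`` and
    the sensor position series ``x_hat = x0 + q_seg ⊗ x ⊗ q_seg*``.
    """
    q_sensor = qk.qmul(seg.q_seg, pose.q_phi)
    x_hat = seg.x0 + qk.rotate_vector(seg.q_seg, np.broadcast_to(pose.x, (seg.n_frames, 3)))
    return q_sensor, x_hat


def angular_rate(q_sensor: np.ndarray, dt: float) -> np.ndarray:
    """Gyroscope signal from consecutive orientations, sensor (body) frame.

    For each frame pair the local increment is ``dq = q_k* ⊗ q_{k+1}`` and

        omega_k = (2 / dt) * (dq_v / ||dq_v||) * atan2(||dq_v||, dq_0)

    which is the body-frame angular rate a physical gyroscope reads.  Sign
    continuity across the double cover is enforced first.  The last frame
    reuses the final pair (forward difference); a vanishing increment maps
    to omega = 0 exactly.
    """
    q = np.asarray(q_sensor, dtype=float)
    if q.ndim != 2 or q.shape[0] < 2:
        raise ValueError("need at least 2 frames of orientations")
    q = qk.enforce_sign_continuity(q)
    dq = qk.qmul(qk.qconj(q[:-1]), q[1:])
    v = dq[:, 1:]
    vnorm = np.linalg.norm(v, axis=1)
    angle = 2.0 * np.arctan2(vnorm, dq[:, 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(vnorm[:, None] > 0, v / np.where(vnorm[:, None] == 0, 1.0, vnorm[:, None]), 0.0)
    omega = axis * (angle / dt)[:, None]
    # last frame: forward difference of the final pair
    return np.vstack([omega, omega[-1]])


def finite_diff(x: np.ndarray, dt: float, order: int = 1) -> np.ndarray:
    """First or second time derivative of a sampled vector series.

    Interior frames use central differences; the first frame uses the
    one-sided forward form and the last the backward form.  The second-order
    interior form ``(x_{k+1} - 2 x_k + x_{k-1}) / dt^2`` is exact on
    quadratics.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if order == 1:
        if n < 2:
            raise ValueError("need at least 2 frames for a first derivative")
        v = np.empty_like(x)
        v[0] = (x[1] - x[0]) / dt
        if n > 2:
            v[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
        v[-1] = (x[-1] - x[-2]) / dt
        return v
    if order == 2:
        if n < 3:
            raise ValueError("need at least 3 frames for a second derivative")
        a = np.empty_like(x)
        a[0] = (x[2] - 2.0 * x[1] + x[0]) / dt**2
        a[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) / dt**2
        a[-1] = (x[-1] - 2.0 * x[-2] + x[-3]) / dt**2
        return a
    raise ValueError(f"order must be 1 or 2, got {order}")


def sensor_acceleration(
    a: np.ndarray, q_sensor: np.ndarray, g: np.ndarray | None = None
) -> np.ndarray:
    """Accelerometer reading (specific force) in the sensor frame.

    ``a`` is the kinematic acceleration of the sensor origin (second time
    derivative of position).  The proof mass reacts to the gravity *field*
    (-Z) with an apparent +Z term while motion acceleration enters
    directly, so the global-frame reading is ``a_g = a + g`` with
    ``g = (0, 0, +9.81)``; ``a_l = q_sensor* ⊗ a_g ⊗ q_sensor`` expresses
    it locally.  At rest this reads +9.81 on the up axis; in free fall
    (``a = -g``) it reads zero.  Formulations that write the motion term
    with a minus sign define ``a`` as the inertial reaction, i.e. the
    negative of the kinematic acceleration used here.
    """
    if g is None:
        g = GRAVITY
    a_g = np.asarray(a, dtype=float) + np.asarray(g, dtype=float)
    return qk.rotate_vector(qk.qconj(np.asarray(q_sensor, dtype=float)), a_g)


def simulate_imu(seg: SegmentPoseSeries, pose: SensorPose, g: np.ndarray | None = None) -> IMUSignal:
    """Full virtual-IMU chain: place sensor, differentiate, add gravity."""
    q_sensor, x_hat = place_sensor(seg, pose)
    omega = angular_rate(q_sensor, seg.dt)
    a = finite_diff(x_hat, seg.dt, order=2)
    accel = sensor_acceleration(a, q_sensor, g=g)
    return IMUSignal(omega=omega, accel=accel, rate=seg.rate)


def resample(sig: IMUSignal, target_rate: float) -> IMUSignal:
    """Cubic-spline resampling of all channels onto the target clock.

    The duration (time of the last sample) is preserved; with
    ``target_rate == sig.rate`` the signal is returned unchanged.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == sig.rate:
        return sig
    t_src = np.arange(sig.n_frames) / sig.rate
    n_out = int(np.floor(t_src[-1] * target_rate)) + 1
    t_out = np.arange(n_out) / target_rate
    omega = CubicSpline(t_src, sig.omega, axis=0)(t_out)
    accel = CubicSpline(t_src, sig.accel, axis=0)(t_out)
    return IMUSignal(omega=omega, accel=accel, rate=target_rate)
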