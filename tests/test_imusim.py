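"""Virtual IMU chain: sensor placement, differentiation, gravity model."""

import numpy as np
import pytest

from gaitsim import quatkin as qk
from gaitsim.imusim import (
    GRAVITY,
    IMUSignal,
    SegmentPoseSeries,
    SensorPose,
    angular_rate,
    finite_diff,
    place_sensor,
    resample,
    sensor_acceleration,
    simulate_imu,
)

from conftest import random_unit_quaternion


def _static_series(n=50, dt=0.008, q=None, origin=(0.0, 0.0, 1.0)):
    q = np.array([1.0, 0.0, 0.0, 0.0]) if q is None else q
    return SegmentPoseSeries(
        q_seg=np.tile(q, (n, 1)), x0=np.tile(np.asarray(origin, float), (n, 1)), dt=dt
    )


def _spin_series(omega_z=3.0, n=100, dt=0.01):
    angles = omega_z * dt * np.arange(n)
    q = np.stack([qk.from_axis_angle(np.array([0.0, 0.0, 1.0]), a) for a in angles])
    return SegmentPoseSeries(q_seg=q, x0=np.zeros((n, 3)), dt=dt)


class TestPlaceSensor:
    def test_identity_offset(self, walk_trial):
        seg = walk_trial[0]["pelvis"]
        q_s, x_hat = place_sensor(seg, SensorPose())
        assert np.allclose(q_s, seg.q_seg)
        assert np.allclose(x_hat, seg.x0)

    def test_static_translation(self):
        seg = _static_series()
        _, x_hat = place_sensor(seg, SensorPose(x=[0.1, 0.0, 0.0]))
        assert np.allclose(x_hat, seg.x0 + np.array([0.1, 0.0, 0.0]))

    def test_matrix_oracle(self, rng):
        n = 40
        q = np.stack([random_unit_quaternion(rng) for _ in range(n)])
        seg = SegmentPoseSeries(q_seg=q, x0=rng.standard_normal((n, 3)), dt=0.01)
        pose = SensorPose(x=rng.uniform(-0.05, 0.05, 3), phi=rng.uniform(0, np.pi / 2, 3))
        _, x_hat = place_sensor(seg, pose)
        R = qk.to_frame(q)
        expected = seg.x0 + np.einsum("nij,j->ni", R, pose.x)
        assert np.max(np.abs(x_hat - expected)) < 1e-9


class TestAngularRate:
    def test_constant_orientation_zero(self):
        seg = _static_series()
        omega = angular_rate(seg.q_seg, seg.dt)
        assert np.allclose(omega, 0.0)

    def test_constant_spin_about_z(self):
        seg = _spin_series(omega_z=3.0, dt=0.01)
        omega = angular_rate(seg.q_seg, seg.dt)
        assert np.allclose(omega[:-1], [0.0, 0.0, 3.0], atol=1e-9)

    def test_differential_oracle(self, rng):
        """Body-frame rate from 2 q* ⊗ q-dot (central differences) to O(dt^2)."""
        dt = 1.0 / 125.0
        t = np.arange(0, 2, dt)
        # smooth random orientation path from low-frequency rotation-vector curves
        rv = np.stack(
            [
                0.8 * np.sin(2 * np.pi * 0.7 * t + 0.3),
                0.5 * np.sin(2 * np.pi * 1.1 * t - 0.8),
                0.6 * np.sin(2 * np.pi * 0.9 * t + 1.4),
            ],
            axis=1,
        )
        q = np.empty((len(t), 4))
        for i, v in enumerate(rv):
            ang = np.linalg.norm(v)
            q[i] = qk.from_axis_angle(v / ang, ang)
        omega = angular_rate(q, dt)
        qdot = np.gradient(q, dt, axis=0)
        oracle = 2.0 * qk.qmul(qk.qconj(q), qdot)[:, 1:]
        # omega[k] is the rate over the pair (k, k+1), i.e. a midpoint
        # estimate; averaging consecutive pairs centres it on frame k
        centered = 0.5 * (omega[:-2] + omega[1:-1])
        assert np.max(np.abs(centered - oracle[1:-1])) < 1e-3

    def test_double_cover_invariance(self):
        seg = _spin_series()
        q_flipped = seg.q_seg.copy()
        q_flipped[20:40] *= -1
        assert np.allclose(angular_rate(q_flipped, seg.dt), angular_rate(seg.q_seg, seg.dt))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            angular_rate(np.array([[1.0, 0, 0, 0]]), 0.01)


class TestFiniteDiff:
    def test_constant_zero_derivatives(self):
        x = np.ones((30, 3)) * 2.5
        assert np.allclose(finite_diff(x, 0.01, order=1), 0.0)
        assert np.allclose(finite_diff(x, 0.01, order=2), 0.0)

    def test_quadratic_exact(self):
        """Central second difference is exact on x = 0.5 k t^2."""
        dt, k = 0.02, 3.7
        t = np.arange(40) * dt
        x = (0.5 * k * t**2)[:, None] * np.array([1.0, -2.0, 0.5])
        a = finite_diff(x, dt, order=2)
        assert np.allclose(a, k * np.array([1.0, -2.0, 0.5]), atol=1e-8)

    def test_sinusoid_taylor_bound(self):
        """Interior error bounded by the central-difference Taylor remainder."""
        f, dt = 2.0, 1.0 / 125.0
        t = np.arange(0, 1, dt)
        x = np.sin(2 * np.pi * f * t)[:, None]
        a = finite_diff(x, dt, order=2)
        exact = -((2 * np.pi * f) ** 2) * x
        # |error| <= (dt^2 / 12) * max|x''''| = (dt^2/12) (2 pi f)^4
        bound = dt**2 / 12.0 * (2 * np.pi * f) ** 4
        assert np.max(np.abs(a[1:-1] - exact[1:-1])) < 1.1 * bound

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            finite_diff(np.zeros((2, 3)), 0.01, order=2)


class TestSensorAcceleration:
    def test_stationary_reads_gravity(self):
        seg = _static_series()
        sig = simulate_imu(seg, SensorPose())
        assert np.allclose(sig.accel, [0.0, 0.0, 9.81], atol=1e-9)
        assert np.allclose(sig.omega, 0.0)

    def test_free_fall_reads_zero(self):
        n, dt = 30, 0.01
        t = np.arange(n) * dt
        x0 = np.zeros((n, 3))
        x0[:, 2] = -0.5 * 9.81 * t**2  # a = g downward... a_g = -a + g = 0
        q = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
        a = finite_diff(x0, dt, order=2)
        a_l = sensor_acceleration(a, q)
        assert np.allclose(a_l[1:-1], 0.0, atol=1e-6)

    def test_flipped_sensor_reads_negative_gravity(self):
        q_flip = qk.from_axis_angle(np.array([1.0, 0.0, 0.0]), np.pi)
        seg = _static_series(q=q_flip)
        sig = simulate_imu(seg, SensorPose())
        assert np.allclose(sig.accel, [0.0, 0.0, -9.81], atol=1e-9)


class TestSimulateIMU:
    def test_vertical_sinusoid_analytic(self):
        """Bobbing pelvis: a_l,z = g + A w^2 sin(wt + pi) + O(dt^2)."""
        A, f, dt = 0.02, 2.0, 1.0 / 125.0
        n = 250
        t = np.arange(n) * dt
        x0 = np.zeros((n, 3))
        x0[:, 2] = 1.0 + A * np.sin(2 * np.pi * f * t)
        seg = SegmentPoseSeries(q_seg=np.tile([1.0, 0, 0, 0], (n, 1)), x0=x0, dt=dt)
        sig = simulate_imu(seg, SensorPose())
        w = 2 * np.pi * f
        expected = 9.81 + A * w**2 * np.sin(w * t + np.pi)
        bound = dt**2 / 12.0 * A * w**4 + 1e-9
        assert np.max(np.abs(sig.accel[1:-1, 2] - expected[1:-1])) < 1.1 * bound
        assert np.allclose(sig.omega, 0.0, atol=1e-12)

    def test_pose_changes_signal(self, walk_trial):
        """Distinct sensor poses yield distinct signals (augmentation premise)."""
        seg = walk_trial[0]["thigh_r"]
        sig_a = simulate_imu(seg, SensorPose(x=[0.02, 0, 0], phi=[0.1, 0.2, 0.3]))
        sig_b = simulate_imu(seg, SensorPose(x=[-0.03, 0.01, 0], phi=[0.8, 0.1, 1.0]))
        assert not np.allclose(sig_a.channels(), sig_b.channels())

    def test_global_frame_covariance(self, walk_trial, rng):
        """Rigidly rotating the world leaves local omega and a_l unchanged."""
        seg = walk_trial[0]["shank_l"]
        pose = SensorPose(x=[0.01, 0.02, -0.01], phi=[0.3, 0.4, 0.5])
        q_world = random_unit_quaternion(rng)
        rotated = SegmentPoseSeries(
            q_seg=qk.qmul(q_world, seg.q_seg),
            x0=qk.rotate_vector(np.tile(q_world, (seg.n_frames, 1)), seg.x0),
            dt=seg.dt,
        )
        g_rot = qk.rotate_vector(q_world, GRAVITY)
        sig = simulate_imu(seg, pose)
        sig_rot = simulate_imu(rotated, pose, g=g_rot)
        assert np.max(np.abs(sig.omega - sig_rot.omega)) < 1e-9
        assert np.max(np.abs(sig.accel - sig_rot.accel)) < 1e-7

    def test_translation_invariance(self, walk_trial):
        seg = walk_trial[0]["pelvis"]
        shifted = SegmentPoseSeries(seg.q_seg, seg.x0 + np.array([5.0, -3.0, 2.0]), seg.dt)
        sig = simulate_imu(seg, SensorPose())
        sig_shift = simulate_imu(shifted, SensorPose())
        assert np.allclose(sig.accel, sig_shift.accel, atol=1e-9)


class TestResample:
    def test_same_rate_unchanged(self):
        sig = IMUSignal(omega=np.zeros((50, 3)), accel=np.ones((50, 3)), rate=125.0)
        assert resample(sig, 125.0) is sig

    def test_sinusoid_amplitude_preserved(self):
        """Pointwise error against the analytic sinusoid < 0.1% of amplitude."""
        t = np.arange(0, 4, 1 / 125.0)
        x = np.sin(2 * np.pi * 2.0 * t)
        sig = IMUSignal(omega=np.tile(x[:, None], 3), accel=np.tile(x[:, None], 3), rate=125.0)
        out = resample(sig, 100.0)
        t_out = np.arange(out.n_frames) / 100.0
        exact = np.sin(2 * np.pi * 2.0 * t_out)
        assert np.max(np.abs(out.omega[2:-2, 0] - exact[2:-2])) < 1e-3

    def test_round_trip_band_limited(self):
        t = np.arange(0, 4, 1 / 125.0)
        x = np.sin(2 * np.pi * 1.3 * t) + 0.5 * np.sin(2 * np.pi * 3.1 * t + 0.7)
        sig = IMUSignal(omega=np.tile(x[:, None], 3), accel=np.tile(x[:, None], 3), rate=125.0)
        back = resample(resample(sig, 100.0), 125.0)
        n = back.n_frames
        assert np.max(np.abs(back.omega[:n, 0] - x[:n])) < 0.01 * np.ptp(x) / 2
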