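"""Constrained sensor-to-segment pose fitting.

The unknown is the constant 6-DoF offset z = (x1, x2, x3, phi1, phi2, phi3)
between a body segment and its worn sensor.  It is found by minimizing the
summed squared difference between the measured IMU channels and the virtual
IMU simulated from the segment poses at z,

    Theta(z) = sum_t ||omega_m - omega_s(z)||^2 + sum_t ||a_m - a_s(z)||^2,

subject to |x_i| <= 50 mm and 0 <= phi_i <= pi/2.  Angular-rate terms carry
units (rad/s)^2 and acceleration terms (m/s^2)^2; they are summed unweighted
by default, with an optional acceleration weight exposed.  The bounded
local minimization uses L-BFGS-B with numerical gradients and a small
multi-start over seeded interior points to dodge local minima.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .imusim import IMUSignal, SegmentPoseSeries, SensorPose, simulate_imu

__all__ = ["PoseFitResult", "pose_objective", "fit_sensor_pose", "best_pose_per_subject", "DEFAULT_BOUNDS"]

logger = logging.getLogger(__name__)

#: (lower, upper) per component of z: +-50 mm translations, [0, pi/2] angles.
DEFAULT_BOUNDS: tuple[np.ndarray, np.ndarray] = (
    np.array([-0.05, -0.05, -0.05, 0.0, 0.0, 0.0]),
    np.array([0.05, 0.05, 0.05, np.pi / 2, np.pi / 2, np.pi / 2]),
)


@dataclass
class PoseFitResult:
    pose: SensorPose
    objective_value: float
    converged: bool
    n_iterations: int
    per_trial_rmse: dict = field(default_factory=dict)
    start_seeds: list = field(default_factory=list)


def pose_objective(
    z: np.ndarray | SensorPose,
    measured: IMUSignal,
    seg: SegmentPoseSeries,
    accel_weight: float = 1.0,
) -> float:
    """Theta(z): summed squared gyro + accelerometer residuals."""
    pose = z if isinstance(z, SensorPose) else SensorPose.from_z(np.asarray(z))
    sim = simulate_imu(seg, pose)
    if sim.n_frames != measured.n_frames:
        raise ValueError(
            f"measured ({measured.n_frames}) and simulated ({sim.n_frames}) "
            "series must be time-aligned and equal length"
        )
    d_omega = measured.omega - sim.omega
    d_accel = measured.accel - sim.accel
    return float(np.sum(d_omega**2) + accel_weight * np.sum(d_accel**2))


def signal_rmse(a: IMUSignal, b: IMUSignal) -> float:
    """RMSE over all six channels of two aligned IMU signals."""
    return float(np.sqrt(np.mean((a.channels() - b.channels()) ** 2)))


def fit_sensor_pose(
    measured: IMUSignal,
    seg: SegmentPoseSeries,
    init: SensorPose | None = None,
    bounds: tuple[np.ndarray, np.ndarray] = DEFAULT_BOUNDS,
    n_starts: int = 5,
    seed: int = 0,
    accel_weight: float = 1.0,
) -> PoseFitResult:
    """Bounded local minimization of the pose objective with multi-start.

    ``init`` defaults to the box centre; ``n_starts - 1`` further starts are
    drawn uniformly inside the bounds from ``seed``.  The best local optimum
    wins; the result never lies outside the bounds and its objective never
    exceeds the objective at ``init``.  On motionless input the pose is
    unidentifiable (only the gravity direction constrains it); the fit then
    warns and reports non-convergence.
    """
    lo, hi = bounds
    if init is None:
        init = SensorPose.from_z((lo + hi) / 2.0)
    z0 = init.z
    if np.any(z0 < lo - 1e-12) or np.any(z0 > hi + 1e-12):
        raise ValueError("init must lie within bounds")

    # per-channel variation over time; a static sensor shows none even
    # though gravity makes the accelerometer channels differ from another
    motion = float(np.std(measured.omega, axis=0).max()) + float(
        np.std(measured.accel, axis=0).max()
    )
    degenerate = motion < 1e-8

    def fun(z: np.ndarray) -> float:
        val = pose_objective(z, measured, seg, accel_weight=accel_weight)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite objective at z={z}")
        return val

    rng = np.random.default_rng(seed)
    starts = [z0] + [rng.uniform(lo, hi) for _ in range(max(n_starts - 1, 0))]
    best = None
    n_iter_total = 0
    for z_start in starts:
        res = minimize(
            fun,
            z_start,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 200},
        )
        n_iter_total += int(res.nit)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    z_hat = np.clip(best.x, lo, hi)
    f_init = fun(z0)
    if best.fun > f_init:  # multi-start never worse than the given init
        z_hat, best_fun = z0, f_init
    else:
        best_fun = float(best.fun)
    if degenerate:
        warnings.warn(
            "input has no motion; sensor pose is unidentifiable beyond the "
            "gravity direction — reporting non-convergence",
            stacklevel=2,
        )
    return PoseFitResult(
        pose=SensorPose.from_z(z_hat),
        objective_value=best_fun,
        converged=bool(best.success) and not degenerate,
        n_iterations=n_iter_total,
        start_seeds=[seed],
    )


def best_pose_per_subject(
    fits: list[PoseFitResult],
    trials: list[tuple[IMUSignal, SegmentPoseSeries]],
) -> SensorPose:
    """Select the subject's single pose by cross-trial re-simulation RMSE.

    A sensor is worn in one fixed spot for a whole session, so one pose must
    explain all of a subject's trials.  Each fitted candidate is re-simulated
    on every trial; the candidate with the lowest mean RMSE wins.
    """
    if not fits:
        raise ValueError("need at least one trial fit")
    if len(fits) == 1:
        return fits[0].pose
    best_pose, best_rmse = None, np.inf
    for fit in fits:
        rmses = [
            signal_rmse(measured, simulate_imu(seg, fit.pose))
            for measured, seg in trials
        ]
        mean_rmse = float(np.mean(rmses))
        fit.per_trial_rmse = {i: r for i, r in enumerate(rmses)}
        if mean_rmse < best_rmse:
            best_pose, best_rmse = fit.pose, mean_rmse
    assert best_pose is not None
    return best_pose
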