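"""End-to-end orchestration: synthesize, simulate, preprocess, train, score.

The canonical flow mirrors the study design:

1. a cohort of synthetic subjects walks at the study speeds;
2. each subject "wears" five sensors (pelvis, both thighs, both shanks) at
   fixed per-subject offsets — virtual IMU signals simulated from
   soft-tissue-perturbed segment poses play the role of *measured* data,
   while signals simulated from clean poses at freshly sampled offsets play
   the role of *simulated* (augmentation) data;
3. trials are segmented into gait cycles (kinematics) or stance phases
   (kinetics), time-normalized to 101 frames and flattened;
4. a feed-forward network is trained under leave-one-subject-out
   cross-validation in a measured-only or combined scenario;
5. held-out predictions are scored per channel (r, RMSE, nRMSE).
"""

from __future__ import annotations

import logging
import time

import numpy as np

from . import metrics as mx
from .gait_synth import (
    SEGMENTS,
    GroundTruthCurves,
    SubjectProfile,
    TrialSpec,
    generate_subject,
    sample_sensor_pose,
)
from .imusim import SegmentPoseSeries, SensorPose, simulate_imu
from .nnpipe import (
    ModelConfig,
    NormalizedSample,
    make_splits,
    run_scenario,
)
from .preprocess import (
    butterworth_zero_lag,
    segment_cycles,
    segment_stance,
    time_normalize,
    normalize_moments,
)

__all__ = ["default_config", "make_cohort", "build_samples", "run_pipeline"]

logger = logging.getLogger(__name__)


def default_config() -> dict:
    """Desk-scale demo defaults; full-scale values live in ModelConfig."""
    return {
        "seed": 0,
        "n_subjects": 3,
        "speeds": [1.1, 1.4, 1.7],
        "n_strides": 4,
        "rate": 125.0,
        "soft_tissue_amplitude": 0.5,
        "n_aug_poses": 1,
        "tasks": ["kinematic"],
        "scenarios": ["combined"],
        "scale": 0.02,
        "split": "loocv",
    }


def make_cohort(n_subjects: int, seed: int = 0) -> list[SubjectProfile]:
    """Sample anthropometrics near the study cohort (1.77±0.07 m, 72±13 kg)."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_subjects):
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                height=float(np.clip(rng.normal(1.77, 0.07), 1.5, 2.05)),
                mass=float(np.clip(rng.normal(72.3, 12.7), 45.0, 115.0)),
                cadence_base=0.9,
                seed=int(rng.integers(2**31)),
            )
        )
    return profiles


def _normalized_inputs(
    imu_by_seg: dict[str, np.ndarray], start: int, end: int
) -> np.ndarray:
    """Stack 5 sensors x 6 channels over [start, end) onto 101 frames."""
    rows = [
        time_normalize(imu_by_seg[name][start:end].T) for name in SEGMENTS
    ]
    return np.vstack(rows)  # (30, 101)


def _segment_windows(
    truth: GroundTruthCurves, task: str, n_frames: int
) -> list[tuple[int, int]]:
    if task == "kinematic":
        segs = segment_cycles(truth.contact_indices)
    else:
        grf = butterworth_zero_lag(truth.vertical_grf, truth.rate)
        segs = segment_stance(grf)
    return [(s.start, s.end) for s in segs if s.end <= n_frames and s.end - s.start >= 5]


def build_samples(
    profiles: list[SubjectProfile],
    task: str = "kinematic",
    speeds: list[float] = (1.4,),
    n_strides: int = 4,
    rate: float = 125.0,
    soft_tissue_amplitude: float = 0.5,
    n_aug_poses: int = 1,
    seed: int = 0,
) -> list[NormalizedSample]:
    """Cohort dataset of measured-role and simulated-role samples.

    Measured-role samples come from soft-tissue-noisy poses seen through
    each subject's fixed worn-sensor offsets; simulated-role samples come
    from clean poses seen through ``n_aug_poses`` freshly sampled offsets
    per trial (the augmentation that widens sensor-placement coverage).
    Kinematic targets are joint angles (deg) over full cycles; kinetic
    targets are mass-and-height-normalized moments over stance phases.
    """
    if task not in ("kinematic", "kinetic"):
        raise ValueError(f"task must be kinematic|kinetic, got {task!r}")
    samples: list[NormalizedSample] = []
    rng = np.random.default_rng(seed)
    for profile in profiles:
        worn = {
            name: sample_sensor_pose(int(rng.integers(2**31)))
            for name in SEGMENTS
        }
        for speed in speeds:
            noisy_series, truth = generate_subject(
                profile,
                TrialSpec(
                    speed=speed,
                    n_strides=n_strides,
                    rate=rate,
                    soft_tissue_amplitude=soft_tissue_amplitude,
                ),
            )
            clean_series, _ = generate_subject(
                profile,
                TrialSpec(speed=speed, n_strides=n_strides, rate=rate,
                          soft_tissue_amplitude=0.0),
            )
            if task == "kinematic":
                target_curves = truth.joint_angles
            else:
                target_curves = normalize_moments(
                    truth.joint_moments, profile.height, profile.mass
                )
            n_frames = truth.joint_angles.shape[1]
            windows = _segment_windows(truth, task, n_frames)

            def emit(series: dict[str, SegmentPoseSeries], poses: dict[str, SensorPose], source: str) -> None:
                imu_by_seg = {
                    name: simulate_imu(series[name], poses[name]).channels()
                    for name in SEGMENTS
                }
                for start, end in windows:
                    samples.append(
                        NormalizedSample(
                            subject_id=profile.subject_id,
                            inputs=_normalized_inputs(imu_by_seg, start, end),
                            targets=time_normalize(target_curves[:, start:end]),
                            source=source,
                        )
                    )

            emit(noisy_series, worn, "measured")
            for _ in range(n_aug_poses):
                aug = {
                    name: sample_sensor_pose(int(rng.integers(2**31)))
                    for name in SEGMENTS
                }
                emit(clean_series, aug, "simulated")
    return samples


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the configured stages and aggregate held-out metrics.

    Returns a report with per-task, per-scenario mean r / RMSE / nRMSE and
    per-channel values, plus the seeds and config used.  Any stage failure
    propagates after logging the stage name.
    """
    cfg = default_config()
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    seed = int(cfg["seed"])
    report: dict = {"config": dict(cfg), "tasks": {}}
    t_start = time.perf_counter()
    profiles = make_cohort(cfg["n_subjects"], seed=seed)
    logger.info("stage=synth subjects=%d seed=%d", len(profiles), seed)
    for task in cfg["tasks"]:
        samples = build_samples(
            profiles,
            task=task,
            speeds=cfg["speeds"],
            n_strides=cfg["n_strides"],
            rate=cfg["rate"],
            soft_tissue_amplitude=cfg["soft_tissue_amplitude"],
            n_aug_poses=cfg["n_aug_poses"],
            seed=seed + 1,
        )
        logger.info("stage=build_samples task=%s n_samples=%d", task, len(samples))
        plan = make_splits([p.subject_id for p in profiles], cfg["split"], seed=seed)
        model_cfg = ModelConfig(task=task, scale=cfg["scale"])
        task_report: dict = {}
        for scenario in cfg["scenarios"]:
            t0 = time.perf_counter()
            preds = run_scenario(samples, scenario, plan, model_cfg, seed=seed + 2)
            per_channel_r, per_channel_rmse, per_channel_nrmse = [], [], []
            for subject, pairs in preds.items():
                for pred_curves, truth_curves in pairs:
                    comp = mx.compare_curves(truth_curves, pred_curves)
                    per_channel_r.append(comp.r)
                    per_channel_rmse.append(comp.rmse)
                    per_channel_nrmse.append(comp.nrmse)
            r = np.nanmean(np.stack(per_channel_r), axis=0)
            e = np.nanmean(np.stack(per_channel_rmse), axis=0)
            ne = np.nanmean(np.stack(per_channel_nrmse), axis=0)
            task_report[scenario] = {
                "n_models": len(plan.folds),
                "n_samples": len(samples),
                "mean_r": float(np.nanmean(r)),
                "mean_rmse": float(np.nanmean(e)),
                "mean_nrmse": float(np.nanmean(ne)),
                "per_channel_r": r.tolist(),
                "per_channel_rmse": e.tolist(),
                "wall_time_s": time.perf_counter() - t0,
            }
            logger.info(
                "stage=train task=%s scenario=%s mean_r=%.3f wall=%.1fs",
                task, scenario, task_report[scenario]["mean_r"],
                task_report[scenario]["wall_time_s"],
            )
        report["tasks"][task] = task_report
    report["wall_time_s"] = time.perf_counter() - t_start
    return report
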