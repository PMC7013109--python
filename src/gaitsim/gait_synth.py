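"""Seeded synthetic multi-subject gait generator.

Produces segment pose trajectories (pelvis, both thighs, both shanks),
smooth periodic joint-angle and joint-moment ground truth, and a vertical
ground-reaction-force channel for walking at the five study speeds
(0.8-2.0 m/s).  The generator exists so every downstream stage — virtual-IMU
simulation, sensor-pose fitting, synchronization, preprocessing and network
training — is testable end to end without external motion-capture data.  It
makes no claim of biomechanical fidelity: curves are sums of 2-4 harmonics
per channel with gait-like shapes and speed-dependent amplitudes, driven
through a documented forward-kinematic chain.

Conventions
-----------
Global frame: X forward (walking direction), Y left, Z up.  Joint rotations
compose intrinsically sagittal (about Y), frontal (about X), transverse
(about Z).  Segment lengths are fixed fractions of subject height (thigh
0.245 H, shank 0.246 H, pelvis width 0.13 H — standard anthropometric
ratios).  The left leg runs half a stride out of phase with the right.

Stride model: ``stride_length = 0.83 * speed ** 0.42`` metres (an empirical
power-law shape; any smooth monotone model would do), so the stride
duration is ``stride_length / speed`` seconds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from . import quatkin as qk
from .imusim import SegmentPoseSeries, SensorPose

__all__ = [
    "SubjectProfile",
    "TrialSpec",
    "GroundTruthCurves",
    "ANGLE_CHANNELS",
    "SEGMENTS",
    "ALLOWED_SPEEDS",
    "generate_subject",
    "generate_static",
    "add_soft_tissue_noise",
    "sample_sensor_pose",
    "stride_length_model",
]

ALLOWED_SPEEDS = (0.8, 1.1, 1.4, 1.7, 2.0)
ALLOWED_RATES = (100.0, 125.0)
SEGMENTS = ("pelvis", "thigh_r", "thigh_l", "shank_r", "shank_l")

#: 18 ground-truth channels: side x joint x anatomical plane.
ANGLE_CHANNELS = tuple(
    f"{side}_{joint}_{plane}"
    for side in ("r", "l")
    for joint in ("hip", "knee", "ankle")
    for plane in ("sagittal", "frontal", "transverse")
)

GRAVITY_MAG = 9.81
STANCE_FRACTION = 0.6

# Harmonic templates per (joint, plane): offset [deg] and (amplitude [deg],
# harmonic order, phase [rad]) triples over the stride cycle.  Version 1 —
# pinned so tests can rely on exact values.
TEMPLATE_VERSION = 1
_ANGLE_TEMPLATES: dict[tuple[str, str], tuple[float, list[tuple[float, int, float]]]] = {
    ("hip", "sagittal"): (8.0, [(27.0, 1, 0.35), (5.0, 2, 1.1)]),
    ("hip", "frontal"): (1.0, [(5.0, 1, -0.6), (2.5, 2, 0.8)]),
    ("hip", "transverse"): (0.0, [(4.0, 1, 1.9), (1.5, 2, -0.4)]),
    ("knee", "sagittal"): (22.0, [(-18.0, 1, 0.25), (14.0, 2, 0.55), (3.5, 3, 0.0)]),
    ("knee", "frontal"): (1.5, [(2.5, 1, 0.9), (1.0, 2, -1.2)]),
    ("knee", "transverse"): (2.0, [(4.0, 1, -0.8), (1.5, 3, 0.4)]),
    ("ankle", "sagittal"): (-2.0, [(7.5, 1, 2.1), (6.0, 2, -0.7), (2.0, 3, 1.2)]),
    ("ankle", "frontal"): (0.5, [(3.0, 1, 0.3), (1.0, 2, 1.5)]),
    ("ankle", "transverse"): (-1.0, [(2.5, 1, -1.6), (1.0, 2, 0.2)]),
}
# Moment templates: offset and harmonics in N·m per (kg·m) of body mass x
# height; multiplied by mass*height and the speed gain at generation time.
_MOMENT_TEMPLATES: dict[tuple[str, str], tuple[float, list[tuple[float, int, float]]]] = {
    ("hip", "sagittal"): (0.05, [(0.55, 1, 0.1), (0.18, 2, 1.3)]),
    ("hip", "frontal"): (0.25, [(0.30, 1, -0.9), (0.12, 2, 0.4)]),
    ("hip", "transverse"): (0.0, [(0.08, 1, 1.4), (0.04, 2, -0.6)]),
    ("knee", "sagittal"): (0.08, [(0.28, 1, 2.0), (0.20, 2, -0.3), (0.06, 3, 0.9)]),
    ("knee", "frontal"): (0.12, [(0.16, 1, -0.2), (0.07, 2, 1.0)]),
    ("knee", "transverse"): (0.0, [(0.06, 1, 0.7), (0.03, 2, -1.1)]),
    ("ankle", "sagittal"): (0.30, [(0.45, 1, -1.3), (0.22, 2, 0.6), (0.05, 3, -0.2)]),
    ("ankle", "frontal"): (0.03, [(0.05, 1, 0.5), (0.02, 2, -0.8)]),
    ("ankle", "transverse"): (0.0, [(0.04, 1, -0.4), (0.02, 2, 1.2)]),
}

# Soft-tissue artifact constants: perturbation RMS per unit amplitude x
# speed, band-limited to SOFT_TISSUE_BAND.
SOFT_TISSUE_BAND = (8.0, 15.0)  # Hz
POS_NOISE_RMS = 0.003  # m per (amplitude * m/s)
ROT_NOISE_RMS = 0.010  # rad per (amplitude * m/s)


@dataclass
class SubjectProfile:
    """Anthropometrics and identity of one synthetic subject."""

    subject_id: str
    height: float  # m
    mass: float  # kg
    cadence_base: float = 0.9  # strides/s at 1.4 m/s (scales with speed)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1.4 <= self.height <= 2.1:
            raise ValueError(f"height {self.height} m outside [1.4, 2.1]")
        if not 40.0 <= self.mass <= 120.0:
            raise ValueError(f"mass {self.mass} kg outside [40, 120]")


@dataclass
class TrialSpec:
    """One walking trial: speed, stride count, sampling rate, noise gain."""

    speed: float = 1.4  # m/s, one of ALLOWED_SPEEDS
    n_strides: int = 5
    rate: float = 125.0  # Hz
    soft_tissue_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not any(abs(self.speed - s) < 1e-9 for s in ALLOWED_SPEEDS):
            raise ValueError(
                f"speed {self.speed} m/s unsupported; allowed: {ALLOWED_SPEEDS}"
            )
        if self.rate not in ALLOWED_RATES:
            raise ValueError(f"rate {self.rate} Hz unsupported; allowed: {ALLOWED_RATES}")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.soft_tissue_amplitude < 0:
            raise ValueError("soft_tissue_amplitude must be >= 0")


@dataclass
class GroundTruthCurves:
    """Per-trial ground truth: 18 angle + 18 moment channels, GRF, events."""

    joint_angles: np.ndarray  # (18, n) degrees
    joint_moments: np.ndarray  # (18, n) N·m (un-normalized)
    vertical_grf: np.ndarray  # (n,) N, right foot's plate
    contact_indices: np.ndarray  # right initial-contact frame per stride
    rate: float
    channel_names: tuple[str, ...] = ANGLE_CHANNELS
    meta: dict = field(default_factory=dict)


def stride_length_model(speed: float) -> float:
    """Stride length in metres for a walking speed (power-law shape)."""
    return 0.83 * speed**0.42


def _eval_template(
    template: tuple[float, list[tuple[float, int, float]]],
    phase: np.ndarray,
    amp_gain: float,
    jitter: np.ndarray,
) -> np.ndarray:
    """Sum of harmonics over stride phase (cycles); jitter is per-harmonic."""
    offset, harmonics = template
    out = np.full(phase.shape, offset)
    for (amp, k, ph), j in zip(harmonics, jitter):
        out += amp * amp_gain * j * np.sin(2.0 * np.pi * k * phase + ph)
    return out


def _speed_gain(speed: float) -> float:
    """Amplitude gain: curves grow with walking speed, 1.0 at 1.4 m/s."""
    return 0.7 + 0.3 * speed / 1.4


def _joint_quat(sagittal: np.ndarray, frontal: np.ndarray, transverse: np.ndarray) -> np.ndarray:
    """Joint rotation series from plane angles (deg), intrinsic Y-X-Z."""
    n = sagittal.shape[0]
    q = np.zeros((n, 4))
    s, f, t = np.deg2rad(sagittal), np.deg2rad(frontal), np.deg2rad(transverse)
    ey, ex, ez = np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])
    for i in range(n):
        qy = qk.from_axis_angle(ey, s[i])
        qx = qk.from_axis_angle(ex, f[i])
        qz = qk.from_axis_angle(ez, t[i])
        q[i] = qk.qmul(qk.qmul(qy, qx), qz)
    return q


def _grf_profile(phase: np.ndarray, mass: float, speed: float) -> np.ndarray:
    """Right-foot plate vertical GRF over stride phase (cycles).

    Double-bump loading during stance (phase in [0, STANCE_FRACTION)),
    zero in swing; second harmonic deepens with speed.
    """
    s = np.mod(phase, 1.0) / STANCE_FRACTION  # stance-normalized time
    in_stance = s < 1.0
    bw = mass * GRAVITY_MAG
    shape = np.sin(np.pi * np.clip(s, 0.0, 1.0)) * (
        1.0 + 0.25 * (speed / 1.4) * np.sin(2.0 * np.pi * np.clip(s, 0.0, 1.0))
    )
    return np.where(in_stance, 1.15 * bw * shape, 0.0)


def generate_subject(
    profile: SubjectProfile, spec: TrialSpec
) -> tuple[dict[str, SegmentPoseSeries], GroundTruthCurves]:
    """Generate one trial: five segment pose series + ground-truth curves.

    Deterministic given ``(profile.seed, spec)``.  The kinematic chain is
    pelvis -> hip -> thigh -> knee -> shank with fixed height-scaled segment
    lengths; joint angles come from the harmonic templates with a small
    seeded per-subject amplitude jitter, so subjects differ but every curve
    stays smooth and periodic over the stride.
    """
    rng = np.random.default_rng(profile.seed)
    # per-subject multiplicative jitter on each harmonic, fixed across trials
    jitters = {
        key: 1.0 + 0.06 * rng.standard_normal(len(tpl[1]))
        for key, tpl in _ANGLE_TEMPLATES.items()
    }
    mom_jitters = {
        key: 1.0 + 0.06 * rng.standard_normal(len(tpl[1]))
        for key, tpl in _MOMENT_TEMPLATES.items()
    }

    dt = 1.0 / spec.rate
    stride_len = stride_length_model(spec.speed)
    stride_time = stride_len / spec.speed
    n = max(int(round(spec.n_strides * stride_time * spec.rate)), 3)
    t = np.arange(n) * dt
    phase_r = t / stride_time  # cycles, right leg
    phase_l = phase_r + 0.5
    gain = _speed_gain(spec.speed)

    H = profile.height
    l_thigh, l_shank, pelvis_w = 0.245 * H, 0.246 * H, 0.13 * H
    hip_height = 0.53 * H

    angles = np.empty((18, n))
    for ci, name in enumerate(ANGLE_CHANNELS):
        side, joint, plane = name.split("_")
        ph = phase_r if side == "r" else phase_l
        angles[ci] = _eval_template(_ANGLE_TEMPLATES[(joint, plane)], ph, gain, jitters[(joint, plane)])

    moments = np.empty((18, n))
    mh = profile.mass * H
    for ci, name in enumerate(ANGLE_CHANNELS):
        side, joint, plane = name.split("_")
        ph = phase_r if side == "r" else phase_l
        offset, harm = _MOMENT_TEMPLATES[(joint, plane)]
        moments[ci] = mh * _eval_template(
            (offset, harm), ph, gain, mom_jitters[(joint, plane)]
        )

    # pelvis trajectory: constant forward progression + periodic sway/bob
    f_stride = 1.0 / stride_time
    px = spec.speed * t + 0.01 * gain * np.sin(2 * np.pi * 2 * f_stride * t + 0.4)
    py = 0.02 * gain * np.sin(2 * np.pi * f_stride * t)
    pz = hip_height + 0.015 * gain * np.sin(2 * np.pi * 2 * f_stride * t + 1.1)
    pelvis_x0 = np.stack([px, py, pz], axis=1)
    # small periodic pelvis tilt/obliquity/rotation (deg)
    p_sag = 3.0 + 1.5 * gain * np.sin(2 * np.pi * 2 * f_stride * t + 0.9)
    p_fro = 2.0 * gain * np.sin(2 * np.pi * f_stride * t + 0.2)
    p_tra = 4.0 * gain * np.sin(2 * np.pi * f_stride * t - 1.0)
    q_pelvis = _joint_quat(p_sag, p_fro, p_tra)

    def chan(side: str, joint: str, plane: str) -> np.ndarray:
        return angles[ANGLE_CHANNELS.index(f"{side}_{joint}_{plane}")]

    series: dict[str, SegmentPoseSeries] = {
        "pelvis": SegmentPoseSeries(q_seg=q_pelvis, x0=pelvis_x0, dt=dt)
    }
    for side, ysign in (("r", -1.0), ("l", 1.0)):
        hip_origin = pelvis_x0 + qk.rotate_vector(
            q_pelvis, np.broadcast_to(np.array([0.0, ysign * pelvis_w / 2.0, 0.0]), (n, 3))
        )
        q_hip = _joint_quat(chan(side, "hip", "sagittal"), chan(side, "hip", "frontal"), chan(side, "hip", "transverse"))
        q_thigh = qk.qmul(q_pelvis, q_hip)
        knee_origin = hip_origin + qk.rotate_vector(
            q_thigh, np.broadcast_to(np.array([0.0, 0.0, -l_thigh]), (n, 3))
        )
        # knee flexion rotates the shank backwards relative to the thigh
        q_knee = _joint_quat(-chan(side, "knee", "sagittal"), chan(side, "knee", "frontal"), chan(side, "knee", "transverse"))
        q_shank = qk.qmul(q_thigh, q_knee)
        series[f"thigh_{side}"] = SegmentPoseSeries(q_seg=q_thigh, x0=hip_origin, dt=dt)
        series[f"shank_{side}"] = SegmentPoseSeries(q_seg=q_shank, x0=knee_origin, dt=dt)

    # right ankle height: the generator's own contact truth is its per-stride
    # minimum (foot flat at initial contact)
    ankle_r = series["shank_r"].x0 + qk.rotate_vector(
        series["shank_r"].q_seg, np.broadcast_to(np.array([0.0, 0.0, -l_shank]), (n, 3))
    )
    contacts = []
    stride_frames = stride_time * spec.rate
    for k in range(spec.n_strides):
        lo = int(round(k * stride_frames))
        hi = min(int(round((k + 1) * stride_frames)), n)
        if hi - lo >= 3:
            contacts.append(lo + int(np.argmin(ankle_r[lo:hi, 2])))
    grf = _grf_profile(phase_r, profile.mass, spec.speed)

    truth = GroundTruthCurves(
        joint_angles=angles,
        joint_moments=moments,
        vertical_grf=grf,
        contact_indices=np.asarray(contacts, dtype=int),
        rate=spec.rate,
        meta={
            "subject_id": profile.subject_id,
            "seed": profile.seed,
            "speed": spec.speed,
            "stride_time": stride_time,
            "template_version": TEMPLATE_VERSION,
        },
    )

    if spec.soft_tissue_amplitude > 0:
        noise_seed = int(np.random.default_rng(profile.seed + 10_007).integers(2**31))
        series = {
            name: add_soft_tissue_noise(s, spec.soft_tissue_amplitude, spec.speed, noise_seed + i)
            for i, (name, s) in enumerate(series.items())
        }
    return series, truth


def generate_static(
    profile: SubjectProfile, duration: float = 2.0, rate: float = 125.0
) -> tuple[dict[str, SegmentPoseSeries], GroundTruthCurves]:
    """Quiet standing: constant poses, zero angles, GRF = body weight.

    With zero joint motion the vertical GRF is exactly ``mass * 9.81`` N.
    """
    n = max(int(round(duration * rate)), 3)
    dt = 1.0 / rate
    H = profile.height
    identity = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (n, 1))
    series: dict[str, SegmentPoseSeries] = {}
    for name in SEGMENTS:
        if name == "pelvis":
            origin = np.array([0.0, 0.0, 0.53 * H])
        elif name.startswith("thigh"):
            ysign = -1.0 if name.endswith("_r") else 1.0
            origin = np.array([0.0, ysign * 0.13 * H / 2.0, 0.53 * H])
        else:
            ysign = -1.0 if name.endswith("_r") else 1.0
            origin = np.array([0.0, ysign * 0.13 * H / 2.0, 0.53 * H - 0.245 * H])
        series[name] = SegmentPoseSeries(
            q_seg=identity.copy(), x0=np.tile(origin, (n, 1)), dt=dt
        )
    truth = GroundTruthCurves(
        joint_angles=np.zeros((18, n)),
        joint_moments=np.zeros((18, n)),
        vertical_grf=np.full(n, profile.mass * GRAVITY_MAG),
        contact_indices=np.empty(0, dtype=int),
        rate=rate,
        meta={"subject_id": profile.subject_id, "static": True},
    )
    return series, truth


def add_soft_tissue_noise(
    series: SegmentPoseSeries, amplitude: float, speed: float, seed: int
) -> SegmentPoseSeries:
    """Band-limited sensor-borne pose perturbation scaling with gait speed.

    Skin-mounted sensors move relative to bone with an artifact that grows
    with walking speed.  White noise is band-passed to 8-15 Hz, re-centred
    to exactly zero mean and unit RMS per channel, then scaled to an RMS of
    ``POS_NOISE_RMS * amplitude * speed`` metres on the origin and
    ``ROT_NOISE_RMS * amplitude * speed`` radians on the orientation
    (applied as a small right-multiplied rotation).  ``amplitude = 0``
    returns the input unchanged.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return series
    rng = np.random.default_rng(seed)
    n = series.n_frames
    fs = series.rate
    sos = butter(2, SOFT_TISSUE_BAND, btype="bandpass", fs=fs, output="sos")

    def band_noise(cols: int, rms: float) -> np.ndarray:
        w = rng.standard_normal((n, cols))
        f = sosfiltfilt(sos, w, axis=0)
        f = f - f.mean(axis=0)
        scale = np.sqrt(np.mean(f**2, axis=0))
        return f / scale * rms

    pos_pert = band_noise(3, POS_NOISE_RMS * amplitude * speed)
    rot_pert = band_noise(3, ROT_NOISE_RMS * amplitude * speed)
    x0 = series.x0 + pos_pert
    q = np.empty_like(series.q_seg)
    for i in range(n):
        rv = rot_pert[i]
        ang = np.linalg.norm(rv)
        dq = (
            np.array([1.0, 0.0, 0.0, 0.0])
            if ang < 1e-12
            else qk.from_axis_angle(rv / ang, ang)
        )
        q[i] = qk.qmul(series.q_seg[i], dq)
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return SegmentPoseSeries(q_seg=q, x0=x0, dt=series.dt)


def sample_sensor_pose(seed: int) -> SensorPose:
    """Uniform draw of a sensor offset inside the admissible box.

    Translations are uniform in [-50, 50] mm per axis and angles uniform in
    [0, pi/2] — the augmentation range used to synthesize varied sensor
    placements.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    return SensorPose(
        x=rng.uniform(-0.05, 0.05, 3), phi=rng.uniform(0.0, np.pi / 2.0, 3)
    )
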