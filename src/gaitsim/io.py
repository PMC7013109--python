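"""Columnar trial files: one row per frame, metadata in a comment header.

The on-disk format is a UTF-8 CSV with leading ``# key = value`` metadata
lines (subject, trial, speed, rate, seed, source, ...) followed by named
columns, e.g. ``pelvis.qw, pelvis.qx, ..., pelvis.x, pelvis.y, pelvis.z,
grf.z, angle.r_hip_sagittal, ...``.  Floats are written with `repr`
precision, so a write/read round trip is lossless.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gait_synth import ANGLE_CHANNELS, GroundTruthCurves, SEGMENTS
from .imusim import IMUSignal, SegmentPoseSeries

__all__ = ["TrialRecord", "read_trial", "write_trial"]

_QUAT_COLS = ("qw", "qx", "qy", "qz")
_POS_COLS = ("x", "y", "z")
_IMU_COLS = ("gx", "gy", "gz", "ax", "ay", "az")


@dataclass
class TrialRecord:
    """In-memory image of one trial file."""

    metadata: dict
    segments: dict[str, SegmentPoseSeries] = field(default_factory=dict)
    imu: dict[str, IMUSignal] = field(default_factory=dict)
    truth: GroundTruthCurves | None = None

    @property
    def rate(self) -> float:
        return float(self.metadata["rate"])


def _to_frame(record: TrialRecord) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, seg in record.segments.items():
        for i, c in enumerate(_QUAT_COLS):
            cols[f"{name}.{c}"] = seg.q_seg[:, i]
        for i, c in enumerate(_POS_COLS):
            cols[f"{name}.{c}"] = seg.x0[:, i]
    for name, sig in record.imu.items():
        data = sig.channels()
        for i, c in enumerate(_IMU_COLS):
            cols[f"imu.{name}.{c}"] = data[:, i]
    if record.truth is not None:
        for i, ch in enumerate(record.truth.channel_names):
            cols[f"angle.{ch}"] = record.truth.joint_angles[i]
            cols[f"moment.{ch}"] = record.truth.joint_moments[i]
        cols["grf.z"] = record.truth.vertical_grf
    lengths = {len(v) for v in cols.values()}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent channel lengths in record: {sorted(lengths)}")
    return pd.DataFrame(cols)


def write_trial(record: TrialRecord, path: str | Path) -> None:
    """Serialize a trial to the columnar CSV format (lossless floats)."""
    path = Path(path)
    frame = _to_frame(record)
    meta = dict(record.metadata)
    if record.truth is not None and record.truth.contact_indices.size:
        meta["contact_indices"] = ",".join(map(str, record.truth.contact_indices))
    buf = _io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key} = {value}\n")
    frame.to_csv(buf, index=False, float_format="%.17g")
    path.write_text(buf.getvalue(), encoding="utf-8")


def _parse_meta_value(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def read_trial(path: str | Path) -> TrialRecord:
    """Parse a trial file back into a :class:`TrialRecord`.

    Raises ``ValueError`` naming the missing column or the offending line
    on malformed input.
    """
    path = Path(path)
    metadata: dict = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    body_start = 0
    for lineno, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = lineno
            break
        try:
            key, value = line.lstrip("# ").split(" = ", 1)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno + 1}: malformed metadata line {line!r}") from exc
        metadata[key] = _parse_meta_value(value)
    if "rate" not in metadata:
        raise ValueError(f"{path}: missing required metadata key 'rate'")
    frame = pd.read_csv(
        _io.StringIO("\n".join(lines[body_start:])), float_precision="round_trip"
    )
    dt = 1.0 / float(metadata["rate"])

    record = TrialRecord(metadata=metadata)
    for name in SEGMENTS:
        qcols = [f"{name}.{c}" for c in _QUAT_COLS]
        pcols = [f"{name}.{c}" for c in _POS_COLS]
        if all(c in frame for c in qcols + pcols):
            record.segments[name] = SegmentPoseSeries(
                q_seg=frame[qcols].to_numpy(), x0=frame[pcols].to_numpy(), dt=dt
            )
        elif any(c in frame for c in qcols + pcols):
            missing = [c for c in qcols + pcols if c not in frame]
            raise ValueError(f"{path}: segment {name!r} incomplete, missing column {missing[0]!r}")
    imu_names = sorted(
        {c.split(".")[1] for c in frame.columns if c.startswith("imu.")}
    )
    for name in imu_names:
        cols = [f"imu.{name}.{c}" for c in _IMU_COLS]
        missing = [c for c in cols if c not in frame]
        if missing:
            raise ValueError(f"{path}: IMU {name!r} incomplete, missing column {missing[0]!r}")
        data = frame[cols].to_numpy()
        record.imu[name] = IMUSignal(
            omega=data[:, :3], accel=data[:, 3:], rate=float(metadata["rate"])
        )
    angle_cols = [f"angle.{ch}" for ch in ANGLE_CHANNELS]
    if all(c in frame for c in angle_cols):
        contacts = metadata.pop("contact_indices", "")
        record.truth = GroundTruthCurves(
            joint_angles=frame[angle_cols].to_numpy().T,
            joint_moments=frame[[f"moment.{ch}" for ch in ANGLE_CHANNELS]].to_numpy().T,
            vertical_grf=frame["grf.z"].to_numpy(),
            contact_indices=np.array(
                [int(v) for v in str(contacts).split(",") if v not in ("", "nan")],
                dtype=int,
            ),
            rate=float(metadata["rate"]),
            meta=dict(metadata),
        )
    return record
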