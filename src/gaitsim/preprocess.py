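"""Filtering, gait-event segmentation, and normalization.

The processing order is fixed: zero-lag low-pass filtering, then event
detection and segmentation into strides (kinematics) or stance phases
(kinetics), then time normalization of every segment onto 101 points
(0-100% of the cycle) and normalization of joint moments by body mass and
height.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

__all__ = [
    "GaitCycleSegment",
    "butterworth_zero_lag",
    "detect_foot_contacts",
    "segment_stance",
    "time_normalize",
    "normalize_moments",
    "segment_cycles",
]

logger = logging.getLogger(__name__)

N_POINTS = 101  # canonical cycle abscissa, 0..100%
STANCE_THRESHOLD_N = 20.0  # common force-plate practice; configurable


@dataclass(frozen=True)
class GaitCycleSegment:
    """Half-open frame interval [start, end) of one cycle or stance phase."""

    start: int
    end: int
    kind: str = "full-cycle"  # or "stance"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment [{self.start}, {self.end})")


def butterworth_zero_lag(
    x: np.ndarray, fs: float, fc: float = 6.0, order: int = 2
) -> np.ndarray:
    """Forward-backward second-order low-pass Butterworth (zero net phase).

    Applied along axis 0.  Edge effects are handled by `filtfilt`'s default
    odd reflective padding of ``3 * max(len(a), len(b))`` samples; the series
    must exceed that warm-up length.  DC gain is 1, so constants pass
    unchanged; the forward-backward pass squares the magnitude response.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2.0 * fc:
        raise ValueError(f"sampling rate {fs} Hz must exceed 2 x cutoff {fc} Hz")
    b, a = butter(order, fc, btype="low", fs=fs)
    padlen = 3 * max(len(a), len(b))
    if x.shape[0] <= padlen:
        raise ValueError(
            f"series length {x.shape[0]} too short for zero-lag filtering; "
            f"need more than {padlen} frames"
        )
    return filtfilt(b, a, x, axis=0)


def detect_foot_contacts(
    vertical_pos: np.ndarray,
    rate: float,
    min_stride_time: float = 0.4,
    prominence_frac: float = 0.2,
) -> np.ndarray:
    """Initial-contact frames from a foot/ankle vertical-position series.

    A threshold detector standing in for marker-based contact algorithms
    from the gait literature: initial contact is taken as the local minimum
    of the (low-pass filtered) vertical position in each stride, i.e. the
    frame where the descending foot reaches the ground.  Minima must be
    separated by at least ``min_stride_time`` seconds and have a prominence
    of at least ``prominence_frac`` times the signal range.  A flat
    (standing) series yields no events; an empty result logs a warning.

    Accepts a 1-D height series or an (n, 3) position series (Z used).
    """
    z = np.asarray(vertical_pos, dtype=float)
    if z.ndim == 2:
        z = z[:, 2]
    rng = float(np.ptp(z))
    if rng < 1e-9:
        logger.warning("no foot contacts found: input has no vertical excursion")
        return np.empty(0, dtype=int)
    peaks, _ = find_peaks(
        -z,
        distance=max(int(min_stride_time * rate), 1),
        prominence=prominence_frac * rng,
    )
    if peaks.size == 0:
        logger.warning("no foot contacts found above prominence threshold")
    return peaks


def segment_stance(
    grf_vertical: np.ndarray, threshold: float = STANCE_THRESHOLD_N
) -> list[GaitCycleSegment]:
    """Maximal runs where the vertical GRF exceeds the contact threshold."""
    grf = np.asarray(grf_vertical, dtype=float)
    loaded = grf > threshold
    if not loaded.any():
        return []
    edges = np.flatnonzero(np.diff(loaded.astype(int)))
    starts = [0] if loaded[0] else []
    starts += [int(e) + 1 for e in edges if not loaded[e]]
    ends = [int(e) + 1 for e in edges if loaded[e]]
    if loaded[-1]:
        ends.append(len(grf))
    return [GaitCycleSegment(s, e, kind="stance") for s, e in zip(starts, ends)]


def segment_cycles(contacts: np.ndarray) -> list[GaitCycleSegment]:
    """Full gait cycles between successive initial contacts."""
    contacts = np.asarray(contacts, dtype=int)
    return [
        GaitCycleSegment(int(a), int(b), kind="full-cycle")
        for a, b in zip(contacts[:-1], contacts[1:])
    ]


def time_normalize(x: np.ndarray, target: int = N_POINTS) -> np.ndarray:
    """Resample each channel onto ``target`` equally spaced points.

    Linear interpolation including both endpoints (exact on the first and
    last frame, exact everywhere on linear ramps).  Input is ``(frames,)``
    or ``(channels, frames)``; output has the same leading shape with the
    time axis of length ``target``.  Idempotent for already-normalized input.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    n = x.shape[1]
    if n < 2:
        raise ValueError("need at least 2 frames to time-normalize")
    s_in = np.linspace(0.0, 1.0, n)
    s_out = np.linspace(0.0, 1.0, target)
    out = np.empty((x.shape[0], target))
    for c in range(x.shape[0]):
        out[c] = np.interp(s_out, s_in, x[c])
    return out[0] if squeeze else out


def normalize_moments(m: np.ndarray, height: float, mass: float) -> np.ndarray:
    """Joint moments normalized by body mass x height (N·m kg⁻¹ m⁻¹)."""
    if height <= 0 or mass <= 0:
        raise ValueError("height and mass must be positive")
    return np.asarray(m, dtype=float) / (mass * height)
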