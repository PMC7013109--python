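"""Evaluation battery: correlation, RMSE, nRMSE, peaks, paired tests.

Curve agreement is scored per channel over the 101-frame normalized cycle:
Pearson r, RMSE in the curve's native units (degrees for angles,
N·m kg⁻¹ m⁻¹ for normalized moments), and nRMSE as a percentage of the
ground-truth curve's range.  Scalar peak values are compared across subjects
with a paired two-sided t-test and Cohen's d for paired samples.

Degenerate inputs (zero variance, zero range) return NaN rather than
raising, so aggregation over many channels never aborts on one flat curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CurveComparison",
    "pearson_r",
    "rmse",
    "nrmse",
    "peak_values",
    "paired_t_and_effect",
    "compare_curves",
]


@dataclass
class CurveComparison:
    """Per-channel agreement between predicted and ground-truth curves."""

    r: np.ndarray
    rmse: np.ndarray
    nrmse: np.ndarray
    peaks_truth: np.ndarray
    peaks_pred: np.ndarray


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN if either side is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need equal-length 1-D series of length >= 3")
    da, db = a - a.mean(), b - b.mean()
    denom = np.sqrt(np.sum(da**2) * np.sum(db**2))
    if denom == 0:
        return float("nan")
    return float(np.sum(da * db) / denom)


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-squared difference in the curves' native units."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def nrmse(truth: np.ndarray, pred: np.ndarray) -> float:
    """RMSE as a percentage of the ground-truth curve's range.

    The denominator is ``max(truth) - min(truth)``; a flat reference curve
    has no meaningful range and yields NaN.
    """
    truth = np.asarray(truth, dtype=float)
    rng = float(np.ptp(truth))
    if rng == 0:
        return float("nan")
    return 100.0 * rmse(truth, pred) / rng


def peak_values(steps: np.ndarray) -> np.ndarray:
    """Per-channel maxima of a subject's mean step.

    ``steps`` is ``(n_steps, channels, frames)``; steps are averaged within
    the subject first, then the per-channel maximum of the mean step is
    taken (one scalar per channel per subject).
    """
    steps = np.asarray(steps, dtype=float)
    if steps.ndim == 2:
        steps = steps[None]
    return steps.mean(axis=0).max(axis=1)


def paired_t_and_effect(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Paired two-sided t-test plus Cohen's d for paired samples.

    Returns ``(t, p, d)`` with ``d = mean(x - y) / sd(x - y)`` (ddof=1).
    Zero-variance differences make t and d undefined; NaN is returned for
    both and p is 1.0 when the means are also equal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        return float("nan"), 1.0 if np.allclose(diff, 0) else 0.0, float("nan")
    t, p = stats.ttest_rel(x, y)
    d = float(diff.mean() / sd)
    return float(t), float(p), d


def compare_curves(truth: np.ndarray, pred: np.ndarray) -> CurveComparison:
    """Channel-wise metric battery for (channels, frames) curve matrices."""
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: truth {truth.shape} vs pred {pred.shape}")
    n_ch = truth.shape[0]
    r = np.array([pearson_r(truth[c], pred[c]) for c in range(n_ch)])
    e = np.array([rmse(truth[c], pred[c]) for c in range(n_ch)])
    ne = np.array([nrmse(truth[c], pred[c]) for c in range(n_ch)])
    return CurveComparison(
        r=r,
        rmse=e,
        nrmse=ne,
        peaks_truth=truth.max(axis=1),
        peaks_pred=pred.max(axis=1),
    )
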