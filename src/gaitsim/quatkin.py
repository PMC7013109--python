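"""Hamilton-convention quaternion algebra and frame conversions.

Quaternions are stored scalar-first as arrays ``(..., 4)`` with components
``(q0, q1, q2, q3)``; the vector part ``(q1, q2, q3)`` multiplies the
imaginary units i, j, k with ``ijk = -1`` (Hamilton convention, right-handed
composition).  Orientation quaternions are kept at unit norm; positions and
accelerations embedded in quaternion products are *pure* quaternions with a
scalar part of exactly zero.

The global frame is right-handed with Z up; gravity acts along -Z on masses
(see :mod:`gaitsim.imusim` for the accelerometer sign convention).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "qmul",
    "qconj",
    "qnormalize",
    "from_axis_angle",
    "rotate_vector",
    "from_frame",
    "to_frame",
    "enforce_sign_continuity",
]

#: Orientation norms deviating by less than this are silently renormalized;
#: larger deviations raise, since they indicate a bug rather than drift.
NORM_TOL = 1e-6


def qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b``.

    Broadcasts over leading axes; the product of two unit quaternions is a
    unit quaternion (up to rounding).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a0, a1, a2, a3 = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    b0, b1, b2, b3 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            a0 * b0 - a1 * b1 - a2 * b2 - a3 * b3,
            a0 * b1 + a1 * b0 + a2 * b3 - a3 * b2,
            a0 * b2 - a1 * b3 + a2 * b0 + a3 * b1,
            a0 * b3 + a1 * b2 - a2 * b1 + a3 * b0,
        ],
        axis=-1,
    )


def qconj(a: np.ndarray) -> np.ndarray:
    """Quaternion conjugate: scalar part unchanged, vector part negated."""
    a = np.asarray(a, dtype=float)
    return a * np.array([1.0, -1.0, -1.0, -1.0])


def qnormalize(q: np.ndarray, tol: float = NORM_TOL) -> np.ndarray:
    """Renormalize orientation quaternions, raising beyond ``tol``.

    Norm drift below ``tol`` (accumulated products) is repaired silently;
    anything larger raises ``ValueError`` as it signals corrupted input.
    """
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(np.abs(norm - 1.0) > tol):
        worst = float(np.max(np.abs(norm - 1.0)))
        raise ValueError(
            f"quaternion norm deviates from 1 by {worst:.3e} (> {tol:.0e}); "
            "refusing to renormalize a non-unit orientation"
        )
    return q / norm


def from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Unit quaternion for a right-handed rotation by ``angle`` about ``axis``.

    The half-angle is stored internally: ``q = (cos(angle/2), u sin(angle/2))``.
    ``axis`` must be a unit vector within 1e-6 (unless ``angle`` is zero).
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if angle == 0.0 and n == 0.0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if n < 1e-12:
        raise ValueError("rotation axis has zero norm but angle is nonzero")
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"rotation axis norm {n:.6f} is not 1 within 1e-6")
    half = 0.5 * angle
    q = np.empty(4)
    q[0] = np.cos(half)
    q[1:] = axis / n * np.sin(half)
    return q


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion(s) ``q`` as ``q ⊗ v ⊗ q*``.

    ``v`` is embedded as a pure quaternion; the rotation is an isometry, so
    the norm of the result equals the norm of ``v``.
    """
    q = qnormalize(q)
    v = np.asarray(v, dtype=float)
    pure = np.zeros(v.shape[:-1] + (4,))
    pure[..., 1:] = v
    return qmul(qmul(q, pure), qconj(q))[..., 1:]


def from_frame(basis: np.ndarray) -> np.ndarray:
    """Convert a right-handed orthonormal 3x3 basis to a unit quaternion.

    Uses Shepperd's branch selection (largest diagonal pivot), which is
    well-conditioned for all rotations including 180-degree cases where
    the trace approaches -1.  Raises for bases that are not orthonormal
    right-handed within 1e-6.
    """
    R = np.asarray(basis, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"basis must be 3x3, got {R.shape}")
    if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6 or np.linalg.det(R) < 0:
        raise ValueError("basis is not orthonormal right-handed within 1e-6")
    t = np.trace(R)
    if t > max(R[0, 0], R[1, 1], R[2, 2]):
        s = np.sqrt(1.0 + t) * 2.0
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax([R[0, 0], R[1, 1], R[2, 2]]))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(1.0 + R[i, i] - R[j, j] - R[k, k]) * 2.0
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    return q / np.linalg.norm(q)


def to_frame(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of unit quaternion(s) ``q``; shape ``(..., 3, 3)``."""
    q = qnormalize(q)
    q0, q1, q2, q3 = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (q2**2 + q3**2)
    R[..., 0, 1] = 2 * (q1 * q2 - q0 * q3)
    R[..., 0, 2] = 2 * (q1 * q3 + q0 * q2)
    R[..., 1, 0] = 2 * (q1 * q2 + q0 * q3)
    R[..., 1, 1] = 1 - 2 * (q1**2 + q3**2)
    R[..., 1, 2] = 2 * (q2 * q3 - q0 * q1)
    R[..., 2, 0] = 2 * (q1 * q3 - q0 * q2)
    R[..., 2, 1] = 2 * (q2 * q3 + q0 * q1)
    R[..., 2, 2] = 1 - 2 * (q1**2 + q2**2)
    return R


def enforce_sign_continuity(q_series: np.ndarray) -> np.ndarray:
    """Flip quaternion signs so consecutive frames stay on one cover branch.

    ``q`` and ``-q`` encode the same rotation (double cover); numerical
    differentiation across a sign flip is ill-behaved, so each frame whose
    dot product with its predecessor is negative is negated.
    """
    q = np.array(q_series, dtype=float)
    if q.ndim != 2 or q.shape[1] != 4:
        raise ValueError(f"expected (n, 4) series, got {q.shape}")
    dots = np.sum(q[:-1] * q[1:], axis=1)
    flip = np.cumprod(np.where(dots < 0, -1.0, 1.0))
    q[1:] *= flip[:, None]
    return q
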