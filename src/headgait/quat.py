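"""Quaternion helpers (scalar-first, Hamilton product, passive sensor→aligned).

All functions accept either a single quaternion ``(4,)`` or a series
``(N, 4)``.  Rotations are active: ``rotate(q, v)`` returns ``q v q*``.
scipy's :class:`~scipy.spatial.transform.Rotation` is scalar-last, so the
conversion helpers below are the only place the two conventions meet.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    return q / n


def conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 ⊗ q2."""
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


def from_axis_angle(axis: np.ndarray, angle: float | np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    angle = np.asarray(angle, dtype=float)
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    half = angle / 2.0
    return np.concatenate(
        [np.cos(half)[..., None], axis * np.sin(half)[..., None]], axis=-1
    )


def to_scipy(q: np.ndarray) -> Rotation:
    """Scalar-first array → scipy Rotation (scalar-last internally)."""
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))


def from_scipy(r: Rotation) -> np.ndarray:
    q = np.atleast_2d(r.as_quat())  # (x, y, z, w)
    out = np.roll(q, 1, axis=-1)
    # canonical sign: non-negative scalar part
    out = np.where(out[..., :1] < 0, -out, out)
    return out if out.shape[0] > 1 else out[0]


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Active rotation of vector(s) v by quaternion(s) q."""
    return to_scipy(q).apply(np.asarray(v, dtype=float))


def rotate_inverse(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    return to_scipy(q).apply(np.asarray(v, dtype=float), inverse=True)
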