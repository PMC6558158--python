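"""Gravity-direction estimation and transformation into the aligned frame.

The gravity filter is a per-sample complementary blend: the previous
gravity estimate is propagated through the incremental gyroscope
rotation (a world-fixed vector observed from a frame rotating with body
rates ω obeys dg/dt = −ω × g; the propagation applies the exact
Rodrigues rotation by −ω·Δt), then pulled toward the low-passed
accelerometer with weight (1 − α), and re-normalized.  The orientation
quaternion q(t) is the axis-angle rotation taking the estimated gravity
onto the world vertical (axis g(t) × g_W); because the axis is always
perpendicular to g_W, q(t) never contains a yaw component and maps
sensor-frame vectors directly into the aligned frame.

Conventions: quaternions scalar-first, Hamilton product; g_W = (0, 0, 1)
in g units (specific force of a static upright sensor).  Net inertial
acceleration in aligned coordinates is i_A = rot(q, a − g); angular
velocity is deliberately left in the body frame (pitch = ML component).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from . import quat
from .errors import ConfigError, DataError
from .io import ImuRecording

log = logging.getLogger(__name__)

G_WORLD = np.array([0.0, 0.0, 1.0])

#: gyroscope weight; the complementary time constant α/(1−α)·Δt must be
#: long against the gait cycle so gait-band tilt oscillations are tracked
#: by the gyro, not fought by the accelerometer pull (see docs/methods.md)
DEFAULT_ALPHA = 0.98
#: accelerometer low-pass cut-off (Hz); see docs/methods.md for the grid
#: search behind this default
DEFAULT_F_LP = 0.5


@dataclass
class OrientationEstimate:
    """Per-sample gravity direction and yaw-free orientation."""

    gravity: np.ndarray  # (N, 3), unit vectors, sensor frame, g
    orientation: np.ndarray  # (N, 4), scalar-first unit quaternions
    alpha: float
    f_lp: float
    g_world: np.ndarray = field(default_factory=lambda: G_WORLD.copy())
    n_degenerate: int = 0  # samples where g was antiparallel to g_world


@dataclass
class AlignedSignals:
    """Inertial acceleration in the gravity-aligned frame + body-frame gyro.

    ``inertial_accel`` columns are (AP, ML, V) in g; ``gyro_body`` columns
    are body-frame (roll, pitch, yaw) rates in rad/s, so ``gyro_body[:, 1]``
    is pitch velocity.
    """

    inertial_accel: np.ndarray
    gyro_body: np.ndarray

    @property
    def ap(self) -> np.ndarray:
        return self.inertial_accel[:, 0]

    @property
    def ml(self) -> np.ndarray:
        return self.inertial_accel[:, 1]

    @property
    def v(self) -> np.ndarray:
        return self.inertial_accel[:, 2]

    @property
    def pitch_velocity(self) -> np.ndarray:
        return self.gyro_body[:, 1]


def prefilter(
    recording: ImuRecording, f_lp: float = DEFAULT_F_LP, f_hp: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase 5th-order Butterworth conditioning of both channels.

    The gyroscope is high-passed at ``f_hp`` (default 0.1 Hz) to remove
    bias drift; the accelerometer is low-passed at ``f_lp`` to suppress
    transient inertial accelerations before the gravity blend.  Both are
    applied forward-backward (the pipeline is offline, so zero phase is
    free).
    """
    nyq = recording.sample_rate / 2.0
    if not (f_hp < f_lp < nyq):
        raise ConfigError(f"f_lp must lie in ({f_hp}, {nyq}) Hz, got {f_lp}")
    b_hp, a_hp = butter(5, f_hp / nyq, btype="highpass")
    b_lp, a_lp = butter(5, f_lp / nyq, btype="lowpass")
    gyro_f = filtfilt(b_hp, a_hp, recording.gyro, axis=0)
    accel_f = filtfilt(b_lp, a_lp, recording.accel, axis=0)
    return accel_f, gyro_f


def _gravity_loop_py(accel, gyro, alpha, g_world, dt):
    n = accel.shape[0]
    gravity = np.empty((n, 3))
    quats = np.empty((n, 4))
    n_degenerate = 0
    gx, gy, gz = g_world
    wx, wy, wz = g_world
    prev_q = (1.0, 0.0, 0.0, 0.0)
    blend = 1.0 - alpha
    for t in range(n):
        # propagate g by the incremental rotation −ω Δt (exact Rodrigues)
        px, py, pz = gyro[t, 0] * dt, gyro[t, 1] * dt, gyro[t, 2] * dt
        ang = (px * px + py * py + pz * pz) ** 0.5
        if ang > 1e-15:
            ux, uy, uz = px / ang, py / ang, pz / ang
            c, s = np.cos(-ang), np.sin(-ang)
            # k×g and k·g with k = rotation axis
            cx = uy * gz - uz * gy
            cy = uz * gx - ux * gz
            cz = ux * gy - uy * gx
            d = ux * gx + uy * gy + uz * gz
            gx = gx * c + cx * s + ux * d * (1.0 - c)
            gy = gy * c + cy * s + uy * d * (1.0 - c)
            gz = gz * c + cz * s + uz * d * (1.0 - c)
        # complementary blend with the (low-passed) accelerometer; the convex
        # form keeps both limits exact (α=1 gyro-only, α=0 accel-only)
        gx = alpha * gx + blend * accel[t, 0]
        gy = alpha * gy + blend * accel[t, 1]
        gz = alpha * gz + blend * accel[t, 2]
        norm = (gx * gx + gy * gy + gz * gz) ** 0.5
        gx, gy, gz = gx / norm, gy / norm, gz / norm
        gravity[t, 0], gravity[t, 1], gravity[t, 2] = gx, gy, gz
        # q(t): axis-angle rotation taking g(t) onto g_W (axis n = g × g_W,
        # always horizontal, so q never contains yaw); q maps sensor→aligned
        nx = gy * wz - gz * wy
        ny = gz * wx - gx * wz
        nz = gx * wy - gy * wx
        nn = (nx * nx + ny * ny + nz * nz) ** 0.5
        dot = wx * gx + wy * gy + wz * gz
        if dot > 1.0:
            dot = 1.0
        elif dot < -1.0:
            dot = -1.0
        if nn < 1e-12:
            if dot > 0.0:
                q = (1.0, 0.0, 0.0, 0.0)
            else:  # antiparallel: axis undefined, keep previous orientation
                q = prev_q
                n_degenerate += 1
        else:
            theta = np.arccos(dot)
            sh = np.sin(theta / 2.0)
            q = (np.cos(theta / 2.0), nx / nn * sh, ny / nn * sh, nz / nn * sh)
        quats[t, 0], quats[t, 1], quats[t, 2], quats[t, 3] = q
        prev_q = q
    return gravity, quats, n_degenerate


try:  # compile the sequential loop if numba is available
    from numba import njit

    _gravity_loop = njit(cache=False)(_gravity_loop_py)
except Exception:  # pragma: no cover - exercised only without numba
    _gravity_loop = _gravity_loop_py


def gravity_filter(
    accel: np.ndarray,
    gyro: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    g_world: np.ndarray = G_WORLD,
    dt: float = 0.01,
    f_lp: float = DEFAULT_F_LP,
) -> OrientationEstimate:
    """Run the complementary gravity filter over prefiltered signals.

    Parameters
    ----------
    accel, gyro : (N, 3) arrays
        Low-passed acceleration (g) and high-passed angular velocity
        (rad/s); see :func:`prefilter`.
    alpha : float in [0, 1]
        Gyroscope weight.  α = 1 integrates the gyro only; α = 0 tracks
        the normalized accelerometer.
    """
    accel = np.ascontiguousarray(accel, dtype=float)
    gyro = np.ascontiguousarray(gyro, dtype=float)
    if not 0.0 <= alpha <= 1.0:
        raise ConfigError(f"alpha must lie in [0, 1], got {alpha}")
    if accel.shape != gyro.shape or accel.ndim != 2 or accel.shape[1] != 3:
        raise DataError("accel and gyro must both be (N, 3)")
    g_world = np.asarray(g_world, dtype=float)
    g_world = g_world / np.linalg.norm(g_world)
    gravity, quats, n_deg = _gravity_loop(accel, gyro, alpha, g_world, dt)
    if n_deg:
        log.warning("gravity filter: %d samples with g antiparallel to g_W", n_deg)
    return OrientationEstimate(
        gravity=gravity,
        orientation=quats,
        alpha=alpha,
        f_lp=f_lp,
        g_world=g_world,
        n_degenerate=int(n_deg),
    )


def geodesic_distance(q1: np.ndarray, q2: np.ndarray) -> np.ndarray | float:
    """Angle (rad) of the shortest rotation between two orientations.

    ``d = arccos(2⟨q1, q2⟩² − 1)`` ∈ [0, π]; invariant to a sign flip of
    either quaternion.  Non-unit inputs are normalized with a warning.
    """
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    n1 = np.linalg.norm(q1, axis=-1)
    n2 = np.linalg.norm(q2, axis=-1)
    if np.any(np.abs(n1 - 1) > 1e-6) or np.any(np.abs(n2 - 1) > 1e-6):
        log.warning("geodesic_distance: normalizing non-unit quaternion input")
    dot = np.sum(q1 * q2, axis=-1) / (n1 * n2)
    return np.arccos(np.clip(2.0 * dot * dot - 1.0, -1.0, 1.0))


def to_aligned(
    accel_raw: np.ndarray,
    estimate: OrientationEstimate,
    gyro_body: np.ndarray | None = None,
) -> AlignedSignals:
    """Transform raw acceleration into net inertial acceleration.

    ``i_A(t) = rot(q(t), a(t) − g(t))``, components (AP, ML, V); q(t)
    rotates sensor-frame vectors into the aligned frame.  The angular
    velocity is passed through unchanged (rotations are reported in the
    body frame).
    """
    accel_raw = np.asarray(accel_raw, dtype=float)
    if accel_raw.shape[0] != estimate.orientation.shape[0]:
        raise DataError("orientation estimate does not cover every sample")
    inertial = quat.rotate(estimate.orientation, accel_raw - estimate.gravity)
    if gyro_body is None:
        gyro_body = np.zeros_like(accel_raw)
    return AlignedSignals(inertial_accel=inertial, gyro_body=np.asarray(gyro_body))
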