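"""IMU time-series I/O, two-device synchronization, and frame calibration.

File format: delimited text with a header line and columns
``t, ax, ay, az, gx, gy, gz`` — time in seconds from recording start,
acceleration in g (specific force, so a static upright sensor reads
+1 g on its vertical axis), angular velocity in rad/s.  Sampling must be
uniform; non-uniform files are rejected, not resampled.  A sidecar mask
file (``start,end,label`` rows) can mark non-wear intervals.

Synchronization follows the knock protocol: both devices are knocked
against each other at the start and end of the recording, producing
large synchronous acceleration spikes.  The two knock pairs define a
linear map (offset + drift) between the device clocks.

Calibration: a quasi-static posture segment pins the body-frame vertical
(mean measured gravity → +1 g up) and a five-nod segment pins the
medial/lateral axis (dominant rotation axis of the nods, signed so the
initial nod is a forward pitch).  For the trunk device no nod is
performed; only the vertical is constrained and yaw is left as identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from . import quat
from .errors import CalibrationError, ConfigError, FormatError, SyncError

COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]

#: body-frame axes: x = anterior/posterior (forward), y = medial/lateral
#: (left), z = vertical (up); right-handed.
AXES = ("AP", "ML", "V")


@dataclass
class ImuRecording:
    """Raw tri-axial IMU recording from one placement.

    Attributes
    ----------
    timestamps : (N,) float array, seconds, uniform
    accel : (N, 3) float array, g
    gyro : (N, 3) float array, rad/s
    placement : {"head", "trunk"}
    sample_rate : float, Hz
    """

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    placement: str
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.timestamps.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise FormatError(
                f"channel length mismatch: {n} timestamps, accel {self.accel.shape},"
                f" gyro {self.gyro.shape}"
            )
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.placement not in ("head", "trunk"):
            raise ConfigError(f"unknown placement {self.placement!r}")
        if n >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise FormatError("timestamps must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.sample_rate)) > 1e-6:
                raise FormatError("sampling is not uniform at the stated rate")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclass
class SyncModel:
    """Linear map from trunk (reference) time to head device time.

    ``t_head = offset + (1 + drift) * t_trunk``
    """

    offset: float
    drift: float

    def __post_init__(self) -> None:
        if abs(self.drift) >= 1e-3:
            raise SyncError(f"implausible clock drift {self.drift:g}")

    def trunk_to_head(self, t: np.ndarray) -> np.ndarray:
        return self.offset + (1.0 + self.drift) * np.asarray(t, dtype=float)

    def head_to_trunk(self, t: np.ndarray) -> np.ndarray:
        return (np.asarray(t, dtype=float) - self.offset) / (1.0 + self.drift)


@dataclass
class CalibrationTransform:
    """Unit quaternion rotating sensor-frame vectors into the body frame."""

    rotation: np.ndarray = field(default_factory=lambda: quat.IDENTITY.copy())

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        n = np.linalg.norm(self.rotation)
        if abs(n - 1.0) > 1e-6:
            raise CalibrationError("calibration quaternion is not unit norm")
        self.rotation = self.rotation / n

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        return quat.rotate(self.rotation, vectors)


# ---------------------------------------------------------------------------
# file I/O


def write_recording(path: str | Path, recording: ImuRecording) -> None:
    """Write a recording as delimited text (columns ``t,ax,...,gz``)."""
    df = pd.DataFrame(
        np.column_stack([recording.timestamps, recording.accel, recording.gyro]),
        columns=COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_recording(
    path: str | Path, placement: str, sample_rate: float = 100.0
) -> ImuRecording:
    """Read and validate a delimited IMU time-series file.

    Short NaN runs (≤ 0.5 s) are linearly interpolated; longer runs are
    fatal (the pipeline does not invent half a second of motion).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns {missing} in {path}")
    t = df["t"].to_numpy(dtype=float)
    data = df[COLUMNS[1:]].to_numpy(dtype=float)
    if np.any(np.isnan(t)):
        raise FormatError("NaN timestamps")
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise FormatError("timestamps are not strictly increasing")
    max_run = int(round(0.5 * sample_rate))
    for j in range(data.shape[1]):
        col = data[:, j]
        bad = np.isnan(col)
        if not bad.any():
            continue
        run = _longest_run(bad)
        if run > max_run:
            raise FormatError(
                f"NaN run of {run} samples (> 0.5 s) in column {COLUMNS[1 + j]}"
            )
        idx = np.arange(col.size)
        data[:, j] = np.interp(idx, idx[~bad], col[~bad])
    return ImuRecording(
        timestamps=t,
        accel=data[:, :3],
        gyro=data[:, 3:],
        placement=placement,
        sample_rate=sample_rate,
    )


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def write_mask(path: str | Path, intervals: list[tuple[float, float, str]]) -> None:
    """Write a sidecar mask file of labeled ``start,end,label`` intervals."""
    df = pd.DataFrame(intervals, columns=["start", "end", "label"])
    df.to_csv(path, index=False)


def read_mask(path: str | Path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path)
    return [(float(r.start), float(r.end), str(r.label)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# synchronization


def detect_knocks(
    recording: ImuRecording,
    threshold: float = 2.5,
    refractory: float = 1.0,
) -> np.ndarray:
    """Times of acceleration-magnitude spikes above ``threshold`` (g).

    Spikes closer than ``refractory`` seconds are merged into the highest
    peak.  Event times are refined to sub-sample precision by the
    centroid of the above-baseline magnitude around each peak (a knock
    lasts only a few samples, and the two-point drift fit needs knock
    times far better than one sample period).  The first and last event
    are the synchronization knocks.
    """
    if recording.duration < 10.0:
        raise SyncError("recording shorter than 10 s; knock detection unreliable")
    mag = np.linalg.norm(recording.accel, axis=1)
    distance = max(1, int(round(refractory * recording.sample_rate)))
    idx, _ = find_peaks(mag, height=threshold, distance=distance)
    times = []
    half = max(2, int(round(0.05 * recording.sample_rate)))
    for i in idx:
        lo, hi = max(i - half, 0), min(i + half + 1, mag.size)
        w = np.clip(mag[lo:hi] - 1.0, 0.0, None)
        if w.sum() > 0:
            times.append(float(np.sum(recording.timestamps[lo:hi] * w) / w.sum()))
        else:
            times.append(float(recording.timestamps[i]))
    return np.asarray(times)


def fit_sync(head_knocks: np.ndarray, trunk_knocks: np.ndarray) -> SyncModel:
    """Two-point linear clock model from the first/last knock of each device."""
    head_knocks = np.asarray(head_knocks, dtype=float)
    trunk_knocks = np.asarray(trunk_knocks, dtype=float)
    if head_knocks.size < 2 or trunk_knocks.size < 2:
        raise SyncError("need at least two knock events per device")
    h1, h2 = head_knocks[0], head_knocks[-1]
    t1, t2 = trunk_knocks[0], trunk_knocks[-1]
    if t2 - t1 < 1e-9 or h2 - h1 < 1e-9:
        raise SyncError("coincident knock times; sync fit is degenerate")
    drift = (h2 - h1) / (t2 - t1) - 1.0
    offset = h1 - (1.0 + drift) * t1
    return SyncModel(offset=offset, drift=drift)


def apply_sync(
    head: ImuRecording, sync: SyncModel, trunk_timestamps: np.ndarray
) -> ImuRecording:
    """Resample the head recording onto the trunk timebase.

    Cubic-spline interpolation of all six channels at the head-device
    times corresponding to the trunk samples.  Times outside the head
    recording are clamped to its edge values (they can only occur in the
    margins before the first / after the last knock).
    """
    tq = np.clip(
        sync.trunk_to_head(trunk_timestamps),
        head.timestamps[0],
        head.timestamps[-1],
    )
    spl_a = CubicSpline(head.timestamps, head.accel, axis=0)
    spl_g = CubicSpline(head.timestamps, head.gyro, axis=0)
    return ImuRecording(
        timestamps=np.asarray(trunk_timestamps, dtype=float),
        accel=spl_a(tq),
        gyro=spl_g(tq),
        placement=head.placement,
        sample_rate=head.sample_rate,
    )


# ---------------------------------------------------------------------------
# calibration


def fit_calibration(
    static_segment: ImuRecording,
    nod_segment: ImuRecording | None,
    static_tolerance: float = 0.05,
) -> CalibrationTransform:
    """Sensor→body rotation from a static posture and (optionally) nods.

    The mean static acceleration defines the body vertical; the first
    principal axis of the nod angular-velocity samples defines the
    medial/lateral axis, with its sign fixed so the initial nod is a
    forward pitch (positive rotation about +ML in a right-handed
    x-forward / y-left / z-up frame).  Without a nod segment only the
    vertical is constrained (minimal rotation, yaw = identity).
    """
    if static_segment.duration < 2.0:
        raise CalibrationError("static segment shorter than 2 s")
    mag = np.linalg.norm(static_segment.accel, axis=1)
    if abs(np.mean(mag) - 1.0) > static_tolerance:
        raise CalibrationError(
            f"static segment mean |a| = {np.mean(mag):.3f} g, not within "
            f"{static_tolerance:.0%} of 1 g"
        )
    wobble = np.sqrt(
        np.mean(
            np.sum((static_segment.accel - static_segment.accel.mean(0)) ** 2, 1)
        )
    )
    if wobble > static_tolerance:
        raise CalibrationError(
            f"static segment is not quasi-static (RMS deviation {wobble:.3f} g)"
        )
    g_hat = np.mean(static_segment.accel, axis=0)
    g_hat = g_hat / np.linalg.norm(g_hat)

    if nod_segment is None:
        z = np.array([0.0, 0.0, 1.0])
        c = float(np.clip(np.dot(g_hat, z), -1.0, 1.0))
        axis = np.cross(g_hat, z)
        n = np.linalg.norm(axis)
        if n < 1e-12:
            rot = quat.IDENTITY.copy() if c > 0 else quat.from_axis_angle(
                np.array([1.0, 0.0, 0.0]), np.pi
            )
        else:
            rot = quat.from_axis_angle(axis / n, np.arccos(c))
        return CalibrationTransform(rotation=rot)

    w = nod_segment.gyro - np.mean(nod_segment.gyro, axis=0)
    if np.max(np.linalg.norm(w, axis=1)) < 0.05:
        raise CalibrationError("nod segment contains no oscillatory rotation")
    # dominant rotation axis = first principal axis of the gyro samples
    _, _, vt = np.linalg.svd(w, full_matrices=False)
    axis = vt[0]
    proj = w @ axis
    # sign: the first strong lobe of the nod must be positive (forward pitch)
    strong = np.flatnonzero(np.abs(proj) > 0.3 * np.max(np.abs(proj)))
    if proj[strong[0]] < 0:
        axis = -axis
        proj = -proj
    if abs(np.dot(axis, g_hat)) > np.cos(np.deg2rad(20.0)):
        raise CalibrationError("nod axis nearly parallel to gravity; ill-conditioned")

    z_b = g_hat
    y_b = axis - np.dot(axis, z_b) * z_b
    y_b = y_b / np.linalg.norm(y_b)
    x_b = np.cross(y_b, z_b)
    rmat = np.stack([x_b, y_b, z_b])  # rows: body axes in sensor coordinates
    from scipy.spatial.transform import Rotation

    rot = quat.from_scipy(Rotation.from_matrix(rmat))
    return CalibrationTransform(rotation=rot)


def apply_calibration(
    recording: ImuRecording, transform: CalibrationTransform
) -> ImuRecording:
    """Rotate both channels of a recording into the body frame."""
    return replace(
        recording,
        accel=transform.apply(recording.accel),
        gyro=transform.apply(recording.gyro),
    )
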