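"""Synthetic dual-IMU gait sessions with ground truth.

The generator emulates the statistical structure of free-living
head/trunk recordings so that every downstream stage can be tested
without a real recording:

* step frequency drawn per bout from N(1.86, 0.23) Hz with small AR(1)
  within-bout jitter;
* vertical trunk acceleration during gait is a harmonic series at the
  step frequency (geometric amplitude decay over 10 harmonics) whose
  per-step peaks clear the step detector's height and prominence
  thresholds; per-bout amplitude scaling is lognormal so the session RMS
  distribution is right-skewed with mode ``vertical_rms_mode``;
* stride-locked (odd-harmonic) content is injected in quadrature, which
  keeps all step peaks at equal height while producing configurable
  even/odd harmonic-power ratios per axis;
* head acceleration equals trunk acceleration attenuated per axis to
  the requested attenuation coefficients, plus independent sensor noise;
* head (and trunk) pitch velocity is a tone at the step frequency,
  phase-locked to vertical head acceleration so the corrected
  displacement-vs-angle phase equals ``head_pitch_phase``;
* bout lengths follow a truncated discrete power law; rests separate
  bouts; occasional cycling-like segments pass the peak detector but
  violate the walking criteria (low vertical RMS, mismatched V/ML
  predominant frequencies);
* each session starts and ends with a synchronized knock spike and
  contains one static and one five-nod calibration segment; sensors are
  mounted with configurable rotations and the head device clock has a
  configurable offset and drift;
* orientation is kinematically consistent: body pitch is the integral
  of the emitted pitch velocity and the accelerometer output is the
  tilted gravity plus the designed inertial acceleration.

Identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from . import quat
from .errors import ConfigError
from .io import ImuRecording

G_UP = np.array([0.0, 0.0, 1.0])


@dataclass
class GaitGeneratorParams:
    """Knobs of the synthetic session generator (axis order AP, ML, V)."""

    step_freq_mean: float = 1.86  # Hz
    step_freq_sd: float = 0.23  # Hz
    vertical_rms_mode: float = 0.3  # g, mode of per-bout vertical RMS
    n_harmonics: int = 10
    harmonic_decay: float = 0.4  # per-harmonic amplitude ratio
    hr_targets: tuple[float, float, float] = (3.0, 0.4, 4.0)  # AP, ML, V
    ac_targets: tuple[float, float, float] = (0.3, 0.2, 0.05)  # AP, ML, V
    head_pitch_phase: float = -50.0 * np.pi / 180.0  # rad
    head_pitch_amp: float = 0.5  # rad/s
    trunk_pitch_amp: float = 0.3  # rad/s
    ap_scale: float = 0.8  # AP RMS relative to vertical
    ml_scale: float = 0.6  # ML RMS relative to vertical
    amp_sigma: float = 0.2  # lognormal sigma of per-bout amplitude scale
    bout_exponent: float = 1.5  # discrete power-law exponent
    bout_min: int = 2
    bout_max: int = 2000
    rest_mean: float = 6.0  # s, median rest between bouts
    rest_sigma: float = 0.5
    rest_min: float = 2.5  # s, keeps true bout gaps well above 1 s
    freq_jitter_sd: float = 0.02  # Hz, within-bout AR(1) jitter
    freq_jitter_ar: float = 0.9
    p_cycling: float = 0.08  # probability of a cycling block after a rest
    cycling_cadence: float = 1.4  # Hz
    gyro_drift_rate: float = 0.01  # rad/s per hour
    gyro_noise_sd: float = 0.01  # rad/s
    accel_noise_sd: float = 0.02  # g
    clock_offset: float = 0.3  # s, head device clock ahead of trunk
    clock_drift: float = 1e-5  # s/s
    knock_amp: float = 3.0  # g
    knock_duration: float = 0.05  # s
    mounting_head: tuple[float, float, float] = (4.0, 8.0, 5.0)  # roll,pitch,yaw deg
    mounting_trunk: tuple[float, float, float] = (-3.0, 5.0, 0.0)
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_freq_mean <= 0:
            raise ConfigError("step_freq_mean must be positive")
        if any(ac >= 1 for ac in self.ac_targets):
            raise ConfigError("ac_targets must each be < 1")
        if self.n_harmonics < 1:
            raise ConfigError("n_harmonics must be >= 1")
        for name in ("step_freq_sd", "accel_noise_sd", "gyro_noise_sd",
                     "gyro_drift_rate", "freq_jitter_sd", "amp_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 2 <= self.bout_min <= self.bout_max:
            raise ConfigError("need 2 <= bout_min <= bout_max")

    def noiseless(self) -> "GaitGeneratorParams":
        """Copy with all sensor-noise sources switched off."""
        return replace(
            self,
            accel_noise_sd=0.0,
            gyro_noise_sd=0.0,
            gyro_drift_rate=0.0,
            freq_jitter_sd=0.0,
        )


@dataclass
class GroundTruth:
    """Per-sample and per-event ground truth of a synthetic session.

    ``true_orientation``/``true_gravity``/``mounting`` are keyed by
    placement ("head"/"trunk"); orientation quaternions are scalar-first
    sensor→world.  All series live on the reference (trunk) timeline.
    """

    timestamps: np.ndarray
    true_step_times: np.ndarray
    true_step_freqs: np.ndarray
    true_bout_boundaries: list[tuple[int, int]]
    bout_lengths: np.ndarray
    bout_freqs: np.ndarray
    true_orientation: dict[str, np.ndarray]
    true_gravity: dict[str, np.ndarray]
    segment_labels: np.ndarray
    knock_times: np.ndarray
    mounting: dict[str, np.ndarray]
    calibration_intervals: dict[str, tuple[float, float]]
    params: GaitGeneratorParams = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# building blocks


def _harmonic_amplitudes(
    rms: float, hr: float, decay: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Even/odd ladder amplitudes for a target RMS and even:odd power ratio.

    ``hr`` is interpreted as even-power : odd-power (the AP/V reading);
    callers pass 1/hr for the ML axis.
    """
    geo = (1.0 - decay ** (2 * n)) / (1.0 - decay**2)
    e_power = rms**2 * hr / (1.0 + hr)
    o_power = rms**2 / (1.0 + hr)
    a1 = np.sqrt(2.0 * e_power / geo)
    b1 = np.sqrt(2.0 * o_power / geo)
    k = np.arange(n)
    return a1 * decay**k, b1 * decay**k


def _axis_waveform(
    theta: np.ndarray,
    even_amp: np.ndarray,
    odd_amp: np.ndarray,
    phase_shift: float = 0.0,
) -> np.ndarray:
    """Harmonic gait waveform of one axis as a function of stride phase.

    Even (step) harmonics in cosine phase peak at θ = 2πm; odd (stride)
    harmonics are injected in quadrature (sine phase) so they vanish at
    the peaks — every step peak then has the same height while the
    even/odd power split is fully controlled.
    """
    th = theta - phase_shift
    out = np.zeros_like(theta)
    for k, a in enumerate(even_amp, start=1):
        out += a * np.cos(k * th)
    for k, b in enumerate(odd_amp, start=1):
        out -= b * np.sin((2 * k - 1) * th / 2.0)
    return out


def _sample_bout_length(rng: np.random.Generator, p: GaitGeneratorParams) -> int:
    k = np.arange(p.bout_min, p.bout_max + 1, dtype=float)
    w = k ** (-p.bout_exponent)
    cdf = np.cumsum(w) / np.sum(w)
    return int(p.bout_min + np.searchsorted(cdf, rng.random()))


def _euler_to_quat(roll_pitch_yaw_deg: tuple[float, float, float]) -> np.ndarray:
    r = Rotation.from_euler("xyz", roll_pitch_yaw_deg, degrees=True)
    return quat.from_scipy(r)


def _half_sine_pulse(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    x = (t - t0) / width
    out = np.zeros_like(t)
    m = (x >= 0) & (x <= 1)
    out[m] = np.sin(np.pi * x[m])
    return out


# ---------------------------------------------------------------------------
# cycling confounder


def generate_cycling_segment(
    params: GaitGeneratorParams, duration: float
) -> np.ndarray:
    """Tri-axial (AP, ML, V) world-frame acceleration of a cycling-like bout.

    Vertical: a sparse train of sharp pedal-stroke spikes (clears the
    step detector's height/prominence thresholds) plus a weak tone at
    the cadence, keeping vertical RMS below the walking range.  The ML
    axis oscillates at a clearly different frequency, so the V-vs-ML
    predominant-frequency mismatch criterion fires as well.
    """
    if duration <= 0:
        raise ConfigError("cycling duration must be positive")
    fs = params.sample_rate
    fc = params.cycling_cadence
    t = np.arange(int(round(duration * fs))) / fs
    v = 0.06 * np.sin(2 * np.pi * fc * t)
    for t0 in np.arange(0.2, duration - 0.1, 1.0 / fc):
        v += 0.45 * _half_sine_pulse(t, t0, 0.05)
    ml = 0.14 * np.sin(2 * np.pi * (fc + 1.3) * t + 0.7)
    ap = 0.08 * np.sin(2 * np.pi * fc * t + 0.3)
    return np.column_stack([ap, ml, v])


# ---------------------------------------------------------------------------
# orientation-only trajectories (gravity-filter validation input)


def pitch_oscillation_trajectory(
    duration: float,
    amp: float = np.deg2rad(20.0),
    freq: float = 0.2,
    sample_rate: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic pure-pitch oscillation (analytic ground truth).

    Returns ``(accel, gyro, q_true)``: the accelerometer sees only the
    tilted gravity (z-component = cos(pitch)), the gyro is the exact
    pitch rate, and ``q_true`` is the sensor→world quaternion series.
    """
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    pitch = amp * np.sin(2 * np.pi * freq * t)
    rate = amp * 2 * np.pi * freq * np.cos(2 * np.pi * freq * t)
    gyro = np.column_stack([np.zeros_like(t), rate, np.zeros_like(t)])
    rot = Rotation.from_rotvec(np.outer(pitch, [0.0, 1.0, 0.0]))
    accel = rot.apply(G_UP, inverse=True)
    return accel, gyro, quat.from_scipy(rot)


def _body_rates_from_rotvec(r: np.ndarray, rdot: np.ndarray) -> np.ndarray:
    """Exact body-frame angular velocity of the trajectory q(t) = exp(r(t)).

    Uses the right Jacobian of SO(3): ω_body = J_r(r) ṙ with
    J_r = I − (1−cosθ)/θ² [r]× + (θ−sinθ)/θ³ [r]×², θ = |r|.
    """
    theta = np.linalg.norm(r, axis=1)
    theta = np.where(theta < 1e-12, 1e-12, theta)
    c1 = (1.0 - np.cos(theta)) / theta**2
    c2 = (theta - np.sin(theta)) / theta**3
    rxd = np.cross(r, rdot)
    rxxd = np.cross(r, rxd)
    return rdot - c1[:, None] * rxd + c2[:, None] * rxxd


def generate_orientation_trajectory(
    seed: int,
    duration: float,
    max_tilt: float = np.deg2rad(20.0),
    rate: float = 0.5,
    sample_rate: float = 100.0,
    n_components: int = 4,
    inertial_amp: float = 0.1,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random smooth yaw-free tilt trajectory with exact body-rate gyro.

    The orientation is q(t) = exp(r(t)) for a horizontal rotation vector
    r(t) = (r_x, r_y, 0) built from band-limited sinusoids — its axis is
    always perpendicular to gravity, so the trajectory contains no yaw
    and is directly comparable with the yaw-free gravity-filter output.
    The emitted gyro is the exact analytic body rate of the trajectory
    (which does include a body-frame z-rate), so integrating the gyro
    reproduces the orientation to integration precision.  Amplitudes are
    scaled to an RMS angular speed of ``rate`` (rad/s) and rescaled down
    if the tilt would exceed ``max_tilt``.  ``inertial_amp`` adds
    gait-band (≈ 1.9 Hz) world-frame inertial acceleration; ``noise_sd``
    adds white accelerometer noise.
    """
    if not max_tilt < np.pi / 2:
        raise ConfigError("max_tilt must be below pi/2")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate

    freqs = rng.uniform(0.08, 0.5, size=(2, n_components))
    phases = rng.uniform(0, 2 * np.pi, size=(2, n_components))
    amps = rng.uniform(0.5, 1.0, size=(2, n_components)) / freqs

    def rotvec(tgrid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        r = np.zeros((tgrid.size, 3))
        rd = np.zeros((tgrid.size, 3))
        for ax in range(2):
            for c in range(n_components):
                arg = 2 * np.pi * freqs[ax, c] * tgrid + phases[ax, c]
                # the −sin(φ) term anchors the trajectory at identity
                r[:, ax] += amps[ax, c] * (np.sin(arg) - np.sin(phases[ax, c]))
                rd[:, ax] += amps[ax, c] * 2 * np.pi * freqs[ax, c] * np.cos(arg)
        return r, rd

    r, rd = rotvec(t)
    w = _body_rates_from_rotvec(r, rd)
    scale = rate / max(np.sqrt(np.mean(np.sum(w**2, axis=1))), 1e-12)
    peak_tilt = scale * np.max(np.linalg.norm(r, axis=1))
    if peak_tilt > max_tilt:
        scale *= max_tilt / peak_tilt * 0.95
    r *= scale
    rd *= scale
    gyro = _body_rates_from_rotvec(r, rd)
    rot = Rotation.from_rotvec(r)
    q_true = quat.from_scipy(rot)
    accel = quat.rotate_inverse(q_true, G_UP)
    if inertial_amp > 0:
        f0 = rng.uniform(1.6, 2.2)
        inertial = np.column_stack(
            [
                inertial_amp * rng.uniform(0.3, 1.0)
                * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
                for _ in range(3)
            ]
        )
        accel = accel + quat.rotate_inverse(q_true, inertial)
    if noise_sd > 0:
        accel = accel + rng.normal(0.0, noise_sd, size=accel.shape)
    return accel, gyro, q_true


# ---------------------------------------------------------------------------
# full session generator


def generate_session(
    params: GaitGeneratorParams, duration: float
) -> tuple[ImuRecording, ImuRecording, GroundTruth]:
    """Generate one synchronized head+trunk session with ground truth.

    Timeline: knock — static calibration — five-nod calibration — an
    activity region of gait bouts, rests and occasional cycling blocks —
    knock.  The trunk recording defines the reference timeline; the head
    recording is emitted on its own clock (configured offset + drift).
    """
    if duration < 60.0:
        raise ConfigError(
            "duration must be at least 60 s to fit calibration and knocks"
        )
    p = params
    fs = p.sample_rate
    dt = 1.0 / fs
    rng = np.random.default_rng(p.seed)
    n = int(round(duration * fs))
    t = np.arange(n) * dt

    labels = np.full(n, "rest", dtype="<U18")
    trunk_inertial = np.zeros((n, 3))  # world frame, (AP, ML, V)
    head_inertial = np.zeros((n, 3))
    trunk_pitchvel = np.zeros(n)
    head_pitchvel = np.zeros(n)

    def mark(t0: float, t1: float, label: str) -> None:
        labels[int(round(t0 * fs)) : int(round(t1 * fs))] = label

    # --- fixed protocol events -------------------------------------------
    knock_times = np.array([1.0, duration - 2.0])
    static_iv = (3.0, 8.0)
    nod_iv = (9.0, 15.5)
    mark(*static_iv, "calibration-static")
    mark(*nod_iv, "calibration-nod")
    for tk in knock_times:
        mark(tk - 0.1, tk + 0.2, "knock")

    # five forward-pitch nods (head only)
    f_nod, a_nod = 0.8, 1.5
    nod_t0 = nod_iv[0] + 0.2
    nod_len = 5.0 / f_nod
    m = (t >= nod_t0) & (t < nod_t0 + nod_len)
    head_pitchvel[m] += a_nod * np.sin(2 * np.pi * f_nod * (t[m] - nod_t0))

    # --- gait / cycling blocks -------------------------------------------
    amps = {}
    hr_ap, hr_ml, hr_v = p.hr_targets
    rms_v = p.vertical_rms_mode
    amps["V"] = _harmonic_amplitudes(rms_v, hr_v, p.harmonic_decay, p.n_harmonics)
    amps["AP"] = _harmonic_amplitudes(
        rms_v * p.ap_scale, hr_ap, p.harmonic_decay, p.n_harmonics
    )
    # ML HR is odd/even, so the even:odd power ratio is its inverse
    amps["ML"] = _harmonic_amplitudes(
        rms_v * p.ml_scale, 1.0 / max(hr_ml, 1e-9), p.harmonic_decay, p.n_harmonics
    )
    axis_phase = {"AP": 0.25 * np.pi, "ML": 0.15 * np.pi, "V": 0.0}
    raw_phase = p.head_pitch_phase + np.pi / 2  # pitch-velocity lead vs V accel

    step_times: list[np.ndarray] = []
    step_freqs: list[np.ndarray] = []
    bout_bounds: list[tuple[int, int]] = []
    bout_lengths: list[int] = []
    bout_freqs: list[float] = []

    cursor = 17.0
    end_margin = duration - 5.0
    while True:
        if rng.random() < p.p_cycling:
            cyc_dur = rng.uniform(15.0, 40.0)
            if cursor + cyc_dur > end_margin:
                break
            i0 = int(round(cursor * fs))
            seg = generate_cycling_segment(p, cyc_dur)
            i1 = min(i0 + seg.shape[0], n)
            trunk_inertial[i0:i1] += seg[: i1 - i0]
            head_inertial[i0:i1] += seg[: i1 - i0] * 0.6
            labels[i0:i1] = "cycling"
            cursor = i1 * dt + max(
                p.rest_min, rng.lognormal(np.log(p.rest_mean), p.rest_sigma)
            )
            continue

        length = _sample_bout_length(rng, p)
        f_bout = float(
            np.clip(rng.normal(p.step_freq_mean, p.step_freq_sd), 0.5, 4.0)
        )
        # AR(1) within-bout jitter of the per-step frequency
        jitter = np.zeros(length)
        for i in range(1, length):
            jitter[i] = p.freq_jitter_ar * jitter[i - 1] + p.freq_jitter_sd * np.sqrt(
                1 - p.freq_jitter_ar**2
            ) * rng.standard_normal()
        f_steps = np.clip(f_bout + jitter, 0.5, 4.0)

        durs = 1.0 / f_steps[1:]
        peaks = cursor + np.concatenate([[0.0], np.cumsum(durs)])
        lead = 0.5 / f_steps[0]
        tail = 0.5 / f_steps[-1]
        if peaks[-1] + tail > end_margin:
            # truncate the bout to whatever still fits
            fit = np.flatnonzero(peaks + tail <= end_margin)
            if fit.size < 2:
                break
            length = int(fit[-1]) + 1
            f_steps = f_steps[:length]
            peaks = peaks[:length]
            tail = 0.5 / f_steps[-1]

        i0 = int(np.ceil((peaks[0] - lead) * fs))
        i1 = min(int(np.floor((peaks[-1] + tail) * fs)) + 1, n)
        tb = t[i0:i1]
        # stride phase: θ = 2π m at peak m
        idx = np.clip(np.searchsorted(peaks, tb, side="right") - 1, 0, length - 2)
        f_seg = f_steps[np.clip(idx + 1, 0, length - 1)]
        f_seg = np.where(tb < peaks[0], f_steps[0], f_seg)
        theta = 2 * np.pi * (idx + (tb - peaks[idx]) * f_seg)
        theta = np.where(
            tb < peaks[0], 2 * np.pi * (tb - peaks[0]) * f_steps[0], theta
        )
        env = np.ones_like(tb)
        pre = tb < peaks[0]
        env[pre] = np.cos(0.5 * np.pi * (peaks[0] - tb[pre]) / lead) ** 2
        post = tb > peaks[-1]
        env[post] = np.cos(0.5 * np.pi * (tb[post] - peaks[-1]) / tail) ** 2

        scale = float(
            np.clip(rng.lognormal(p.amp_sigma**2, p.amp_sigma), 0.7, 2.5)
        )
        ac_ap, ac_ml, ac_v = p.ac_targets
        for ax_i, (ax, ac) in enumerate(
            zip(("AP", "ML", "V"), (ac_ap, ac_ml, ac_v))
        ):
            wave = scale * env * _axis_waveform(theta, *amps[ax], axis_phase[ax])
            trunk_inertial[i0:i1, ax_i] += wave
            head_inertial[i0:i1, ax_i] += (1.0 - ac) * wave
        # zero the envelope-weighted mean so pitch returns to baseline after
        # every bout (otherwise short bouts leave a net pitch offset that
        # accumulates over the session)
        pv_shape = env * np.cos(theta + raw_phase)
        pv_shape -= env * (np.trapezoid(pv_shape) / max(np.trapezoid(env), 1e-12))
        head_pitchvel[i0:i1] += scale * p.head_pitch_amp * pv_shape
        trunk_pitchvel[i0:i1] += scale * p.trunk_pitch_amp * pv_shape
        labels[i0:i1] = "gait"

        step_times.append(peaks)
        step_freqs.append(f_steps)
        bout_bounds.append(
            (int(round(peaks[0] * fs)), int(round(peaks[-1] * fs)))
        )
        bout_lengths.append(length)
        bout_freqs.append(f_bout)

        cursor = peaks[-1] + tail + max(
            p.rest_min, rng.lognormal(np.log(p.rest_mean), p.rest_sigma)
        )
        if cursor > end_margin:
            break

    # --- kinematically consistent sensor outputs -------------------------
    mount = {
        "head": _euler_to_quat(p.mounting_head),
        "trunk": _euler_to_quat(p.mounting_trunk),
    }
    recs: dict[str, dict[str, np.ndarray]] = {}
    for placement, inertial, pitchvel in (
        ("trunk", trunk_inertial, trunk_pitchvel),
        ("head", head_inertial, head_pitchvel),
    ):
        pitch = np.concatenate(
            [[0.0], cumulative_trapezoid(pitchvel, dx=dt)]
        )
        r_body = Rotation.from_rotvec(np.outer(pitch, [0.0, 1.0, 0.0]))
        r_mount = quat.to_scipy(mount[placement])
        r_true = r_body * r_mount  # sensor -> world
        accel_sensor = r_true.apply(G_UP + inertial, inverse=True)
        omega_body = np.column_stack(
            [np.zeros_like(pitchvel), pitchvel, np.zeros_like(pitchvel)]
        )
        gyro_sensor = r_mount.apply(omega_body, inverse=True)
        recs[placement] = dict(
            accel=accel_sensor,
            gyro=gyro_sensor,
            q_true=quat.from_scipy(r_true),
            gravity=r_true.apply(G_UP, inverse=True),
        )

    # --- head device clock (offset + drift) ------------------------------
    head_t_dev = t  # the head device's own uniform grid
    tau = (head_t_dev - p.clock_offset) / (1.0 + p.clock_drift)
    tau = np.clip(tau, t[0], t[-1])
    head_accel = CubicSpline(t, recs["head"]["accel"], axis=0)(tau)
    head_gyro = CubicSpline(t, recs["head"]["gyro"], axis=0)(tau)

    # --- knocks (synchronous in true time) --------------------------------
    knock_scale = p.knock_amp
    for tk in knock_times:
        pulse_t = _half_sine_pulse(t, tk - p.knock_duration / 2, p.knock_duration)
        recs["trunk"]["accel"][:, 0] += knock_scale * pulse_t
        tk_dev = p.clock_offset + (1.0 + p.clock_drift) * tk
        pulse_h = _half_sine_pulse(
            head_t_dev, tk_dev - p.knock_duration / 2, p.knock_duration
        )
        head_accel[:, 0] += knock_scale * pulse_h

    # --- sensor noise ------------------------------------------------------
    def add_noise(accel: np.ndarray, gyro: np.ndarray) -> None:
        if p.accel_noise_sd > 0:
            accel += rng.normal(0.0, p.accel_noise_sd, size=accel.shape)
        if p.gyro_noise_sd > 0:
            gyro += rng.normal(0.0, p.gyro_noise_sd, size=gyro.shape)
        if p.gyro_drift_rate > 0:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            gyro += np.outer(t / 3600.0 * p.gyro_drift_rate, direction)

    add_noise(recs["trunk"]["accel"], recs["trunk"]["gyro"])
    add_noise(head_accel, head_gyro)

    trunk_rec = ImuRecording(
        timestamps=t,
        accel=recs["trunk"]["accel"],
        gyro=recs["trunk"]["gyro"],
        placement="trunk",
        sample_rate=fs,
    )
    head_rec = ImuRecording(
        timestamps=head_t_dev,
        accel=head_accel,
        gyro=head_gyro,
        placement="head",
        sample_rate=fs,
    )
    truth = GroundTruth(
        timestamps=t,
        true_step_times=(
            np.concatenate(step_times) if step_times else np.empty(0)
        ),
        true_step_freqs=(
            np.concatenate(step_freqs) if step_freqs else np.empty(0)
        ),
        true_bout_boundaries=bout_bounds,
        bout_lengths=np.asarray(bout_lengths, dtype=int),
        bout_freqs=np.asarray(bout_freqs, dtype=float),
        true_orientation={k: recs[k]["q_true"] for k in recs},
        true_gravity={k: recs[k]["gravity"] for k in recs},
        segment_labels=labels,
        knock_times=knock_times,
        mounting=mount,
        calibration_intervals={"static": static_iv, "nod": nod_iv},
        params=p,
    )
    return head_rec, trunk_rec, truth
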