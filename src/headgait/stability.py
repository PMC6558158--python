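"""Per-step head-stabilization measures: AC, HR, coherence, phase difference.

Attenuation coefficient
    ``AC = 1 − A_H / A_T`` from head and trunk RMS acceleration of the
    same step segment; positive values mean head accelerations are
    attenuated relative to the trunk.

Harmonic ratio
    Step-cycle acceleration is harmonic at multiples of the stride base
    frequency f_s = f_dom / 2 (a stride is two steps, so the step
    frequency f_dom is the second stride harmonic).  AP and V
    accelerations are biphasic within a stride — their regular content
    sits at the even stride harmonics k·f_dom — while ML acceleration is
    monophasic — odd stride harmonics (2k−1)·f_s.  With E and O the
    summed spectral power over the first N even/odd stride harmonics,
    HR = E/O for AP and V and HR = O/E for ML, so high HR always means
    regular gait.

Coherence
    Welch magnitude-squared coherence K²(f) = |S_xy|²/(S_xx·S_yy) over a
    1024-sample window split into 5 Blackman sub-segments of 512 samples
    advanced by 128 samples, evaluated at the grid bin nearest the
    predominant frequency.

Phase difference
    Lag of the cross-correlation peak between two 512-sample segments,
    converted to phase via the period of the first signal (estimated
    from its autocorrelation) and corrected by −π/2 so that phases
    between vertical *acceleration* and pitch *velocity* are comparable
    with vertical *displacement* vs. pitch *angle*: integrating a
    sinusoid shifts its phase by −π/2, so displacement-vs-angle =
    acceleration-vs-velocity + 2(−π/2) − (−π/2) = acceleration-vs-velocity − π/2.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import get_window

from .errors import ConfigError
from .spectral import StepSpectrum, extract_segment

#: phase correction (rad) mapping acceleration-vs-velocity phase onto
#: displacement-vs-angle phase for sinusoidal signals
PHASE_CORRECTION = -np.pi / 2


def attenuation_coefficient(rms_head: float, rms_trunk: float) -> float:
    """AC = 1 − rms_head / rms_trunk (NaN if the trunk RMS vanishes)."""
    if rms_trunk <= 0:
        return float("nan")
    return 1.0 - rms_head / rms_trunk


def harmonic_ratio(
    spectrum: StepSpectrum,
    f_dom: float,
    axis: str,
    n_harmonics: int = 10,
    cap: float = 100.0,
) -> float:
    """Even/odd harmonic power ratio of a step-centered spectrum.

    Each harmonic's power is read from the single nearest grid bin;
    harmonics above Nyquist are truncated.  A zero denominator returns
    the configurable ``cap``.
    """
    if axis not in ("AP", "ML", "V"):
        raise ConfigError(f"unknown axis {axis!r}")
    if not np.isfinite(f_dom) or f_dom <= 0:
        return float("nan")
    f_stride = f_dom / 2.0
    nyq = spectrum.sample_rate / 2.0
    even = np.array([k * f_dom for k in range(1, n_harmonics + 1)])
    odd = np.array([(2 * k - 1) * f_stride for k in range(1, n_harmonics + 1)])
    e = _bin_power_sum(spectrum, even[even <= nyq])
    o = _bin_power_sum(spectrum, odd[odd <= nyq])
    num, den = (o, e) if axis == "ML" else (e, o)
    if den <= 0:
        return cap
    return min(num / den, cap)


def _bin_power_sum(spectrum: StepSpectrum, freqs: np.ndarray) -> float:
    if freqs.size == 0:
        return 0.0
    idx = np.rint(freqs / spectrum.resolution).astype(int)
    idx = idx[(idx > 0) & (idx < spectrum.power.size)]
    return float(np.sum(spectrum.power[idx]))


def coherence_at_fdom(
    x: np.ndarray,
    y: np.ndarray,
    center: int,
    f_dom: float,
    sample_rate: float = 100.0,
    window_length: int = 1024,
    seglen: int = 512,
    hop: int = 128,
    window: str = "blackman",
) -> float:
    """Welch coherence of two step-centered windows at the dominant bin.

    The 1024-sample window yields exactly 5 sub-segments of 512 samples
    advanced by 128 (consecutive sub-segments overlap by 384), keeping
    the 100/512 Hz frequency resolution of the per-step spectra.
    Returns NaN if either signal has no power at the evaluated bin.
    """
    segx = extract_segment(x, center, window_length)
    segy = extract_segment(y, center, window_length)
    w = get_window(window, seglen, fftbins=True)
    n_segs = (window_length - seglen) // hop + 1
    sxx = np.zeros(seglen // 2 + 1)
    syy = np.zeros(seglen // 2 + 1)
    sxy = np.zeros(seglen // 2 + 1, dtype=complex)
    for i in range(n_segs):
        sl = slice(i * hop, i * hop + seglen)
        fx = np.fft.rfft(w * segx[sl])
        fy = np.fft.rfft(w * segy[sl])
        sxx += np.abs(fx) ** 2
        syy += np.abs(fy) ** 2
        sxy += np.conj(fx) * fy
    k = int(np.rint(f_dom * seglen / sample_rate))
    k = min(max(k, 0), seglen // 2)
    if sxx[k] <= 0 or syy[k] <= 0:
        return float("nan")
    coh = np.abs(sxy[k]) ** 2 / (sxx[k] * syy[k])
    return float(min(max(coh, 0.0), 1.0))


def _parabolic_refine(values: np.ndarray, i: int) -> float:
    """Sub-sample peak location by parabolic interpolation around index i."""
    if i <= 0 or i >= values.size - 1:
        return float(i)
    a, b, c = values[i - 1], values[i], values[i + 1]
    den = a - 2 * b + c
    if den == 0:
        return float(i)
    return i + 0.5 * (a - c) / den


def estimate_period(x: np.ndarray) -> float:
    """Period of a quasi-periodic segment (samples), from autocorrelation.

    First local maximum of the autocorrelation beyond lag zero, refined
    by parabolic interpolation.  Returns NaN for aperiodic input.
    """
    x = np.asarray(x, dtype=float)
    x = x - np.mean(x)
    if not np.any(x):
        return float("nan")
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    # skip the zero-lag lobe: first positive-going zero crossing
    neg = np.flatnonzero(ac < 0)
    if neg.size == 0:
        return float("nan")
    start = neg[0]
    rest = ac[start:]
    peaks = np.flatnonzero((rest[1:-1] > rest[:-2]) & (rest[1:-1] >= rest[2:])) + 1
    if peaks.size == 0:
        return float("nan")
    i = start + peaks[0]
    return _parabolic_refine(ac, i)


def phase_difference(
    x: np.ndarray,
    y: np.ndarray,
    center: int,
    correction: float = PHASE_CORRECTION,
    seglen: int = 512,
    window: str = "blackman",
) -> float:
    """Corrected phase of y relative to x (rad, wrapped to (−π, π]).

    Both 512-sample segments are mean-removed and Blackman-weighted to
    suppress edge effects.  The cross-correlation peak is searched
    within ±1 period of x (period from :func:`estimate_period`) and
    refined by parabolic interpolation; a positive lag (y delayed)
    yields a negative phase.  Returns NaN if x is aperiodic.
    """
    w = get_window(window, seglen, fftbins=True)
    segx = extract_segment(x, center, seglen)
    segy = extract_segment(y, center, seglen)
    # a segment that is constant up to floating-point cancellation has no
    # period; the threshold is relative, so the check stays scale-invariant
    if np.max(np.abs(segx - np.mean(segx))) <= 1e-9 * max(
        np.max(np.abs(segx)), 1e-300
    ):
        return float("nan")
    segx = (segx - np.mean(segx)) * w
    segy = (segy - np.mean(segy)) * w
    period = estimate_period(segx)
    if not np.isfinite(period) or period <= 0:
        return float("nan")
    # cc[lag + seglen - 1] = sum_t x(t) y(t + lag)
    cc = np.correlate(segy, segx, mode="full")
    lags = np.arange(-(seglen - 1), seglen)
    keep = np.abs(lags) <= period
    if not keep.any():
        return float("nan")
    sub = cc[keep]
    sub_lags = lags[keep]
    i = int(np.argmax(sub))
    lag = sub_lags[0] + _parabolic_refine(sub, i)
    phase = -2.0 * np.pi * lag / period + correction
    return float(wrap_phase(phase))


def wrap_phase(phase: float | np.ndarray) -> float | np.ndarray:
    """Wrap angle(s) to (−π, π]."""
    return -((-np.asarray(phase) + np.pi) % (2.0 * np.pi) - np.pi)
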