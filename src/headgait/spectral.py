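"""Short-time power spectra, predominant frequency, and segment RMS.

Every detected step gets a power spectrum of the acceleration in a
segment centered on the step peak: 1024 samples (Blackman window) for
step classification, 512 samples for the per-step analysis measures.
At 100 Hz a 512-sample spectrum has a grid spacing of 100/512 ≈
0.195 Hz; the 1024-sample grid is twice as fine and contains the coarse
grid as a subset.  Segments that overrun the recording edges are
zero-padded symmetrically.

Power is normalized so that Parseval holds for the windowed segment:
``sum(power) == sum((w·x)**2)``.  Only ratios and argmaxes of the power
are used downstream, so the normalization convention is free; Parseval
makes it easy to verify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .errors import ConfigError, DataError


@dataclass
class StepSpectrum:
    """One-sided power spectrum of a windowed, step-centered segment."""

    freqs: np.ndarray
    power: np.ndarray
    segment_length: int
    window: str
    center_index: int
    sample_rate: float = 100.0

    @property
    def resolution(self) -> float:
        return self.sample_rate / self.segment_length


def extract_segment(signal: np.ndarray, center: int, seglen: int) -> np.ndarray:
    """Segment of ``seglen`` samples centered on ``center``.

    Samples beyond the recording edges are zero (symmetric zero-padding:
    the returned segment always has the peak at index ``seglen // 2``).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise DataError("signal must be one-dimensional")
    if seglen > signal.size:
        raise DataError(f"segment length {seglen} exceeds signal length {signal.size}")
    half = seglen // 2
    out = np.zeros(seglen)
    lo = center - half
    hi = lo + seglen
    src_lo, src_hi = max(lo, 0), min(hi, signal.size)
    out[src_lo - lo : src_hi - lo] = signal[src_lo:src_hi]
    return out


def step_spectrum(
    signal: np.ndarray,
    center: int,
    seglen: int = 1024,
    window: str = "blackman",
    sample_rate: float = 100.0,
) -> StepSpectrum:
    """Windowed periodogram of the step-centered segment."""
    if seglen < 2 or seglen & (seglen - 1):
        raise ConfigError(f"segment length must be a power of two, got {seglen}")
    seg = extract_segment(signal, center, seglen)
    w = get_window(window, seglen, fftbins=True)
    spec = np.fft.rfft(w * seg)
    # one-sided power with Parseval normalization: sum(power) == sum((w x)^2)
    power = np.abs(spec) ** 2 / seglen
    power[1:] *= 2.0
    if seglen % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(seglen, d=1.0 / sample_rate)
    return StepSpectrum(
        freqs=freqs,
        power=power,
        segment_length=seglen,
        window=window,
        center_index=center,
        sample_rate=sample_rate,
    )


def predominant_frequency(
    spectrum: StepSpectrum, band: tuple[float, float] | None = None
) -> float:
    """Frequency of maximum spectral power (DC excluded).

    The DC bin is excluded so that residual gravity cannot win the
    argmax.  Ties break toward the lower frequency.  Returns NaN for an
    all-zero spectrum.
    """
    freqs, power = spectrum.freqs, spectrum.power
    mask = freqs > 0
    if band is not None:
        lo, hi = band
        if not lo < hi:
            raise ConfigError(f"empty frequency band ({lo}, {hi})")
        mask &= (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ConfigError("frequency band contains no grid point")
    p = np.where(mask, power, -np.inf)
    if np.max(p) <= 0:
        return float("nan")
    return float(freqs[int(np.argmax(p))])


def segment_rms(
    signal: np.ndarray,
    center: int,
    seglen: int = 512,
    window: str | None = None,
) -> float:
    """Root mean square of the step-centered segment.

    With ``window`` set, the segment is window-weighted and the RMS is
    normalized by the window's own RMS (``sqrt(Σ(wx)² / Σw²)``), so a
    constant signal keeps its value; the attenuation-coefficient ratio
    uses Blackman weighting to de-emphasize non-locomotor samples at the
    segment edges.
    """
    seg = extract_segment(signal, center, seglen)
    if window is None:
        return float(np.sqrt(np.mean(seg**2)))
    w = get_window(window, seglen, fftbins=True)
    return float(np.sqrt(np.sum((w * seg) ** 2) / np.sum(w**2)))
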