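"""Step detection, cycling exclusion, bout grouping, and frequency gating.

Candidate steps are peaks of the vertical trunk inertial acceleration
(minimum height 0.2 g, prominence 0.4 g, minimum separation 0.2 s — the
separation corresponds to a maximum detectable step frequency of 5 Hz).
Cycling-like periods pass the peak detector but show low vertical RMS
and mismatched vertical vs. medial/lateral predominant frequencies;
steps failing either criterion are excluded.  Surviving steps are
grouped into bouts wherever consecutive peaks are less than 1 s apart
(peak-to-peak); single-step bouts are discarded.  Finally, analysis is
restricted to steps whose head vertical predominant frequency lies in
[1, 2.6] Hz, the range over which predominant frequency is a usable
proxy for walking speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import DataError

#: exclusion reason codes attached to steps by the pipeline
REASONS = ("cycling", "single_step_bout", "out_of_gate")


@dataclass
class StepEvent:
    """A candidate step with its per-axis spectral features.

    ``pred_freq`` / ``rms`` are trunk features in axis order (AP, ML, V);
    ``head_pred_freq_v`` (attached later in the pipeline) keys the
    frequency gate.
    """

    peak_index: int
    peak_time: float
    pred_freq: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    rms: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    head_pred_freq_v: float = float("nan")

    @property
    def pred_freq_v(self) -> float:
        return float(self.pred_freq[2])

    @property
    def pred_freq_ml(self) -> float:
        return float(self.pred_freq[1])

    @property
    def rms_v(self) -> float:
        return float(self.rms[2])


@dataclass
class Bout:
    """A maximal run of steps with inter-step gaps below the bout gap."""

    steps: list[StepEvent]

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def start_time(self) -> float:
        return self.steps[0].peak_time

    @property
    def end_time(self) -> float:
        return self.steps[-1].peak_time

    @property
    def mean_pred_freq_v(self) -> float:
        return float(np.nanmean([s.pred_freq_v for s in self.steps]))

    @property
    def sd_pred_freq_v(self) -> float:
        return float(np.nanstd([s.pred_freq_v for s in self.steps], ddof=0))


def detect_step_peaks(
    trunk_aligned_v: np.ndarray,
    sample_rate: float = 100.0,
    min_height: float = 0.2,
    min_prominence: float = 0.4,
    min_distance: float = 0.2,
) -> np.ndarray:
    """Indices of candidate step peaks in vertical trunk acceleration."""
    v = np.asarray(trunk_aligned_v, dtype=float)
    if v.size < 3:
        raise DataError("signal too short for peak detection")
    distance = max(1, int(round(min_distance * sample_rate)))
    idx, _ = find_peaks(
        v, height=min_height, prominence=min_prominence, distance=distance
    )
    return idx


def classify_cycling(
    step: StepEvent,
    rms_threshold: float = 0.1,
    freq_mismatch_threshold: float = 0.5,
) -> bool:
    """True if the step looks like cycling rather than walking.

    Cycling produces periodic vertical peaks with little vertical energy
    and with vertical and medial/lateral predominant frequencies that do
    not match; a step is flagged when vertical RMS < ``rms_threshold``
    (g) or |f_V − f_ML| > ``freq_mismatch_threshold`` (Hz).
    """
    if step.rms_v < rms_threshold:
        return True
    if abs(step.pred_freq_v - step.pred_freq_ml) > freq_mismatch_threshold:
        return True
    return False


def group_bouts(steps: list[StepEvent], max_gap: float = 1.0) -> list[Bout]:
    """Group time-sorted steps into bouts; single-step runs are dropped."""
    bouts: list[Bout] = []
    run: list[StepEvent] = []
    for step in steps:
        if run and step.peak_time - run[-1].peak_time >= max_gap:
            if len(run) >= 2:
                bouts.append(Bout(steps=run))
            run = []
        run.append(step)
    if len(run) >= 2:
        bouts.append(Bout(steps=run))
    return bouts


def frequency_gate(
    steps: list[StepEvent], low: float = 1.0, high: float = 2.6
) -> list[StepEvent]:
    """Retain steps whose head vertical predominant frequency ∈ [low, high]."""
    return [s for s in steps if low <= s.head_pred_freq_v <= high]
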