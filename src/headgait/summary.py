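"""Frequency-binned boxplot summaries and the Kruskal–Wallis effect size.

Every stability measure is summarized as a function of head vertical
predominant frequency, which only takes values on the 512-sample
spectral grid (spacing 100/512 Hz); the summary bins are those grid
frequencies within the analysis gate.  The strength of the frequency
dependence is reported as the Kruskal–Wallis effect size
η² = (H − k + 1)/(n − k) with the conventional thresholds: small below
0.04, intermediate up to 0.11, large above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

GRID_SPACING = 100.0 / 512.0


@dataclass
class EffectSize:
    """Kruskal–Wallis effect size with its conventional label."""

    eta_squared: float
    label: str
    p_value: float
    h_statistic: float
    k_groups: int
    n_samples: int


def effect_size_label(eta_squared: float) -> str:
    if eta_squared < 0.04:
        return "small"
    if eta_squared <= 0.11:
        return "intermediate"
    return "large"


def kruskal_eta_squared(groups: list[np.ndarray]) -> EffectSize:
    """Kruskal–Wallis test with η² effect size across ≥ 2 groups.

    H is tie-corrected.  η² may come out slightly negative under the
    null (near-identical groups); it is reported as computed and labeled
    small.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise DataError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise DataError("empty group")
    n = sum(g.size for g in groups)
    if n <= k:
        raise DataError("need more samples than groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise DataError("all values identical; H is undefined under full ties")
    h, p = stats.kruskal(*groups)
    eta = (h - k + 1) / (n - k)
    return EffectSize(
        eta_squared=float(eta),
        label=effect_size_label(float(eta)),
        p_value=float(p),
        h_statistic=float(h),
        k_groups=k,
        n_samples=n,
    )


def frequency_bins(
    low: float = 1.0, high: float = 2.6, spacing: float = GRID_SPACING
) -> np.ndarray:
    """Spectral-grid bin centers spanning [low, high]."""
    k_lo = int(np.ceil(low / spacing - 1e-9))
    k_hi = int(np.floor(high / spacing + 1e-9))
    return np.arange(k_lo, k_hi + 1) * spacing


def binned_boxstats(
    values: np.ndarray,
    bin_keys: np.ndarray,
    bin_width: float = GRID_SPACING,
    low: float = 1.0,
    high: float = 2.6,
) -> pd.DataFrame:
    """Per-frequency-bin boxplot statistics of a measure.

    ``bin_keys`` (Hz, typically head vertical predominant frequencies)
    are assigned to the nearest spectral-grid bin center.  Quartiles use
    linear interpolation; whiskers follow the 1.5·IQR rule (most extreme
    sample within 1.5·IQR of the nearer quartile); outliers are counted,
    not listed.  Empty bins yield n = 0 with NaN statistics.
    """
    values = np.asarray(values, dtype=float)
    bin_keys = np.asarray(bin_keys, dtype=float)
    if values.shape != bin_keys.shape:
        raise DataError("values and bin_keys must have equal length")
    centers = frequency_bins(low, high, bin_width)
    assignment = np.rint(bin_keys / bin_width).astype(int)
    rows = []
    for c in centers:
        k = int(np.rint(c / bin_width))
        sel = values[(assignment == k) & np.isfinite(values)]
        if sel.size == 0:
            rows.append(
                dict(
                    bin_center=c, n=0, q1=np.nan, median=np.nan, q3=np.nan,
                    whisker_low=np.nan, whisker_high=np.nan, n_outliers=0,
                )
            )
            continue
        q1, med, q3 = np.percentile(sel, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = sel[(sel >= lo_fence) & (sel <= hi_fence)]
        rows.append(
            dict(
                bin_center=c,
                n=int(sel.size),
                q1=q1,
                median=med,
                q3=q3,
                whisker_low=float(np.min(inside)),
                whisker_high=float(np.max(inside)),
                n_outliers=int(sel.size - inside.size),
            )
        )
    return pd.DataFrame(rows)
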