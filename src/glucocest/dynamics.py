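"""Dynamic glucoCEST analysis: delta-ST maps, enhanced-pixel fractions,
ROI time courses and the group statistics.

Contrast is reported as the post-minus-pre change in the saturation
transfer fraction, in percentage points:

    dST% = (ST_post - ST_pre) * 100

The enhanced-pixel fraction is the percentage of tumor-ROI voxels with
dST% > 0.  Group differences over time are tested with one-way ANOVA
across frames followed by Dunnett's two-sided multiple comparisons of each
later frame against the first post-injection frame.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .zspectrum import STMap

__all__ = [
    "DeltaSTMap",
    "delta_st",
    "enhanced_fraction",
    "roi_time_course",
    "DunnettResult",
    "anova_dunnett",
]


@dataclass
class DeltaSTMap:
    """Post-minus-pre ST change in percentage points, on the joint mask."""

    values: np.ndarray
    mask: np.ndarray
    frame_time: float | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    def masked(self) -> np.ndarray:
        return np.where(self.mask, self.values, np.nan)


def delta_st(pre: STMap, post: STMap, frame_time: float | None = None) -> DeltaSTMap:
    """dST% map: (ST_post - ST_pre) * 100 on the intersection of masks."""
    if pre.values.shape != post.values.shape:
        raise ValueError(
            f"geometry mismatch: pre {pre.values.shape} vs post {post.values.shape}"
        )
    if not math.isclose(pre.analysis_offset, post.analysis_offset):
        raise ValueError(
            f"analysis offsets differ: {pre.analysis_offset} vs {post.analysis_offset}"
        )
    mask = pre.mask & post.mask
    vals = np.where(mask, (post.values - pre.values) * 100.0, np.nan)
    return DeltaSTMap(vals, mask, frame_time)


def enhanced_fraction(dmap: DeltaSTMap, roi: np.ndarray) -> float:
    """Percentage of ROI voxels (on the valid mask) with dST% > 0.

    Returns NaN with a warning when the ROI does not intersect the valid
    mask — an undefined fraction, not zero.
    """
    roi = np.asarray(roi).astype(bool)
    sel = roi & dmap.mask
    n = int(sel.sum())
    if n == 0:
        warnings.warn("ROI does not intersect the valid mask; enhanced fraction undefined")
        return math.nan
    return 100.0 * float(np.sum(dmap.values[sel] > 0)) / n


def roi_time_course(
    maps: Sequence[DeltaSTMap],
    roi: np.ndarray,
    subject: str = "s1",
    group: str = "",
    dose: float = math.nan,
    roi_id: int = 1,
) -> pd.DataFrame:
    """Per-frame ROI statistics: mean and sd of dST%, enhanced fraction.

    One row per frame, in the order given; frame times are taken from the
    maps (index used when absent).
    """
    rows = []
    for i, m in enumerate(maps):
        sel = np.asarray(roi).astype(bool) & m.mask
        vals = m.values[sel]
        rows.append(
            {
                "subject": subject,
                "group": group,
                "dose_g_per_kg": dose,
                "frame_time_min": m.frame_time if m.frame_time is not None else float(i),
                "roi": roi_id,
                "mean_dst_pct": float(np.mean(vals)) if len(vals) else math.nan,
                "sd_dst_pct": float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan,
                "enhanced_fraction_pct": enhanced_fraction(m, roi) if len(vals) else math.nan,
                "n_voxels": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DunnettResult:
    """One-way ANOVA across frames plus Dunnett comparisons vs. reference."""

    f_statistic: float
    anova_p: float
    frame_labels: list
    reference_label: object
    dunnett_statistics: np.ndarray  # one per non-reference frame
    dunnett_pvalues: np.ndarray
    significant: np.ndarray  # at alpha
    alpha: float
    degenerate: bool = False


def anova_dunnett(
    measurements: np.ndarray | pd.DataFrame,
    baseline_frame: int = 0,
    alpha: float = 0.05,
    frame_labels: Sequence | None = None,
) -> DunnettResult:
    """Test dST% differences over time against a reference frame.

    Parameters
    ----------
    measurements : array (subjects x frames) or DataFrame
        Per-subject ROI-mean dST% at each time point.  A DataFrame must
        have columns ``subject``, ``frame_time_min`` and ``mean_dst_pct``.
    baseline_frame : int
        Column index of the reference frame (the first post-injection
        frame in the standard protocol).

    Degenerate input (zero variance everywhere) is flagged rather than
    raising; no comparison is then significant.
    """
    if isinstance(measurements, pd.DataFrame):
        wide = measurements.pivot_table(
            index="subject", columns="frame_time_min", values="mean_dst_pct"
        ).sort_index(axis=1)
        frame_labels = list(wide.columns)
        data = wide.to_numpy()
    else:
        data = np.asarray(measurements, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a subjects x frames array with >= 2 frames")
    if data.shape[0] < 2:
        raise ValueError("need >= 2 subjects per frame")
    n_frames = data.shape[1]
    if frame_labels is None:
        frame_labels = list(range(n_frames))
    if not (0 <= baseline_frame < n_frames):
        raise ValueError(f"baseline_frame {baseline_frame} out of range")

    cols = [data[:, j] for j in range(n_frames)]
    others = [j for j in range(n_frames) if j != baseline_frame]
    if all(np.ptp(c) == 0 for c in cols):
        return DunnettResult(
            math.nan, math.nan, list(frame_labels), frame_labels[baseline_frame],
            np.full(len(others), np.nan), np.full(len(others), np.nan),
            np.zeros(len(others), dtype=bool), alpha, degenerate=True,
        )
    f_stat, anova_p = stats.f_oneway(*cols)
    res = stats.dunnett(*[cols[j] for j in others], control=cols[baseline_frame])
    pvals = np.asarray(res.pvalue, dtype=float)
    return DunnettResult(
        float(f_stat), float(anova_p), list(frame_labels), frame_labels[baseline_frame],
        np.asarray(res.statistic, dtype=float), pvals, pvals < alpha, alpha,
    )
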