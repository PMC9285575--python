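"""Voxel-wise Z-spectrum processing: segmentation, smoothing-spline
interpolation, B0 correction, asymmetry ST computation and quality
filtering.

The per-voxel chain is: threshold-segment the S0 image; fit each voxel's
Z-spectrum with a smoothing spline; locate the bulk-water resonance as the
minimum of the smooth curve; shift the spectrum so water sits at 0 ppm;
compute the saturation-transfer fraction

    ST = (S(-dw) - S(+dw)) / S0

on the corrected smooth curve (S0 = smoothed signal at -10 ppm of the
uncorrected spectrum); and keep only voxels whose spline explains the raw
data well (R^2 strictly above 0.97 by default), which discards voxels whose
spectra are noise-dominated.

Smoothing-parameter choice: for a single voxel the default is
generalized-cross-validation (GCV) selection.  For whole stacks the GCV
optimisation per voxel is wasteful, so ``st_map`` calibrates one smoothing
parameter per stack by k-fold cross-validation on a voxel subsample and
reuses it for every voxel.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import BSpline, make_smoothing_spline

from .centering import plateau_center
from .containers import ZSpectrum, ZSpectrumStack

__all__ = [
    "VoxelFit",
    "STMap",
    "ProcessingConfig",
    "segment_foreground",
    "fit_voxel",
    "calibrate_smoothing",
    "correct_b0",
    "compute_st",
    "filter_quality",
    "st_map",
]

log = logging.getLogger(__name__)

DENSE_GRID_PPM = 0.005
WATER_SEARCH_PPM = 1.5


@dataclass
class VoxelFit:
    """Smoothing-spline fit of one voxel's Z-spectrum."""

    spline: BSpline | None
    water_center: float
    r2: float
    valid: bool
    support: tuple[float, float]  # sampled offset range (ascending)

    def curve(self, ppm: np.ndarray) -> np.ndarray:
        """Smoothed spectrum at ``ppm``; NaN outside the sampled support."""
        ppm = np.asarray(ppm, dtype=float)
        if self.spline is None:
            return np.full(ppm.shape, np.nan)
        out = np.asarray(self.spline(ppm), dtype=float)
        lo, hi = self.support
        return np.where((ppm >= lo) & (ppm <= hi), out, np.nan)


@dataclass
class STMap:
    """Per-voxel saturation-transfer map with validity mask."""

    values: np.ndarray
    mask: np.ndarray
    analysis_offset: float
    # diagnostics from the per-voxel chain
    r2: np.ndarray | None = None
    shift: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    def masked(self) -> np.ndarray:
        out = np.where(self.mask, self.values, np.nan)
        return out


@dataclass(frozen=True)
class ProcessingConfig:
    """Tunables of the per-voxel chain (defaults follow the protocol)."""

    analysis_offset: float = 1.2
    r2_threshold: float = 0.97
    segmentation_fraction: float = 0.1
    smoothing: float | None = None  # None = cross-validated per stack
    max_shift_ppm: float = WATER_SEARCH_PPM
    calibration_voxels: int = 48
    seed: int = 0


def segment_foreground(stack: ZSpectrumStack, threshold_fraction: float = 0.1) -> np.ndarray:
    """Foreground mask: S0 at or above a fraction of its 99th percentile.

    Interior holes are filled; an empty result warns instead of raising.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    s0 = stack.s0_image
    ref = np.percentile(s0, 99)
    mask = s0 >= threshold_fraction * ref
    if ref <= 0 or not mask.any():
        warnings.warn("segmentation produced an empty foreground mask")
        return np.zeros(stack.shape, dtype=bool)
    mask = ndimage.binary_fill_holes(mask)
    return mask


def _r2(raw: np.ndarray, fitted: np.ndarray) -> float:
    ss_tot = float(np.sum((raw - raw.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - float(np.sum((raw - fitted) ** 2)) / ss_tot


def fit_voxel(
    offsets: np.ndarray,
    signals: np.ndarray,
    smoothing: float | None = None,
    max_shift_ppm: float = WATER_SEARCH_PPM,
) -> VoxelFit:
    """Smoothing-spline fit plus water-centre and goodness-of-fit estimate.

    Parameters
    ----------
    smoothing : float or None
        Spline roughness penalty ``lam``; None selects it by GCV.
    max_shift_ppm : float
        Half-width of the water-centre search window around 0 ppm.

    The water centre is located on a dense (0.005 ppm) grid inside the
    search window as the midpoint of the deepest plateau of the smooth
    curve (the argmin when the bottom is curved; robust when saturation
    flattens it).  All-constant or non-finite spectra are invalid with
    r2 = 0.
    """
    offsets = np.asarray(offsets, dtype=float)
    signals = np.asarray(signals, dtype=float)
    order = np.argsort(offsets)
    x, y = offsets[order], signals[order]
    support = (float(x[0]), float(x[-1]))
    bad = VoxelFit(None, math.nan, 0.0, False, support)
    if len(x) < 15:
        raise ValueError(f"need >= 15 offsets spanning water, got {len(x)}")
    if not np.all(np.isfinite(y)) or np.ptp(y) == 0.0:
        return bad
    try:
        spline = make_smoothing_spline(x, y, lam=smoothing)
    except Exception:  # pragma: no cover - degenerate numerical input
        return bad
    fitted = spline(x)
    r2 = max(0.0, min(1.0, _r2(y, fitted)))

    half = min(max_shift_ppm, -support[0], support[1])
    grid = np.arange(-half, half + DENSE_GRID_PPM / 2, DENSE_GRID_PPM)
    vals = spline(grid)
    center = plateau_center(grid, vals)
    return VoxelFit(spline, center, r2, True, support)


def calibrate_smoothing(
    stack: ZSpectrumStack,
    mask: np.ndarray,
    n_sample: int = 48,
    seed: int = 0,
    lam_grid: np.ndarray | None = None,
    n_folds: int = 5,
) -> float:
    """One smoothing parameter for a whole stack by k-fold cross-validation.

    Fits each candidate ``lam`` on a subsample of foreground voxels with
    every ``n_folds``-th offset held out and picks the lam minimising the
    summed held-out squared error.
    """
    if lam_grid is None:
        lam_grid = np.logspace(-7, 2, 19)
    idx = np.argwhere(mask)
    if len(idx) == 0:
        return float(lam_grid[len(lam_grid) // 2])
    rng = np.random.default_rng(seed)
    take = idx[rng.choice(len(idx), size=min(n_sample, len(idx)), replace=False)]
    order = np.argsort(stack.offsets)
    x = stack.offsets[order]
    errs = np.zeros(len(lam_grid))
    for r, c in take:
        y = stack.data[r, c, :][order]
        if not np.all(np.isfinite(y)) or np.ptp(y) == 0:
            continue
        for fold in range(n_folds):
            test = np.zeros(len(x), dtype=bool)
            test[fold::n_folds] = True
            # keep both endpoints in training to avoid extrapolation
            test[0] = test[-1] = False
            xt, yt = x[~test], y[~test]
            for i, lam in enumerate(lam_grid):
                sp = make_smoothing_spline(xt, yt, lam=lam)
                errs[i] += float(np.sum((sp(x[test]) - y[test]) ** 2))
    return float(lam_grid[int(np.argmin(errs))])


def correct_b0(
    fit: VoxelFit, offsets: np.ndarray, max_shift_ppm: float = WATER_SEARCH_PPM
) -> ZSpectrum:
    """Shift the smooth spectrum so bulk water sits at 0 ppm.

    The corrected spectrum is the smooth curve evaluated at
    ``offset + water_center``; points falling outside the sampled support
    are NaN (missing), never extrapolated.
    """
    if not fit.valid:
        raise ValueError("cannot B0-correct an invalid voxel fit")
    if abs(fit.water_center) > max_shift_ppm:
        raise ValueError(
            f"water centre {fit.water_center:.3f} ppm beyond the allowed "
            f"+/-{max_shift_ppm} ppm"
        )
    offsets = np.asarray(offsets, dtype=float)
    vals = fit.curve(offsets + fit.water_center)
    return ZSpectrum(offsets, np.clip(vals, 0.0, None))


def compute_st(spectrum: ZSpectrum, analysis_offset: float, s0: float) -> float:
    """Asymmetry saturation-transfer fraction (S(-dw) - S(+dw)) / S0.

    Returns NaN when either +/-analysis_offset lies outside the spectrum's
    support or ``s0`` is not positive (voxel invalid).
    """
    if s0 is None or not np.isfinite(s0) or s0 <= 0:
        return math.nan
    lo = spectrum.signal_at(-analysis_offset)
    hi = spectrum.signal_at(analysis_offset)
    if not (np.isfinite(lo) and np.isfinite(hi)):
        return math.nan
    return (lo - hi) / s0


def filter_quality(
    r2: np.ndarray,
    valid: np.ndarray,
    foreground: np.ndarray | None = None,
    r2_threshold: float = 0.97,
) -> np.ndarray:
    """Validity mask: voxel valid, in foreground, and r2 strictly above threshold."""
    if not (0.0 < r2_threshold < 1.0):
        raise ValueError("r2_threshold must be in (0, 1)")
    mask = (r2 > r2_threshold) & valid.astype(bool)
    if foreground is not None:
        mask &= foreground.astype(bool)
    return mask


def st_map(stack: ZSpectrumStack, config: ProcessingConfig = ProcessingConfig()) -> STMap:
    """Full per-voxel chain: segment, fit, B0-correct, ST, quality filter."""
    fg = segment_foreground(stack, config.segmentation_fraction)
    rows, cols = stack.shape
    st = np.full((rows, cols), np.nan)
    r2 = np.zeros((rows, cols))
    shift = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)
    if not fg.any():
        return STMap(st, valid, config.analysis_offset, r2, shift)

    lam = config.smoothing
    if lam is None:
        lam = calibrate_smoothing(
            stack, fg, n_sample=config.calibration_voxels, seed=config.seed
        )
        log.info("calibrated smoothing lam=%.3g", lam)

    offsets = stack.offsets
    n_shift_rejected = 0
    for r, c in np.argwhere(fg):
        fit = fit_voxel(offsets, stack.data[r, c, :], smoothing=lam,
                        max_shift_ppm=config.max_shift_ppm)
        r2[r, c] = fit.r2
        if not fit.valid:
            continue
        if abs(fit.water_center) > config.max_shift_ppm:
            n_shift_rejected += 1
            continue
        shift[r, c] = fit.water_center
        corrected = correct_b0(fit, offsets, config.max_shift_ppm)
        s0 = fit.curve(np.array([stack.s0_offset]))[0]
        if not np.isfinite(s0):
            # S0 offset not sampled: fall back to the most negative offset
            s0 = fit.curve(np.array([min(offsets.min(), offsets.max())]))[0]
            log.warning("S0 offset %.1f ppm not in sampled range; using edge", stack.s0_offset)
        val = compute_st(corrected, config.analysis_offset, s0)
        if np.isfinite(val):
            st[r, c] = val
            valid[r, c] = True
    mask = filter_quality(r2, valid, fg, config.r2_threshold)
    log.info(
        "st_map: %d foreground, %d valid, %d pass r2>%.2f, %d shift-rejected",
        int(fg.sum()), int(valid.sum()), int(mask.sum()), config.r2_threshold,
        n_shift_rejected,
    )
    st[~mask] = np.nan
    return STMap(st, mask, config.analysis_offset, r2, shift)
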