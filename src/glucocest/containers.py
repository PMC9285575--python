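"""In-memory containers for Z-spectra and image stacks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ZSpectrum", "ZSpectrumStack"]


@dataclass
class ZSpectrum:
    """A single Z-spectrum: saturation offsets (ppm) and normalized signal.

    Signals may contain NaN to mark offsets without support (e.g. after a
    B0 shift); offsets must be strictly monotone.
    """

    offsets: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.offsets.ndim != 1 or self.offsets.shape != self.signals.shape:
            raise ValueError("offsets and signals must be 1-D and equal length")
        d = np.diff(self.offsets)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("offsets must be strictly monotone")
        finite = self.signals[np.isfinite(self.signals)]
        if np.any(finite < 0):
            raise ValueError("signals must be non-negative")

    @property
    def ascending(self) -> "ZSpectrum":
        """View with offsets sorted ascending."""
        if len(self.offsets) and self.offsets[0] > self.offsets[-1]:
            return ZSpectrum(self.offsets[::-1].copy(), self.signals[::-1].copy())
        return self

    def signal_at(self, ppm: float) -> float:
        """Linear interpolation of the raw samples at ``ppm``."""
        a = self.ascending
        if not (a.offsets[0] <= ppm <= a.offsets[-1]):
            return float("nan")
        return float(np.interp(ppm, a.offsets, a.signals))

    def asymmetry(self, offset: float) -> float:
        """S(-offset) - S(+offset), linearly interpolated."""
        return self.signal_at(-offset) - self.signal_at(offset)


@dataclass
class ZSpectrumStack:
    """A 2-D slice of Z-spectra: data[row, col, offset_index].

    ``frame_time`` is minutes post-injection (None for static acquisitions);
    ``s0_offset`` names the offset used as the unsaturated reference S0.
    """

    data: np.ndarray
    offsets: np.ndarray
    frame_time: float | None = None
    s0_offset: float = -10.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be rows x cols x offsets, got shape {self.data.shape}")
        if self.data.shape[2] != len(self.offsets):
            raise ValueError(
                f"offset axis mismatch: data has {self.data.shape[2]} frames, "
                f"offsets list has {len(self.offsets)}"
            )
        if np.any(self.data[np.isfinite(self.data)] < 0):
            raise ValueError("stack data must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def s0_index(self) -> int:
        """Index of the offset closest to ``s0_offset`` (warns if far)."""
        i = int(np.argmin(np.abs(self.offsets - self.s0_offset)))
        return i

    @property
    def s0_image(self) -> np.ndarray:
        """2-D image of the signal at the S0 reference offset."""
        return self.data[:, :, self.s0_index]

    def voxel(self, row: int, col: int) -> ZSpectrum:
        return ZSpectrum(self.offsets.copy(), self.data[row, col, :].copy())

    def copy(self) -> "ZSpectrumStack":
        return ZSpectrumStack(
            self.data.copy(), self.offsets.copy(), self.frame_time, self.s0_offset
        )
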