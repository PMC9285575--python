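"""Synthetic phantoms: vial stacks, B0 field corruption, and noise.

``generate_phantom`` emulates the multi-vial pH phantom: disks of agent
solution at 20 mM in buffer, titrated to a list of pH values, on a zero
(air) background.  Ground truth (per-vial asymmetry at the analysis
offsets and the noise-free spectra) is returned alongside, so the analysis
pipeline can be validated voxel for voxel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .containers import ZSpectrum, ZSpectrumStack
from .pools import AgentModel, WaterPool
from .simulate import AcquisitionConfig, SaturationScheme, simulate_zspectrum

__all__ = [
    "PhantomResult",
    "centered_asymmetry",
    "vial_layout",
    "generate_phantom",
    "polynomial_fieldmap",
    "add_b0_field",
    "add_noise",
]

PH_VALUES_PHANTOM = (7.4, 7.0, 6.8, 6.6, 6.4, 6.2, 6.0)


def centered_asymmetry(
    spec: ZSpectrum,
    analysis_offset: float,
    search_ppm: float = 1.5,
    grid_ppm: float = 0.005,
) -> float:
    """Asymmetry of a spectrum after centring its minimum at 0 ppm.

    This is the ground-truth counterpart of the analysis chain's ST
    definition: ST is defined on the B0-corrected spectrum, whose bulk-water
    minimum sits at zero frequency.  Even a shift-free simulated spectrum
    has its continuous minimum displaced slightly downfield by the CEST
    pool, so the reference value must apply the same centring convention
    (plateau-midpoint, see :mod:`glucocest.centering`).  Uses plain
    cubic-spline interpolation, independent of the smoothing-spline
    analysis path.
    """
    from .centering import plateau_center

    a = spec.ascending
    cs = CubicSpline(a.offsets, a.signals)
    half = min(search_ppm, -a.offsets[0], a.offsets[-1])
    g = np.arange(-half, half + grid_ppm / 2, grid_ppm)
    wc = plateau_center(g, cs(g))
    return float(cs(-analysis_offset + wc) - cs(analysis_offset + wc))


@dataclass
class PhantomResult:
    """A simulated vial phantom with ground truth."""

    stack: ZSpectrumStack
    labels: np.ndarray  # int image; 0 background, 1..n vial ids
    pH_by_vial: dict[int, float]
    truth_spectra: dict[int, ZSpectrum]  # noise-free, per vial
    truth_st: dict[int, dict[float, float]]  # vial -> {analysis_offset: ST}


def vial_layout(
    n_vials: int, matrix: tuple[int, int], radius: int | None = None
) -> np.ndarray:
    """Disk-shaped vials arranged on a ring (plus a centre vial when it fits).

    Returns an integer label image (0 = background).  Raises if the
    requested number of vials cannot be placed disjointly.
    """
    if n_vials < 1:
        raise ValueError("need at least one vial")
    rows, cols = matrix
    if radius is None:
        radius = max(2, min(rows, cols) // 12)
    labels = np.zeros((rows, cols), dtype=np.int32)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    centres: list[tuple[float, float]] = []
    if n_vials == 1:
        centres = [(cy, cx)]
    else:
        n_ring = n_vials - 1 if n_vials > 4 else n_vials
        ring_r = min(rows, cols) / 2.0 - radius - 2
        if ring_r <= radius:
            raise ValueError(f"matrix {matrix} too small for {n_vials} vials of radius {radius}")
        for i in range(n_ring):
            a = 2 * math.pi * i / n_ring
            centres.append((cy + ring_r * math.sin(a), cx + ring_r * math.cos(a)))
        if n_ring < n_vials:
            centres.append((cy, cx))
        # disjointness check: ring chord must exceed vial diameter
        if n_ring > 1:
            chord = 2 * ring_r * math.sin(math.pi / n_ring)
            if chord < 2 * radius + 1:
                raise ValueError(
                    f"too many vials ({n_vials}) for matrix {matrix} at radius {radius}"
                )
    yy, xx = np.mgrid[0:rows, 0:cols]
    for vid, (vy, vx) in enumerate(centres, start=1):
        disk = (yy - vy) ** 2 + (xx - vx) ** 2 <= radius**2
        labels[disk] = vid
    return labels


def generate_phantom(
    agent: AgentModel,
    pH_values: tuple[float, ...] = PH_VALUES_PHANTOM,
    concentration_mM: float = 20.0,
    water: WaterPool | None = None,
    sat: SaturationScheme = SaturationScheme(3.0, 5.0),
    acq: AcquisitionConfig | None = None,
    snr: float = math.inf,
    seed: int = 0,
    analysis_offsets: tuple[float, ...] = (0.8, 1.2),
) -> PhantomResult:
    """Simulate a multi-vial pH phantom image stack.

    Every voxel of vial *i* carries the noise-free spectrum of the agent at
    ``pH_values[i]``; Gaussian noise at the requested SNR is then added.
    Ground-truth per-vial asymmetry at each analysis offset comes from the
    noise-free spectra (linear interpolation on the simulated grid).
    """
    from .pools import water_preset

    if acq is None:
        from .simulate import make_offset_list

        acq = AcquisitionConfig(B0=7.0, offsets=tuple(make_offset_list(0.1, 10.0)))
    if water is None:
        water = water_preset(acq.B0, "solution")
    labels = vial_layout(len(pH_values), acq.matrix)
    # the S0 reference is acquired as an extra frame when not in the list
    from dataclasses import replace

    from .simulate import ensure_s0

    offsets = ensure_s0(acq.offset_array, acq.s0_offset)
    if len(offsets) != len(acq.offsets):
        acq = replace(acq, offsets=tuple(offsets))
    data = np.zeros((*acq.matrix, len(offsets)))
    truth_spectra: dict[int, ZSpectrum] = {}
    truth_st: dict[int, dict[float, float]] = {}
    pH_by_vial: dict[int, float] = {}
    for vid, pH in enumerate(pH_values, start=1):
        spec = simulate_zspectrum(agent, concentration_mM, pH, water, sat, acq)
        data[labels == vid, :] = spec.signals
        truth_spectra[vid] = spec
        pH_by_vial[vid] = pH
        truth_st[vid] = {a: centered_asymmetry(spec, a) for a in analysis_offsets}
    stack = ZSpectrumStack(data, offsets, s0_offset=acq.s0_offset)
    if math.isfinite(snr):
        stack = add_noise(stack, snr, seed=seed)
    return PhantomResult(stack, labels, pH_by_vial, truth_spectra, truth_st)


def polynomial_fieldmap(
    shape: tuple[int, int],
    amplitude_ppm: float = 0.3,
    order: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Smooth low-order polynomial B0 shift surface, scaled to max |amplitude|."""
    rng = np.random.default_rng(seed)
    rows, cols = shape
    y = np.linspace(-1, 1, rows)[:, None]
    x = np.linspace(-1, 1, cols)[None, :]
    surf = np.zeros(shape)
    for py in range(order + 1):
        for px in range(order + 1 - py):
            surf = surf + rng.normal() * (y**py) * (x**px)
    peak = np.max(np.abs(surf))
    if peak == 0:  # pragma: no cover - measure-zero draw
        return np.zeros(shape)
    return surf * (amplitude_ppm / peak)


def add_b0_field(
    stack: ZSpectrumStack, fieldmap_ppm: np.ndarray
) -> tuple[ZSpectrumStack, np.ndarray]:
    """Corrupt a stack as if each voxel's water centre sat at its B0 shift.

    Each spectrum is resampled so the value previously at offset ``x`` now
    appears at ``x + shift`` (cubic interpolation, edge values held at the
    ends of the sampled range).  Returns the shifted stack and the ground
    truth shift map (a copy of the input surface).
    """
    fieldmap_ppm = np.asarray(fieldmap_ppm, dtype=float)
    if fieldmap_ppm.shape != stack.shape:
        raise ValueError(f"fieldmap shape {fieldmap_ppm.shape} != stack shape {stack.shape}")
    offsets = stack.offsets
    half_range = (offsets.max() - offsets.min()) / 2.0
    if np.max(np.abs(fieldmap_ppm)) > half_range:
        raise ValueError(
            f"fieldmap peak {np.max(np.abs(fieldmap_ppm)):.3g} ppm exceeds half the "
            f"offset range ({half_range:.3g} ppm)"
        )
    asc = np.argsort(offsets)
    out = stack.copy()
    for r in range(stack.shape[0]):
        for c in range(stack.shape[1]):
            s = fieldmap_ppm[r, c]
            if s == 0.0:
                continue
            sig = stack.data[r, c, :]
            cs = CubicSpline(offsets[asc], sig[asc])
            query = np.clip(offsets - s, offsets[asc][0], offsets[asc][-1])
            out.data[r, c, :] = np.clip(cs(query), 0.0, None)
    return out, fieldmap_ppm.copy()


def add_noise(
    stack: ZSpectrumStack, snr: float, model: str = "gaussian", seed: int = 0
) -> ZSpectrumStack:
    """Add measurement noise per voxel per offset.

    SNR is defined against the unsaturated reference signal: the noise
    standard deviation is median(S0 over non-zero voxels) / snr.  The
    ``rician`` model applies magnitude-detection noise (no negative values,
    positive floor on zero background); ``gaussian`` clips at zero since
    stacks hold magnitude data.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {model!r}; use 'gaussian' or 'rician'")
    if math.isinf(snr):
        return stack.copy()
    s0 = stack.s0_image
    ref = float(np.median(s0[s0 > 0])) if np.any(s0 > 0) else 1.0
    sigma = ref / snr
    rng = np.random.default_rng(seed)
    out = stack.copy()
    if model == "gaussian":
        out.data = np.clip(out.data + rng.normal(0.0, sigma, out.data.shape), 0.0, None)
    else:
        re = out.data + rng.normal(0.0, sigma, out.data.shape)
        im = rng.normal(0.0, sigma, out.data.shape)
        out.data = np.hypot(re, im)
    return out
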