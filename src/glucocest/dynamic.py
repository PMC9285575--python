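"""Dynamic in-vivo-like series: agent uptake in a tumor-bearing slice.

``generate_dynamic_series`` emulates the dynamic glucoCEST protocol: a
baseline frame before injection, then a frame every few minutes while the
agent distributes between the extracellular and intracellular compartments
of two tumor regions embedded in tissue.  Two kinetic presets capture the
two headline behaviours:

* ``stable`` (3OMG-like): constant compartment concentrations and pH after
  arrival; the ground-truth tumor contrast stays flat over the post frames.
* ``rising`` (glucose-like): constant extracellular concentration with an
  extracellular acidification (pH drifting down over the observation
  window); since glucose contrast grows toward acidic pH, the ground-truth
  contrast rises monotonically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import ZSpectrum, ZSpectrumStack
from .phantom import add_noise, centered_asymmetry
from .pools import AgentModel, WaterPool, water_preset
from .simulate import AcquisitionConfig, SaturationScheme, simulate_zspectrum

__all__ = [
    "UptakeModel",
    "stable_uptake",
    "rising_uptake",
    "dose_to_peak_mM",
    "DynamicSeries",
    "generate_dynamic_series",
]

#: Dose (g/kg) to peak extracellular concentration (mM); only the ratio
#: between the two study doses matters for ordinal comparisons.
DOSE_TO_MM = {1.5: 5.0, 3.0: 10.0}


def dose_to_peak_mM(dose: float) -> float:
    try:
        return DOSE_TO_MM[float(dose)]
    except KeyError:
        raise KeyError(f"no preset for dose {dose} g/kg; known: {sorted(DOSE_TO_MM)}") from None


@dataclass(frozen=True)
class UptakeModel:
    """Per-frame compartment concentrations and pH for the post frames.

    All arrays have one entry per post-injection frame.  ``pH_intra`` is
    fixed; volume fractions weight the compartments' spectra in each tumor
    voxel.
    """

    kind: str  # "stable" | "rising"
    c_extra: tuple[float, ...]  # mM
    c_intra: tuple[float, ...]  # mM
    pH_extra: tuple[float, ...]
    pH_intra: float = 7.2
    dose: float = 3.0
    # extracellular (incl. vascular) vs intracellular signal volume fractions
    # of an aggressive subcutaneous tumor
    v_extra: float = 0.5
    v_intra: float = 0.5

    def __post_init__(self) -> None:
        n = len(self.c_extra)
        if not (len(self.c_intra) == len(self.pH_extra) == n) or n < 1:
            raise ValueError("c_extra, c_intra and pH_extra must have equal length >= 1")
        if any(c < 0 for c in self.c_extra + self.c_intra):
            raise ValueError("concentrations must be >= 0")
        if self.kind not in ("stable", "rising"):
            raise ValueError(f"unknown uptake kind {self.kind!r}")
        if self.kind == "rising" and np.any(np.diff(self.pH_extra) > 1e-12):
            raise ValueError("rising uptake requires non-increasing extracellular pH")
        if not math.isclose(self.v_extra + self.v_intra, 1.0, abs_tol=1e-9):
            raise ValueError("compartment volume fractions must sum to 1")

    @property
    def n_post(self) -> int:
        return len(self.c_extra)


def stable_uptake(dose: float = 3.0, n_post: int = 5, pH: float = 7.0) -> UptakeModel:
    """3OMG-like preset: constant concentrations and pH after arrival."""
    peak = dose_to_peak_mM(dose)
    return UptakeModel(
        kind="stable",
        c_extra=(peak,) * n_post,
        c_intra=(peak,) * n_post,
        pH_extra=(pH,) * n_post,
        dose=dose,
    )


def rising_uptake(
    dose: float = 3.0,
    n_post: int = 5,
    pH_start: float = 7.0,
    pH_end: float = 6.4,
) -> UptakeModel:
    """Glucose-like preset: extracellular acidification drives rising contrast."""
    peak = dose_to_peak_mM(dose)
    return UptakeModel(
        kind="rising",
        c_extra=(peak,) * n_post,
        c_intra=(0.0,) * n_post,
        pH_extra=tuple(np.linspace(pH_start, pH_end, n_post)),
        dose=dose,
    )


@dataclass
class DynamicSeries:
    """A simulated dynamic acquisition with ground truth."""

    frames: list[ZSpectrumStack]  # frame 0 = baseline
    roi: np.ndarray  # int image; 0 background, 1..n tumor ids
    frame_times: np.ndarray  # minutes; baseline = 0
    truth_st: np.ndarray  # ground-truth tumor asymmetry per frame
    truth_spectra: list[ZSpectrum]  # mixed tumor spectrum per frame


def _tumor_rois(matrix: tuple[int, int]) -> np.ndarray:
    """Two disk ROIs on the left/right flanks of the slice."""
    rows, cols = matrix
    r = max(3, min(rows, cols) // 6)
    yy, xx = np.mgrid[0:rows, 0:cols]
    roi = np.zeros((rows, cols), dtype=np.int32)
    for vid, cx in enumerate((cols * 0.27, cols * 0.73), start=1):
        roi[(yy - rows / 2.0) ** 2 + (xx - cx) ** 2 <= r**2] = vid
    return roi


def generate_dynamic_series(
    agent: AgentModel,
    uptake: UptakeModel,
    water: WaterPool | None = None,
    sat: SaturationScheme = SaturationScheme(2.0, 5.0),
    acq: AcquisitionConfig | None = None,
    n_frames: int | None = None,
    frame_interval_min: float = 6.0,
    snr: float = math.inf,
    seed: int = 0,
    analysis_offset: float = 1.2,
) -> DynamicSeries:
    """Simulate baseline + post-injection Z-spectrum stacks.

    Frame 0 carries no agent anywhere.  In post frame t, tumor voxels mix
    the extracellular and intracellular spectra with the uptake model's
    volume fractions; non-tumor tissue stays agent-free.  Ground-truth ST
    per frame is the asymmetry of the noise-free mixed tumor spectrum at
    ``analysis_offset``.
    """
    if acq is None:
        from .simulate import make_offset_list

        acq = AcquisitionConfig(B0=7.0, offsets=tuple(make_offset_list(0.2, 6.0)))
    if water is None:
        water = water_preset(acq.B0, "tissue")
    if n_frames is None:
        n_frames = 1 + uptake.n_post
    if n_frames < 2:
        raise ValueError("need n_frames >= 2 (baseline plus at least one post frame)")
    if n_frames - 1 != uptake.n_post:
        raise ValueError(
            f"uptake model provides {uptake.n_post} post frames but n_frames={n_frames} "
            f"requests {n_frames - 1}"
        )
    roi = _tumor_rois(acq.matrix)
    # the S0 reference is acquired as an extra frame when not in the list
    from dataclasses import replace

    from .simulate import ensure_s0

    offsets = ensure_s0(acq.offset_array, acq.s0_offset)
    if len(offsets) != len(acq.offsets):
        acq = replace(acq, offsets=tuple(offsets))
    base_spec = simulate_zspectrum(agent, 0.0, 7.0, water, sat, acq)

    frames: list[ZSpectrumStack] = []
    truth_st = np.zeros(n_frames)
    truth_spectra: list[ZSpectrum] = []
    frame_times = np.concatenate([[0.0], frame_interval_min * np.arange(1, n_frames)])
    for t in range(n_frames):
        if t == 0:
            tumor_sig = base_spec.signals
        else:
            i = t - 1
            z_e = simulate_zspectrum(
                agent, uptake.c_extra[i], uptake.pH_extra[i], water, sat, acq
            )
            z_i = simulate_zspectrum(
                agent, uptake.c_intra[i], uptake.pH_intra, water, sat, acq
            )
            tumor_sig = uptake.v_extra * z_e.signals + uptake.v_intra * z_i.signals
        spec = ZSpectrum(offsets, tumor_sig)
        truth_spectra.append(spec)
        truth_st[t] = centered_asymmetry(spec, analysis_offset)
        data = np.broadcast_to(base_spec.signals, (*acq.matrix, len(offsets))).copy()
        data[roi > 0, :] = tumor_sig
        stack = ZSpectrumStack(data, offsets, frame_time=float(frame_times[t]),
                               s0_offset=acq.s0_offset)
        if math.isfinite(snr):
            stack = add_noise(stack, snr, seed=seed + 1000 * t)
        frames.append(stack)
    return DynamicSeries(frames, roi, frame_times, truth_st, truth_spectra)
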