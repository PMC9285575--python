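"""Forward simulation of single Z-spectra under CW saturation.

Maps agent/pH/concentration onto Bloch-McConnell pool parameters and
produces normalized Z-spectra: water Mz after saturation at each offset,
divided by the signal at the S0 reference offset (-10 ppm by default,
simulated as an extra frame when it is not part of the offset list).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bloch import SolutePool, zspectrum_expm, zspectrum_ode
from .constants import WATER_PROTON_M
from .containers import ZSpectrum
from .pools import AgentModel, WaterPool, exchange_rate

__all__ = [
    "SaturationScheme",
    "AcquisitionConfig",
    "make_offset_list",
    "solute_pools",
    "simulate_zspectrum",
]


@dataclass(frozen=True)
class SaturationScheme:
    """Continuous-wave block saturation pulse: amplitude (uT) and duration (s)."""

    B1: float
    duration: float
    shape: str = "block"

    def __post_init__(self) -> None:
        if self.B1 < 0:
            raise ValueError("B1 must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.shape != "block":
            raise ValueError(f"only block pulses are supported, got {self.shape!r}")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Field strength, offset list and imaging geometry."""

    B0: float
    offsets: tuple[float, ...]
    s0_offset: float = -10.0
    matrix: tuple[int, int] = (64, 64)
    temperature: float = 37.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", tuple(float(o) for o in self.offsets))
        d = np.diff(self.offsets)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("offsets must be strictly monotone")
        if self.B0 <= 0:
            raise ValueError("B0 must be > 0")
        if len(self.matrix) != 2 or min(self.matrix) < 1:
            raise ValueError("matrix must be (rows, cols) with positive sizes")

    @property
    def offset_array(self) -> np.ndarray:
        return np.array(self.offsets, dtype=float)


def make_offset_list(
    step_ppm: float,
    half_range_ppm: float,
    descending: bool = True,
    allow_degenerate: bool = False,
) -> np.ndarray:
    """Symmetric saturation-offset list from -half_range to +half_range.

    The in-vivo protocol samples 0.2 ppm steps over +/-6 ppm (61 offsets);
    phantoms use 0.1 ppm over +/-10 ppm (201 offsets).

    Parameters
    ----------
    step_ppm : float
        Spacing between offsets; must divide ``half_range_ppm`` exactly.
    half_range_ppm : float
        Largest |offset|.
    descending : bool
        Store from +max to -max (acquisition convention) when True.
    allow_degenerate : bool
        Permit ``half_range_ppm == 0`` (single on-resonance offset).
    """
    if step_ppm <= 0:
        raise ValueError(f"step_ppm must be > 0, got {step_ppm}")
    if half_range_ppm < 0:
        raise ValueError(f"half_range_ppm must be >= 0, got {half_range_ppm}")
    if half_range_ppm == 0:
        if allow_degenerate:
            return np.array([0.0])
        raise ValueError("half_range_ppm = 0 gives a single offset; pass allow_degenerate=True")
    n_half = half_range_ppm / step_ppm
    if abs(n_half - round(n_half)) > 1e-9:
        raise ValueError(
            f"half_range_ppm {half_range_ppm} is not a multiple of step_ppm {step_ppm}"
        )
    n_half = int(round(n_half))
    offs = np.arange(-n_half, n_half + 1) * step_ppm
    return offs[::-1].copy() if descending else offs


def ensure_s0(offsets: np.ndarray, s0_offset: float) -> np.ndarray:
    """Append the S0 reference offset as an extra acquired frame if absent.

    Keeps strict monotonicity: the reference (far off-resonance on the
    negative side by convention) goes at the descending end / ascending
    start of the list.
    """
    offsets = np.asarray(offsets, dtype=float)
    if np.any(np.isclose(offsets, s0_offset)):
        return offsets
    descending = len(offsets) > 1 and offsets[0] > offsets[-1]
    if descending:
        if s0_offset >= offsets[-1]:
            raise ValueError(f"s0 offset {s0_offset} cannot extend the offset list")
        return np.append(offsets, s0_offset)
    if len(offsets) == 0 or s0_offset <= offsets[0]:
        return np.insert(offsets, 0, s0_offset)
    raise ValueError(f"s0 offset {s0_offset} cannot extend the offset list")


def solute_pools(agent: AgentModel, concentration_mM: float, pH: float) -> list[SolutePool]:
    """Resolve an agent at a concentration (mM) and pH into solver pools."""
    if concentration_mM < 0:
        raise ValueError("concentration must be >= 0")
    if concentration_mM == 0:
        return []
    scale = agent.anomer_scale()
    out = []
    for p in agent.pools:
        frac = p.protons_per_molecule * concentration_mM * 1e-3 / WATER_PROTON_M
        out.append(
            SolutePool(
                chemical_shift=p.chemical_shift,
                fraction=frac,
                k=scale * exchange_rate(p, pH),
                T1=p.T1,
                T2=p.T2,
            )
        )
    return out


def simulate_zspectrum(
    agent: AgentModel,
    concentration_mM: float,
    pH: float,
    water: WaterPool,
    sat: SaturationScheme,
    acq: AcquisitionConfig,
    solver: str = "expm",
) -> ZSpectrum:
    """Normalized Z-spectrum of ``agent`` at one concentration and pH.

    The signal at every offset is divided by the signal at the S0 offset
    (appended transparently if absent from the offset list), so Z = 1 at S0
    by construction and Z = 1 everywhere when B1 = 0.
    """
    offsets = acq.offset_array
    run = {"expm": zspectrum_expm, "ode": zspectrum_ode}.get(solver)
    if run is None:
        raise ValueError(f"unknown solver {solver!r}; use 'expm' or 'ode'")
    pools = solute_pools(agent, concentration_mM, pH)

    need_s0 = not np.any(np.isclose(offsets, acq.s0_offset))
    sim_offsets = np.append(offsets, acq.s0_offset) if need_s0 else offsets
    mz = run(sim_offsets, sat.duration, acq.B0, sat.B1, water, pools)
    if need_s0:
        s0, mz = mz[-1], mz[:-1]
    else:
        s0 = mz[int(np.argmin(np.abs(offsets - acq.s0_offset)))]
    if s0 <= 0:
        raise RuntimeError("non-positive S0 signal; saturation scheme is degenerate")
    z = mz / s0
    # Clip away solver round-off; physical Z lies in [0, 1].
    return ZSpectrum(offsets, np.clip(z, 0.0, 1.0))
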