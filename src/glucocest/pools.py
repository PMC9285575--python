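"""Exchangeable-proton pools, agents and the pH -> exchange-rate law.

Hydroxyl protons of sugars resonate 1-3 ppm downfield of water and exchange
with bulk water at rates that are base-catalysed: above ~pH 6 the rate grows
roughly one decade per pH unit on top of a pH-independent floor.  The law
used here is

    k(pH) = k_0 + (k_ref - k_0) * 10**(pH - pH_ref)

so that k(pH_ref) = k_ref exactly and k is monotone non-decreasing in pH.

The glucose and 3OMG presets are effective single-pool models: all hydroxyl
resonances are collapsed onto the in-vivo analysis offset (+1.2 ppm) with a
literature-informed effective rate; glucose exchanges several-fold faster
than 3OMG, which is what flips the pH of maximal CEST contrast between the
two agents (acidic optimum for glucose, near-neutral for 3OMG).  A three-pool
glucose variant with resolved OH resonances is provided for multi-pool
solver checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ProtonPool",
    "WaterPool",
    "AgentModel",
    "exchange_rate",
    "glucose",
    "omg3",
    "glucose_3pool",
    "get_agent",
    "water_preset",
]

PH_MIN, PH_MAX = 5.0, 9.0


@dataclass(frozen=True)
class ProtonPool:
    """One exchangeable-proton resonance of a CEST agent.

    Parameters
    ----------
    label : str
        Name of the resonance (e.g. ``"OH"``).
    chemical_shift : float
        Offset from water in ppm; positive is downfield.
    protons_per_molecule : int
        Number of exchangeable protons this pool contributes per molecule.
    k_ref : float
        Exchange rate to water at ``pH_ref``, s^-1.
    pH_ref : float
        Reference pH of ``k_ref``.
    k_0 : float
        pH-independent floor rate, s^-1 (buffer catalysis folded in).
    T1, T2 : float
        Longitudinal / transverse relaxation times of the pool, s.
    """

    label: str
    chemical_shift: float
    protons_per_molecule: int
    k_ref: float
    pH_ref: float = 7.0
    k_0: float = 0.0
    T1: float = 1.0
    T2: float = 0.015

    def __post_init__(self) -> None:
        if not math.isfinite(self.chemical_shift):
            raise ValueError("chemical_shift must be finite")
        if self.k_ref <= 0:
            raise ValueError(f"k_ref must be > 0, got {self.k_ref}")
        if self.k_0 < 0 or self.k_0 >= self.k_ref:
            raise ValueError("need 0 <= k_0 < k_ref")
        if self.protons_per_molecule < 1:
            raise ValueError("protons_per_molecule must be >= 1")
        if not (self.T1 > self.T2 > 0):
            raise ValueError(f"need T1 > T2 > 0, got T1={self.T1}, T2={self.T2}")

    @property
    def k_base(self) -> float:
        """Base-catalysis coefficient (s^-1 at pH_ref, one decade per pH unit)."""
        return self.k_ref - self.k_0


@dataclass(frozen=True)
class WaterPool:
    """Bulk water pool: relaxation times and proton concentration."""

    T1: float
    T2: float
    proton_concentration: float = 111.0  # mol/L of protons

    def __post_init__(self) -> None:
        if not (self.T1 > self.T2 > 0):
            raise ValueError(f"need T1 > T2 > 0, got T1={self.T1}, T2={self.T2}")
        if self.proton_concentration <= 0:
            raise ValueError("proton_concentration must be > 0")


@dataclass(frozen=True)
class AgentModel:
    """A CEST agent: a set of proton pools plus anomer composition.

    ``anomer_rate_ratio`` optionally models mutarotation: the beta anomer's
    hydroxyls exchange faster than the alpha anomer's.  When set (beta/alpha
    rate ratio > 1), every pool's rate is scaled by the population-weighted
    mean ``(1 - f_beta) + f_beta * ratio`` normalised to a 50:50 mixture.
    Default is off (``None``): rates are effective single-anomer values.
    """

    name: str
    pools: tuple[ProtonPool, ...]
    anomer_beta_fraction: float = 0.5
    anomer_rate_ratio: float | None = None

    def __post_init__(self) -> None:
        if not self.pools:
            raise ValueError("AgentModel needs at least one pool")
        if not (0.0 <= self.anomer_beta_fraction <= 1.0):
            raise ValueError("anomer_beta_fraction must be in [0, 1]")
        object.__setattr__(self, "pools", tuple(self.pools))

    def anomer_scale(self) -> float:
        """Multiplier applied to every pool rate from the anomer mixture."""
        if self.anomer_rate_ratio is None:
            return 1.0
        r, fb = self.anomer_rate_ratio, self.anomer_beta_fraction
        return ((1.0 - fb) + fb * r) / (0.5 + 0.5 * r)


def exchange_rate(pool: ProtonPool, pH: float) -> float:
    """Exchange rate (s^-1) of ``pool`` at ``pH`` under the base-catalysis law.

    Raises
    ------
    ValueError
        If ``pH`` lies outside the supported [5, 9] range.
    """
    if not (PH_MIN <= pH <= PH_MAX):
        raise ValueError(f"pH {pH} outside supported range [{PH_MIN}, {PH_MAX}]")
    return pool.k_0 + pool.k_base * 10.0 ** (pH - pool.pH_ref)


# --------------------------------------------------------------------------
# Presets.  Exchange rates are effective values chosen so that the simulated
# contrast reproduces the field's qualitative pH/B1/B0 behaviour: glucose in
# the fast-exchange regime at neutral pH (contrast grows toward acidic pH at
# moderate B1), 3OMG several-fold slower (contrast peaks near pH 7).

def glucose() -> AgentModel:
    """D-glucose, single effective OH pool at +1.2 ppm (5 OH protons)."""
    return AgentModel(
        name="glucose",
        pools=(ProtonPool("OH", 1.2, 5, k_ref=4000.0, pH_ref=7.0, k_0=300.0),),
        anomer_beta_fraction=0.64,
    )


def omg3() -> AgentModel:
    """3-O-methyl-D-glucose, single effective OH pool at +1.2 ppm (4 OH protons)."""
    return AgentModel(
        name="3OMG",
        pools=(ProtonPool("OH", 1.2, 4, k_ref=800.0, pH_ref=7.0, k_0=60.0),),
        anomer_beta_fraction=0.58,
    )


def glucose_3pool() -> AgentModel:
    """D-glucose with resolved hydroxyl resonances (+0.8, +1.5, +2.9 ppm)."""
    return AgentModel(
        name="glucose-3pool",
        pools=(
            ProtonPool("OH-1", 0.8, 2, k_ref=6000.0, pH_ref=7.0, k_0=450.0),
            ProtonPool("OH-2", 1.5, 2, k_ref=3000.0, pH_ref=7.0, k_0=250.0),
            ProtonPool("OH-3", 2.9, 1, k_ref=1500.0, pH_ref=7.0, k_0=120.0),
        ),
        anomer_beta_fraction=0.64,
    )


_AGENTS = {"glucose": glucose, "3OMG": omg3, "3omg": omg3, "glucose-3pool": glucose_3pool}


def get_agent(name: str) -> AgentModel:
    try:
        return _AGENTS[name]()
    except KeyError:
        raise KeyError(f"unknown agent {name!r}; known: {sorted(set(_AGENTS))}") from None


# Water relaxation presets.  "solution" emulates buffered phantoms (long T2,
# narrow direct-saturation line); "tissue" emulates in-vivo tumor tissue
# (short T2, broad spillover).  Values differ between fields: T1 lengthens
# and tissue T2 shortens with B0.
_WATER_PRESETS: dict[tuple[float, str], WaterPool] = {
    (7.0, "solution"): WaterPool(T1=3.5, T2=1.2),
    (3.0, "solution"): WaterPool(T1=3.0, T2=1.8),
    (7.0, "tissue"): WaterPool(T1=2.0, T2=0.050),
    (3.0, "tissue"): WaterPool(T1=1.7, T2=0.070),
}


def water_preset(b0: float, medium: str = "solution") -> WaterPool:
    """Water pool preset for field ``b0`` (3 or 7 T) and medium."""
    try:
        return _WATER_PRESETS[(float(b0), medium)]
    except KeyError:
        raise KeyError(
            f"no water preset for B0={b0} T, medium={medium!r}; "
            f"known: {sorted(_WATER_PRESETS)}"
        ) from None
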