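"""Physical constants and per-field water relaxation presets.

All frequencies are handled in angular units (rad/s) inside the solver;
the public API speaks ppm and microtesla.
"""

from __future__ import annotations

#: Proton gyromagnetic ratio over 2*pi, in Hz per microtesla
#: (equivalently MHz per tesla).
GAMMA_HZ_PER_UT = 42.577478461

#: Water proton concentration of pure water, mol/L of protons (2 * 55.5 M).
WATER_PROTON_M = 111.0


def larmor_hz_per_ppm(b0_tesla: float) -> float:
    """Frequency per ppm of chemical shift at field ``b0_tesla`` (Hz/ppm)."""
    return GAMMA_HZ_PER_UT * b0_tesla


def omega1_rad_s(b1_ut: float) -> float:
    """RF nutation frequency (rad/s) of a continuous-wave pulse of ``b1_ut`` uT."""
    import math

    return 2.0 * math.pi * GAMMA_HZ_PER_UT * b1_ut
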