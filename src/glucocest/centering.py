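"""Water-centre localisation on a sampled spectrum curve.

Under strong saturation the bulk-water line has a flat, fully-saturated
bottom spanning a few tenths of a ppm; a global argmin there is decided by
sub-resolution interpolation wiggles and can land anywhere on the plateau.
The centre is therefore defined as the midpoint of the deepest plateau:
the contiguous super-level region around the minimum whose values stay
within a small fraction of the line depth.  For a curved bottom the
plateau collapses to a point and this reduces to the argmin; under a
constant B0 shift the estimate translates exactly with the spectrum.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plateau_center"]

#: fraction of the in-window line depth treated as "at the minimum"; large
#: enough that the plateau edges land on the steep flanks of the water line
#: (where interpolation ringing displaces them negligibly), small enough
#: that the agent resonance stays outside the plateau
REL_LEVEL = 0.05


def plateau_center(grid: np.ndarray, values: np.ndarray, rel_level: float = REL_LEVEL) -> float:
    """Midpoint of the contiguous near-minimum plateau of ``values``.

    ``grid`` must be sorted ascending.  The plateau is the run of
    consecutive points around the argmin with values within
    ``rel_level * (max - min)`` of the minimum.
    """
    values = np.asarray(values, dtype=float)
    i0 = int(np.argmin(values))
    depth = float(values.max() - values[i0])
    if depth == 0.0:
        return float(grid[len(grid) // 2])
    level = values[i0] + rel_level * depth
    lo = i0
    while lo > 0 and values[lo - 1] <= level:
        lo -= 1
    hi = i0
    while hi < len(values) - 1 and values[hi + 1] <= level:
        hi += 1
    return float(0.5 * (grid[lo] + grid[hi]))
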