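"""Fixed-bin-number gray-level discretisation of a masked map."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretisedROI", "discretise"]


@dataclass
class DiscretisedROI:
    """Integer gray levels 1..ng on the mask (0 outside)."""

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    bin_edges: np.ndarray  # in original map units


def discretise(map3d: np.ndarray, mask: np.ndarray, ng: int) -> DiscretisedROI:
    """Equal-width binning between the masked minimum and maximum.

    level = floor(ng * (x - min) / (max - min)) + 1, with the maximum mapped
    to level ng.  A constant map assigns every voxel level 1.  The resulting
    level multiset is invariant to affine rescaling of the map with positive
    slope (and reflected by negative slope).
    """
    if ng < 2:
        raise ValueError("ng must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(map3d, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    if not np.all(np.isfinite(vals)):
        raise ValueError("map must be finite on the mask")
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(mask.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
        edges = np.array([lo, hi])
    else:
        scaled = np.floor(ng * (np.asarray(map3d, dtype=float) - lo) / (hi - lo)) + 1
        levels[mask] = np.clip(scaled[mask], 1, ng).astype(np.int64)
        edges = np.linspace(lo, hi, ng + 1)
    return DiscretisedROI(levels=levels, mask=mask, ng=ng, bin_edges=edges)
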