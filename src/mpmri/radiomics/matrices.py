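"""Texture matrix construction on a discretised 3D ROI.

All matrices use distance-1 neighbourhoods: the GLCM and GLRLM pool the 13
unique 3D directions (26-connectivity, one of each antipodal pair); the
GLSZM and NGTDM use full 26-connected neighbourhoods.  Only voxels inside
the mask contribute; a pair/run/zone never crosses the mask boundary.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve, label

__all__ = ["DIRECTIONS_13", "build_glcm", "build_glrlm", "build_glszm", "build_ngtdm"]

# the 13 unique distance-1 directions in 3D (antipodes excluded)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=int)


def _masked_coords(mask: np.ndarray) -> np.ndarray:
    return np.argwhere(mask)


def _in_bounds(coords: np.ndarray, shape) -> np.ndarray:
    ok = np.ones(len(coords), dtype=bool)
    for k in range(3):
        ok &= (coords[:, k] >= 0) & (coords[:, k] < shape[k])
    return ok


def build_glcm(
    roi, directions=DIRECTIONS_13, symmetric: bool = True
) -> np.ndarray:
    """Symmetric gray-level co-occurrence probability matrix (ng x ng).

    Pair counts at distance 1 are pooled over all requested directions
    ("merged" aggregation: one matrix, then one value per feature) and
    normalised to probabilities.
    """
    levels, mask, ng = roi.levels, roi.mask, roi.ng
    counts = np.zeros((ng, ng), dtype=float)
    coords = _masked_coords(mask)
    for d in directions:
        nb = coords + np.array(d)
        ok = _in_bounds(nb, mask.shape)
        ok[ok] &= mask[tuple(nb[ok].T)]
        a = levels[tuple(coords[ok].T)] - 1
        b = levels[tuple(nb[ok].T)] - 1
        np.add.at(counts, (a, b), 1.0)
        if symmetric:
            np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("mask too small: no in-mask voxel pair at distance 1")
    return counts / total


def build_glrlm(roi, directions=DIRECTIONS_13) -> np.ndarray:
    """Run-length count matrix (ng x max_run_length), pooled over directions.

    A run is a maximal straight segment of equal-level in-mask voxels; per
    direction the run lengths of each level partition the masked voxels, so
    sum(counts * length) equals n_masked per direction.
    """
    levels, mask, ng = roi.levels, roi.mask, roi.ng
    coords = _masked_coords(mask)
    if len(coords) == 0:
        raise ValueError("empty mask")
    runs: list[tuple[int, int]] = []
    mask_idx = set(map(tuple, coords))
    for d in directions:
        dv = np.array(d)
        for c in coords:
            prev = tuple(c - dv)
            if prev in mask_idx and levels[prev] == levels[tuple(c)]:
                continue  # not a run start
            length = 1
            nxt = c + dv
            while tuple(nxt) in mask_idx and levels[tuple(nxt)] == levels[tuple(c)]:
                length += 1
                nxt = nxt + dv
            runs.append((int(levels[tuple(c)]), length))
    max_len = max(l for _, l in runs)
    out = np.zeros((ng, max_len), dtype=float)
    for lev, l in runs:
        out[lev - 1, l - 1] += 1.0
    return out


def build_glszm(roi) -> np.ndarray:
    """Size-zone count matrix (ng x max_zone_size).

    A zone is a 26-connected component of equal-level in-mask voxels; zones
    partition the mask, so sum(counts * size) equals n_masked.
    """
    levels, mask, ng = roi.levels, roi.mask, roi.ng
    if not mask.any():
        raise ValueError("empty mask")
    zones: list[tuple[int, int]] = []
    for lev in range(1, ng + 1):
        binary = (levels == lev) & mask
        if not binary.any():
            continue
        lab, n = label(binary, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((lev, int(s)) for s in sizes if s > 0)
    max_size = max(s for _, s in zones)
    out = np.zeros((ng, max_size), dtype=float)
    for lev, s in zones:
        out[lev - 1, s - 1] += 1.0
    return out


def build_ngtdm(roi) -> tuple[np.ndarray, np.ndarray]:
    """Neighbourhood gray-tone difference accumulators.

    Returns (n_i, s_i), i = 1..ng: n_i counts masked voxels of level i that
    have at least one masked 26-neighbour, and s_i sums |i - A_v| where A_v
    is the mean level of the masked neighbours of voxel v.
    """
    levels, mask, ng = roi.levels, roi.mask, roi.ng
    kernel = _STRUCT_26.copy()
    kernel[1, 1, 1] = 0
    lv = np.where(mask, levels, 0).astype(float)
    nb_sum = convolve(lv, kernel, mode="constant", cval=0.0)
    nb_cnt = convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    n = np.zeros(ng)
    s = np.zeros(ng)
    use = mask & (nb_cnt > 0)
    avg = np.zeros(mask.shape)
    avg[use] = nb_sum[use] / nb_cnt[use]
    for lev in range(1, ng + 1):
        sel = use & (levels == lev)
        n[lev - 1] = sel.sum()
        s[lev - 1] = np.abs(lev - avg[sel]).sum()
    return n, s
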