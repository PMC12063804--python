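"""Shared helpers for texture-matrix computation.

ROIs are carried as a bounding-box "levels" array: 0 outside the ROI,
1..Ng inside, where levels come from fixed-bin-width discretization of
the HU values (floor(x/w) - floor(min/w) + 1, pyradiomics-style).
"""

from __future__ import annotations

import numpy as np

EPS = np.finfo(np.float64).eps


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray-level discretization to integer levels >= 1."""
    lo = np.floor(values.min() / bin_width)
    return (np.floor(values / bin_width) - lo + 1).astype(np.int64)


def roi_levels(intensities: np.ndarray, mask: np.ndarray, label: int, bin_width: float):
    """Bounding-box levels array (0 = outside ROI) and the raw ROI values."""
    roi = mask == label
    idx = np.argwhere(roi)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_roi = roi[box]
    sub_int = intensities[box]
    values = sub_int[sub_roi]
    levels = np.zeros(sub_roi.shape, dtype=np.int64)
    levels[sub_roi] = discretize(values, bin_width)
    return levels, values


# The 13 unique direction offsets of the 26-neighbourhood (one per
# antipodal pair); texture matrices are symmetrized so the half chosen is
# immaterial.
def unique_directions() -> list[tuple[int, int, int]]:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if (-dx, -dy, -dz) in dirs:
                    continue
                dirs.append(d)
    return dirs


def all_neighbors() -> list[tuple[int, int, int]]:
    out = []
    for d in unique_directions():
        out.append(d)
        out.append(tuple(-c for c in d))
    return out


def offset_slices(shape, d):
    """Slice tuples (src, dst) with dst = src + d, or (None, None) if empty."""
    src, dst = [], []
    for n, di in zip(shape, d):
        if abs(di) >= n:
            return None, None
        src.append(slice(max(0, -di), n - max(0, di)))
        dst.append(slice(max(0, di), n - max(0, -di)))
    return tuple(src), tuple(dst)


def offset_pairs(levels: np.ndarray, d: tuple[int, int, int]):
    """Aligned (center, neighbour) level views for offset ``d``.

    Returned arrays contain 0 where the voxel is outside the ROI.
    """
    src, dst = offset_slices(levels.shape, d)
    if src is None:
        return None, None
    return levels[src], levels[dst]
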