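"""Gray-level size-zone matrix features (16).

Zones are 26-connected components of equal gray level; a single matrix is
built per ROI (no direction averaging)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ctharmony.features._family import family_features

NAMES = [
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

_KEYMAP = {
    "SmallAreaEmphasis": "small_emphasis",
    "LargeAreaEmphasis": "large_emphasis",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "SizeZoneNonUniformity": "size_n",
    "SizeZoneNonUniformityNormalized": "size_nn",
    "ZonePercentage": "percentage",
    "GrayLevelVariance": "gl_variance",
    "ZoneVariance": "size_variance",
    "ZoneEntropy": "entropy",
    "LowGrayLevelZoneEmphasis": "low_gl",
    "HighGrayLevelZoneEmphasis": "high_gl",
    "SmallAreaLowGrayLevelEmphasis": "small_low",
    "SmallAreaHighGrayLevelEmphasis": "small_high",
    "LargeAreaLowGrayLevelEmphasis": "large_low",
    "LargeAreaHighGrayLevelEmphasis": "large_high",
}

_STRUCT = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


def size_zone_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    n_vox = int((levels > 0).sum())
    M = np.zeros((n_levels, n_vox), dtype=np.int64)
    for lvl in range(1, n_levels + 1):
        region = levels == lvl
        if not region.any():
            continue
        labeled, n_zones = ndimage.label(region, structure=_STRUCT)
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            M[lvl - 1, s - 1] += 1
    return M


def compute(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    n_vox = int((levels > 0).sum())
    M = size_zone_matrix(levels, n_levels)
    feats = family_features(M, n_vox)
    return {name: feats[_KEYMAP[name]] for name in NAMES}
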