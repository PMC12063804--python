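"""Gray-level dependence matrix features (14).

A voxel's dependence is 1 + the number of 26-neighbours inside the ROI
whose gray level differs by at most ``alpha`` (default 0); an isolated
voxel therefore has dependence 1.
"""

from __future__ import annotations

import numpy as np

from ctharmony.features._family import family_features
from ctharmony.features._utils import all_neighbors, offset_slices

NAMES = [
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]

_KEYMAP = {
    "SmallDependenceEmphasis": "small_emphasis",
    "LargeDependenceEmphasis": "large_emphasis",
    "GrayLevelNonUniformity": "gln",
    "DependenceNonUniformity": "size_n",
    "DependenceNonUniformityNormalized": "size_nn",
    "GrayLevelVariance": "gl_variance",
    "DependenceVariance": "size_variance",
    "DependenceEntropy": "entropy",
    "LowGrayLevelEmphasis": "low_gl",
    "HighGrayLevelEmphasis": "high_gl",
    "SmallDependenceLowGrayLevelEmphasis": "small_low",
    "SmallDependenceHighGrayLevelEmphasis": "small_high",
    "LargeDependenceLowGrayLevelEmphasis": "large_low",
    "LargeDependenceHighGrayLevelEmphasis": "large_high",
}


def dependence_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    valid = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in all_neighbors():
        src, dst = offset_slices(levels.shape, d)
        if src is None:
            continue
        ok = valid[dst] & valid[src] & (np.abs(levels[dst] - levels[src]) <= alpha)
        dep[dst] += ok
    dep += 1  # the voxel itself
    M = np.zeros((n_levels, 27), dtype=np.int64)
    lv, dv = levels[valid] - 1, dep[valid] - 1
    np.add.at(M, (lv, dv), 1)
    return M


def compute(levels: np.ndarray, n_levels: int, alpha: int = 0) -> dict[str, float]:
    n_vox = int((levels > 0).sum())
    M = dependence_matrix(levels, n_levels, alpha)
    feats = family_features(M, n_vox)
    return {name: feats[_KEYMAP[name]] for name in NAMES}
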