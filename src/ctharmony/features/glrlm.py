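"""Gray-level run-length matrix features (16), averaged over the 13
unique 3D directions."""

from __future__ import annotations

import numpy as np

from ctharmony.features._family import family_features
from ctharmony.features._utils import offset_slices, unique_directions

NAMES = [
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

_KEYMAP = {
    "ShortRunEmphasis": "small_emphasis",
    "LongRunEmphasis": "large_emphasis",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "RunLengthNonUniformity": "size_n",
    "RunLengthNonUniformityNormalized": "size_nn",
    "RunPercentage": "percentage",
    "GrayLevelVariance": "gl_variance",
    "RunVariance": "size_variance",
    "RunEntropy": "entropy",
    "LowGrayLevelRunEmphasis": "low_gl",
    "HighGrayLevelRunEmphasis": "high_gl",
    "ShortRunLowGrayLevelEmphasis": "small_low",
    "ShortRunHighGrayLevelEmphasis": "small_high",
    "LongRunLowGrayLevelEmphasis": "large_low",
    "LongRunHighGrayLevelEmphasis": "large_high",
}


def run_length_matrix(levels: np.ndarray, d, n_levels: int) -> np.ndarray:
    """Count runs of equal gray level along direction ``d``."""
    max_len = max(levels.shape)
    M = np.zeros((n_levels, max_len), dtype=np.int64)
    valid = levels > 0
    prev_same = np.zeros_like(valid)
    src, dst = offset_slices(levels.shape, d)
    if src is not None:
        prev_same[dst] = valid[src] & (levels[src] == levels[dst])
    starts = valid & ~prev_same
    shape = levels.shape
    for idx in np.argwhere(starts):
        x, y, z = idx
        lvl = levels[x, y, z]
        length = 1
        while True:
            x2, y2, z2 = x + d[0], y + d[1], z + d[2]
            if not (0 <= x2 < shape[0] and 0 <= y2 < shape[1] and 0 <= z2 < shape[2]):
                break
            if levels[x2, y2, z2] != lvl:
                break
            length += 1
            x, y, z = x2, y2, z2
        M[lvl - 1, length - 1] += 1
    return M


def compute(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    n_vox = int((levels > 0).sum())
    per_dir = []
    for d in unique_directions():
        M = run_length_matrix(levels, d, n_levels)
        if M.sum() > 0:
            per_dir.append(family_features(M, n_vox))
    out = {}
    for name in NAMES:
        key = _KEYMAP[name]
        out[name] = float(np.mean([f[key] for f in per_dir]))
    return out
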