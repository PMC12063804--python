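"""Shared formula family for GLRLM / GLSZM / GLDM matrices.

All three are (gray level i, count j) matrices — run length, zone size or
dependence — and share the same emphasis / non-uniformity / variance /
entropy functional forms; only the names differ per class.
"""

from __future__ import annotations

import numpy as np

from ctharmony.features._utils import EPS


def family_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Generic features of a (level, size) count matrix.

    Keys are the generic functional names; each class maps them onto its
    own feature names.
    """
    N = P.sum()
    p = P / N
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)  # marginal over sizes
    ps = p.sum(axis=0)  # marginal over levels
    mu_i = (i[:, 0] * pg).sum()
    mu_j = (j[0, :] * ps).sum()
    nz = p > 0
    return {
        "small_emphasis": float((p / j**2).sum()),
        "large_emphasis": float((p * j**2).sum()),
        "gln": float((P.sum(axis=1) ** 2).sum() / N),
        "glnn": float((P.sum(axis=1) ** 2).sum() / N**2),
        "size_n": float((P.sum(axis=0) ** 2).sum() / N),
        "size_nn": float((P.sum(axis=0) ** 2).sum() / N**2),
        "percentage": float(N / n_voxels),
        "gl_variance": float((p * (i - mu_i) ** 2).sum()),
        "size_variance": float((p * (j - mu_j) ** 2).sum()),
        "entropy": float(-(p[nz] * np.log2(p[nz] + EPS)).sum()),
        "low_gl": float((p / i**2).sum()),
        "high_gl": float((p * i**2).sum()),
        "small_low": float((p / (i**2 * j**2)).sum()),
        "small_high": float((p * i**2 / j**2).sum()),
        "large_low": float((p * j**2 / i**2).sum()),
        "large_high": float((p * i**2 * j**2).sum()),
    }
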