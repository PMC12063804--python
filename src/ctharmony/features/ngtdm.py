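"""Neighbouring gray-tone difference matrix features (5).

For each gray level i: n_i voxels, p_i = n_i / Nv, and s_i the summed
absolute difference between i and the mean gray level of each voxel's
valid 26-neighbourhood (voxels with no ROI neighbour contribute 0).
"""

from __future__ import annotations

import numpy as np

from ctharmony.features._utils import all_neighbors, offset_slices

NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

COARSENESS_CAP = 1e6


def ngtdm(levels: np.ndarray, n_levels: int):
    valid = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for d in all_neighbors():
        src, dst = offset_slices(levels.shape, d)
        if src is None:
            continue
        ok = valid[src]
        nb_sum[dst] += np.where(ok, levels[src], 0)
        nb_cnt[dst] += ok
    has_nb = valid & (nb_cnt > 0)
    diff = np.zeros(levels.shape)
    diff[has_nb] = np.abs(levels[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb])
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for lvl in range(1, n_levels + 1):
        sel = levels == lvl
        n_i[lvl - 1] = sel.sum()
        s_i[lvl - 1] = diff[sel].sum()
    return n_i, s_i


def compute(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    n_i, s_i = ngtdm(levels, n_levels)
    Nv = n_i.sum()
    p_i = n_i / Nv
    i = np.arange(1, n_levels + 1, dtype=float)
    present = p_i > 0
    Ngp = int(present.sum())

    ps_dot = (p_i * s_i).sum()
    coarseness = 1.0 / ps_dot if ps_dot > 0 else COARSENESS_CAP

    if Ngp > 1:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pp = np.outer(p_i[present], p_i[present])
        contrast = (pp * (ii - jj) ** 2).sum() / (Ngp * (Ngp - 1)) * (s_i.sum() / Nv)
        denom = np.abs(
            (i[present] * p_i[present])[:, None] - (i[present] * p_i[present])[None, :]
        ).sum()
        busyness = ps_dot / denom if denom > 0 else 0.0
        pi_v, si_v = p_i[present], s_i[present]
        num = np.abs(ii - jj) * (
            (pi_v * si_v)[:, None] + (pi_v * si_v)[None, :]
        ) / (pi_v[:, None] + pi_v[None, :])
        complexity = num.sum() / Nv
        strength_num = ((pi_v[:, None] + pi_v[None, :]) * (ii - jj) ** 2).sum()
        strength = strength_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }
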