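"""Gray-level co-occurrence matrix features (24).

A symmetric GLCM is built for each of the 13 unique 3D offsets at
distance 1; each feature is averaged over offsets that yield at least one
voxel pair.  Gray levels enter the formulas as their integer bin indices
(1..Ng).
"""

from __future__ import annotations

import numpy as np

from ctharmony.features._utils import EPS, offset_pairs, unique_directions

NAMES = [
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "Mcc",
]


def cooccurrence_matrix(levels: np.ndarray, d, n_levels: int) -> np.ndarray:
    """Symmetric (unnormalized) co-occurrence counts for one offset."""
    a, b = offset_pairs(levels, d)
    if a is None:
        return np.zeros((n_levels, n_levels))
    ok = (a > 0) & (b > 0)
    if not ok.any():
        return np.zeros((n_levels, n_levels))
    counts = np.bincount(
        (a[ok] - 1) * n_levels + (b[ok] - 1), minlength=n_levels * n_levels
    ).reshape(n_levels, n_levels)
    return counts + counts.T


def _features_from_matrix(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    p = P / P.sum()
    i = np.arange(1, Ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    var_x = ((i - mu_x) ** 2 * px).sum()
    var_y = ((i - mu_y) ** 2 * py).sum()

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(Ng, dtype=float)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * Ng + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    diff_avg = (k_diff * p_diff).sum()
    HX = -(px * np.log2(px + EPS)).sum()
    HY = -(py * np.log2(py + EPS)).sum()
    HXY = -(p * np.log2(p + EPS)).sum()
    pxy = np.outer(px, py)
    HXY1 = -(p * np.log2(pxy + EPS)).sum()
    HXY2 = -(pxy * np.log2(pxy + EPS)).sum()

    if var_x > EPS and var_y > EPS:
        correlation = ((ii * jj * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 1.0
    imc1 = (HXY - HXY1) / max(HX, HY) if max(HX, HY) > EPS else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY))))

    off_diag = np.abs(ii - jj) > 0
    inv_var = (p[off_diag] / (ii - jj)[off_diag] ** 2).sum() if off_diag.any() else 0.0

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": float(mu_x),
        "ClusterProminence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": float(diff_avg),
        "DifferenceEntropy": float(-(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": float(HXY),
        "Imc1": float(imc1),
        "Imc2": float(imc2),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / Ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / Ng)).sum()),
        "InverseVariance": float(inv_var),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "SumSquares": float(var_x),
        "Mcc": float(_mcc(p, px, py)),
    }


def _mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    keep = px > EPS
    if keep.sum() <= 1:
        return 1.0
    ps, pxs, pys = p[np.ix_(keep, keep)], px[keep], py[keep]
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    Q = (ps / pys[None, :]) @ ps.T / pxs[:, None]
    eigs = np.sort(np.abs(np.linalg.eigvals(Q)))
    return float(np.sqrt(max(0.0, eigs[-2].real)))


def compute(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    per_dir = []
    for d in unique_directions():
        M = cooccurrence_matrix(levels, d, n_levels)
        if M.sum() > 0:
            per_dir.append(_features_from_matrix(M))
    if not per_dir:
        raise ValueError("no co-occurring voxel pairs in ROI")
    return {name: float(np.mean([f[name] for f in per_dir])) for name in NAMES}
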