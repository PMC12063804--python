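"""First-order intensity statistics (18 features).

Computed on raw HU values; entropy and uniformity use the discretized
histogram.  Skewness/kurtosis/variance are population moments; kurtosis
is the plain (non-excess) fourth standardized moment.
"""

from __future__ import annotations

import numpy as np

from ctharmony.features._utils import EPS, discretize

NAMES = [
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
]


def compute(values: np.ndarray, bin_width: float, voxel_volume: float) -> dict[str, float]:
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    mean = x.mean()
    m2 = ((x - mean) ** 2).mean()
    m3 = ((x - mean) ** 3).mean()
    m4 = ((x - mean) ** 4).mean()
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = np.abs(robust - robust.mean()).mean() if robust.size else 0.0

    counts = np.bincount(discretize(x, bin_width))[1:]
    p = counts[counts > 0] / n

    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(voxel_volume * (x**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()) if p.size > 1 else 0.0,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(rmad),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(m3 / m2**1.5) if m2 > EPS else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > EPS else 0.0,
        "Variance": float(m2),
        "Uniformity": float((p**2).sum()),
    }
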