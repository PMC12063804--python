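"""Radiomic feature extraction: 93 non-shape features per ROI.

Class breakdown: 18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM +
14 GLDM + 5 NGTDM = 93 — the standard non-shape feature classes.
First-order features are computed on raw HU values; texture classes on
the fixed-bin-width discretized ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ctharmony.features import firstorder, glcm, gldm, glrlm, glszm, ngtdm
from ctharmony.features._utils import roi_levels
from ctharmony.types import LabeledVolume

logger = logging.getLogger(__name__)

CLASS_MODULES = {
    "firstorder": firstorder,
    "glcm": glcm,
    "glrlm": glrlm,
    "glszm": glszm,
    "gldm": gldm,
    "ngtdm": ngtdm,
}

CLASS_COUNTS = {
    "firstorder": 18,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}

FEATURE_NAMES: list[str] = [
    f"{cls}_{name}" for cls, mod in CLASS_MODULES.items() for name in mod.NAMES
]
assert len(FEATURE_NAMES) == 93

KEY_COLUMNS = ["group", "scan", "roi"]


class MissingROIError(ValueError):
    """The requested ROI label is absent from the mask."""


class DegenerateROIError(ValueError):
    """The ROI has fewer than 2 voxels."""


class EmptyTableError(RuntimeError):
    """No ROI produced a feature row."""


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings.

    bin_width : HU width of the gray-level discretization bins (default 25).
    gldm_alpha : dependence tolerance in gray levels.
    """

    bin_width: float = 25.0
    gldm_alpha: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


def extract_features(
    volume: LabeledVolume, roi_label: int, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Compute all 93 features for one ROI; returns an ordered name->value dict."""
    config = config or ExtractionConfig()
    n_vox = int((volume.mask == roi_label).sum())
    if n_vox == 0:
        raise MissingROIError(f"ROI label {roi_label} not present in mask")
    if n_vox < 2:
        raise DegenerateROIError(f"ROI label {roi_label} has a single voxel")

    levels, values = roi_levels(volume.intensities, volume.mask, roi_label, config.bin_width)
    n_levels = int(levels.max())
    voxel_volume = float(np.prod(volume.spacing))

    out: dict[str, float] = {}
    for name, v in firstorder.compute(values, config.bin_width, voxel_volume).items():
        out[f"firstorder_{name}"] = v
    for name, v in glcm.compute(levels, n_levels).items():
        out[f"glcm_{name}"] = v
    for name, v in glrlm.compute(levels, n_levels).items():
        out[f"glrlm_{name}"] = v
    for name, v in glszm.compute(levels, n_levels).items():
        out[f"glszm_{name}"] = v
    for name, v in gldm.compute(levels, n_levels, config.gldm_alpha).items():
        out[f"gldm_{name}"] = v
    for name, v in ngtdm.compute(levels, n_levels).items():
        out[f"ngtdm_{name}"] = v

    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad}")
    return out


def extract_dataset(
    volumes: Mapping[tuple[int, int], LabeledVolume],
    config: ExtractionConfig | None = None,
    roi_labels: tuple[int, ...] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """Extract a long-format feature table: one row per (group, scan, roi).

    ROIs that fail extraction are excluded with a logged reason; if no row
    succeeds an :class:`EmptyTableError` is raised.
    """
    config = config or ExtractionConfig()
    rows, keys = [], []
    for (group, scan), vol in volumes.items():
        for roi in roi_labels:
            try:
                feats = extract_features(vol, roi, config)
            except (MissingROIError, DegenerateROIError, ValueError) as exc:
                logger.warning("skipping (group=%s, scan=%s, roi=%s): %s", group, scan, roi, exc)
                continue
            keys.append((group, scan, roi))
            rows.append(feats)
    if not rows:
        raise EmptyTableError("no (group, scan, roi) produced features")
    table = pd.DataFrame(rows, columns=FEATURE_NAMES)
    keys_df = pd.DataFrame(keys, columns=KEY_COLUMNS)
    return pd.concat([keys_df, table], axis=1)
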