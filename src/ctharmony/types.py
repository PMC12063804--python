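"""Core domain types shared across modules.

A *group* is one CT reconstruction-protocol arm (algorithm, kernel, slice
thickness/spacing); a *scan* is one test-retest acquisition; the four ROI
labels are liver-region tissue classes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

ROI_NAMES = {1: "normal_liver", 2: "benign_cyst", 3: "hemangioma", 4: "metastasis"}


class InvalidSpecError(ValueError):
    """A domain object violates its invariants."""


@dataclass(frozen=True)
class GroupConfig:
    """One reconstruction-protocol arm.

    Parameters
    ----------
    group_id : int
        Protocol group identifier (1-8 in the default study).
    algorithm : str
        ``"FBP"`` (filtered back projection) or ``"IR"`` (iterative
        reconstruction).  FBP arms carry more image noise.
    kernel : str
        Reconstruction-kernel label (e.g. ``"B30f"``).  Image sharpness is
        parameterized by ``kernel_sigma_mm``, the point-spread-function
        Gaussian sigma.
    kernel_sigma_mm : float
        PSF sigma in mm; smaller = sharper.
    slice_thickness_mm, slice_spacing_mm : float
        Axial reconstruction geometry.
    """

    group_id: int
    algorithm: str
    kernel: str
    kernel_sigma_mm: float
    slice_thickness_mm: float
    slice_spacing_mm: float

    def __post_init__(self) -> None:
        if self.algorithm not in ("FBP", "IR"):
            raise InvalidSpecError(f"algorithm must be FBP or IR, got {self.algorithm!r}")
        if not (self.slice_thickness_mm >= self.slice_spacing_mm > 0):
            raise InvalidSpecError(
                "require slice_thickness >= slice_spacing > 0, got "
                f"{self.slice_thickness_mm}/{self.slice_spacing_mm}"
            )
        if self.kernel_sigma_mm <= 0:
            raise InvalidSpecError("kernel_sigma_mm must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


# Kernel sharpness stand-ins: the sharper "26f" kernels get a smaller PSF
# sigma than the smoother "30f" kernels.
KERNEL_SIGMA_MM = {"B26f": 0.6, "I26f": 0.6, "B30f": 1.0, "I30f": 1.0}


def default_groups() -> list[GroupConfig]:
    """The eight protocol arms of the default study design."""
    rows = [
        (1, "FBP", "B26f", 1.0, 0.75),
        (2, "FBP", "B30f", 1.5, 1.0),
        (3, "FBP", "B30f", 2.0, 1.0),
        (4, "FBP", "B30f", 3.0, 2.0),
        (5, "IR", "I26f", 1.0, 0.75),
        (6, "IR", "I30f", 1.5, 1.0),
        (7, "IR", "I30f", 2.0, 1.0),
        (8, "IR", "I30f", 3.0, 2.0),
    ]
    return [
        GroupConfig(g, alg, k, KERNEL_SIGMA_MM[k], th, sp) for g, alg, k, th, sp in rows
    ]


REFERENCE_GROUP = 7


@dataclass(frozen=True)
class TissueSpec:
    """HU statistics of one ROI tissue class.

    ``texture_correlation_length_mm`` sets the spatial scale of the
    correlated texture filling the ROI.
    """

    label: int
    name: str
    mean_hu: float
    hu_sd: float
    texture_correlation_length_mm: float = 2.0

    def __post_init__(self) -> None:
        if not 1 <= self.label <= 4:
            raise InvalidSpecError(f"ROI label must be 1-4, got {self.label}")
        if self.hu_sd <= 0 or self.texture_correlation_length_mm <= 0:
            raise InvalidSpecError("hu_sd and correlation length must be > 0")


def default_tissues() -> list[TissueSpec]:
    """Liver-region tissue statistics inside the [-45, 125] HU analysis window."""
    return [
        TissueSpec(1, "normal_liver", 60.0, 12.0, 2.0),
        TissueSpec(2, "benign_cyst", 5.0, 8.0, 1.5),
        TissueSpec(3, "hemangioma", 45.0, 12.0, 2.5),
        TissueSpec(4, "metastasis", 30.0, 15.0, 3.0),
    ]


@dataclass
class LabeledVolume:
    """A 3D HU volume with voxel spacing and an aligned integer ROI mask."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.intensities.ndim != 3:
            raise InvalidSpecError("intensities must be 3D")
        if self.intensities.shape != self.mask.shape:
            raise InvalidSpecError(
                f"mask shape {self.mask.shape} != intensity shape {self.intensities.shape}"
            )
        if not np.issubdtype(self.mask.dtype, np.integer):
            self.mask = self.mask.astype(np.int16)
        labels = set(np.unique(self.mask).tolist())
        if not labels <= {0, 1, 2, 3, 4}:
            raise InvalidSpecError(f"mask labels must be within {{0..4}}, got {sorted(labels)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(self.intensities.copy(), tuple(self.spacing), self.mask.copy())

    def roi_values(self, label: int) -> np.ndarray:
        return self.intensities[self.mask == label]


@dataclass
class SimDesign:
    """Design of a feature-table simulation under the location/scale batch model.

    Values are generated as ``y_ijg = alpha_g + beta_g . X_j + gamma_ig +
    delta_ig * eps`` for batch i, sample j, feature g, with eps ~ N(0,
    noise_sd).  ``covariates`` (X) are shared across batches for the same
    sample index, which encodes the paired test-retest structure: sample j
    of batch i is the same object as sample j of the reference batch.

    ``gamma`` / ``delta`` may be scalars, per-batch vectors, (batch,
    feature) matrices, or (roi, batch, feature) arrays when ``n_rois > 1``.
    """

    n_features: int
    batch_ids: Sequence[int]
    n_per_batch: int
    alpha: float | np.ndarray = 0.0
    beta: np.ndarray | None = None
    covariates: np.ndarray | None = None
    gamma: float | np.ndarray = 0.0
    delta: float | np.ndarray = 1.0
    noise_sd: float = 1.0
    n_rois: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0 or self.n_per_batch <= 0 or self.n_rois <= 0:
            raise InvalidSpecError("n_features, n_per_batch, n_rois must be positive")
        if len(set(self.batch_ids)) != len(self.batch_ids):
            raise InvalidSpecError("batch_ids must be unique")
        if np.any(np.asarray(self.delta, dtype=float) <= 0):
            raise InvalidSpecError("delta must be > 0 for all batches")
        if self.noise_sd <= 0:
            raise InvalidSpecError("noise_sd must be > 0")
        if (self.beta is None) != (self.covariates is None):
            raise InvalidSpecError("beta and covariates must be given together")
        if self.covariates is not None:
            cov = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if cov.shape[0] != self.n_per_batch:
                raise InvalidSpecError(
                    f"covariates have {cov.shape[0]} rows, expected n_per_batch={self.n_per_batch}"
                )

    def broadcast_effect(self, value: float | np.ndarray) -> np.ndarray:
        """Return the effect as an (n_rois, n_batches, n_features) array."""
        n_b, n_f, n_r = len(self.batch_ids), self.n_features, self.n_rois
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.broadcast_to(arr, (n_r, n_b, n_f)).copy()
        if arr.ndim == 1:
            if arr.shape[0] != n_b:
                raise InvalidSpecError(f"per-batch effect has length {arr.shape[0]}, expected {n_b}")
            return np.broadcast_to(arr[None, :, None], (n_r, n_b, n_f)).copy()
        if arr.ndim == 2:
            if arr.shape != (n_b, n_f):
                raise InvalidSpecError(f"effect shape {arr.shape} != (n_batches, n_features)")
            return np.broadcast_to(arr[None], (n_r, n_b, n_f)).copy()
        if arr.shape != (n_r, n_b, n_f):
            raise InvalidSpecError(f"effect shape {arr.shape} != (n_rois, n_batches, n_features)")
        return arr.copy()
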