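"""Synthetic multi-protocol phantom data.

Two generators back the test surface of every downstream stage:

* :func:`generate_phantom` + :func:`apply_acquisition` build labeled HU
  volumes under the eight reconstruction-protocol arms (PSF blur, axial
  slice-profile resampling, algorithm-dependent noise), emulating a
  test-retest phantom study without any external scans.
* :func:`simulate_feature_table` draws feature tables directly from the
  location/scale batch-effect model with known ground-truth effects, so
  batch-effect recovery is checkable against the truth.

All randomness flows from explicit integer seeds; there is no global RNG
state anywhere in this module.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ctharmony.types import (
    GroupConfig,
    InvalidSpecError,
    LabeledVolume,
    SimDesign,
    TissueSpec,
    default_groups,
    default_tissues,
)

AIR_HU = -1000.0
BODY_HU = 20.0
LIVER_BG_HU = 55.0

# ROI multiplicity mirrors the annotated phantom: two normal-liver blobs,
# two benign cysts, one hemangioma, one metastasis.
ROI_BLOB_COUNTS = {1: 2, 2: 2, 3: 1, 4: 1}


class PlacementError(RuntimeError):
    """The volume is too small to place the requested ROI blobs."""


def _child_seed(*parts: int) -> int:
    """Deterministic derived seed < 2**31 from integer parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] & 0x7FFFFFFF)


def _correlated_noise(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    correlation_length_mm: float,
    sd: float,
) -> np.ndarray:
    """Zero-mean Gaussian field with given spatial correlation length and sd."""
    white = rng.standard_normal(shape)
    sigma_vox = [correlation_length_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    s = smooth.std()
    if s < 1e-12:  # pathological tiny volume: fall back to white noise
        return white * sd
    return smooth * (sd / s)


def _super_ellipsoid(shape, center, radii, power=2.5) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc += np.abs((g - c) / r) ** power
    return acc <= 1.0


def generate_phantom(
    seed: int,
    shape: tuple[int, int, int] = (64, 64, 48),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tissues: Sequence[TissueSpec] | None = None,
    max_attempts: int = 200,
) -> LabeledVolume:
    """Generate a liver-like labeled phantom volume.

    The anatomy is a soft-tissue body ellipsoid containing a liver
    super-ellipsoid; ellipsoidal ROI blobs with seeded random centers are
    placed inside the liver without overlap and filled with spatially
    correlated texture at each tissue's HU statistics.

    Raises
    ------
    InvalidSpecError
        If the tissue list does not contain labels 1-4 exactly once.
    PlacementError
        If the volume is too small to host all ROI blobs.
    """
    if tissues is None:
        tissues = default_tissues()
    if any(n <= 0 for n in shape):
        raise InvalidSpecError(f"shape must be positive, got {shape}")
    labels = sorted(t.label for t in tissues)
    if labels != [1, 2, 3, 4]:
        raise InvalidSpecError(f"need tissue labels 1-4 exactly once, got {labels}")

    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in shape)
    intens = np.full(shape, AIR_HU, dtype=np.float64)
    mask = np.zeros(shape, dtype=np.int16)

    center = [n / 2.0 for n in shape]
    body = _super_ellipsoid(shape, center, [0.46 * n for n in shape], power=2.0)
    liver = _super_ellipsoid(shape, center, [0.38 * n for n in shape], power=2.5)
    intens[body] = BODY_HU
    intens[liver] = LIVER_BG_HU
    intens[liver] += _correlated_noise(rng, shape, spacing, 2.0, 4.0)[liver]

    min_dim = min(shape)
    if min_dim < 12:
        raise PlacementError(f"shape {shape} too small to place ROI blobs")

    occupied = np.zeros(shape, dtype=bool)
    liver_idx = np.argwhere(liver)
    by_label = {t.label: t for t in tissues}
    for label in (1, 2, 3, 4):
        tissue = by_label[label]
        for _ in range(ROI_BLOB_COUNTS[label]):
            placed = False
            for _attempt in range(max_attempts):
                c = liver_idx[rng.integers(len(liver_idx))]
                radii = rng.uniform(0.09, 0.14, size=3) * min_dim
                blob = _super_ellipsoid(shape, c, radii, power=2.0) & liver
                if blob.sum() < 8 or (blob & occupied).any():
                    continue
                mask[blob] = label
                occupied |= ndimage.binary_dilation(blob, iterations=1)
                texture = _correlated_noise(
                    rng, shape, spacing, tissue.texture_correlation_length_mm, tissue.hu_sd
                )
                intens[blob] = tissue.mean_hu + texture[blob]
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place blob for label {label} in shape {shape}"
                )
    return LabeledVolume(intens, tuple(spacing), mask)


def apply_acquisition(
    volume: LabeledVolume,
    group: GroupConfig,
    seed: int,
    noise_sd_hu: float = 5.0,
    fbp_noise_factor: float = 1.5,
) -> LabeledVolume:
    """Simulate acquisition under one protocol arm.

    The intensities are perturbed by additive Gaussian noise whose
    amplitude depends on the reconstruction algorithm (FBP noisier than
    IR), blurred by the kernel's point-spread function, and passed through
    an axial slice profile: box-averaged over the slice thickness,
    sampled at the slice spacing, and linearly resampled back onto the
    native grid.  The ROI mask is returned unchanged (the output lives on
    the input grid).
    """
    if group.slice_thickness_mm <= 0 or group.slice_spacing_mm <= 0:
        raise InvalidSpecError("non-positive slice thickness/spacing")
    rng = np.random.default_rng(seed)
    out = volume.copy()
    x = out.intensities

    amp = noise_sd_hu * (fbp_noise_factor if group.algorithm == "FBP" else 1.0)
    if amp > 0:
        x = x + rng.normal(0.0, amp, size=x.shape)

    sigma_vox = [group.kernel_sigma_mm / s for s in volume.spacing]
    x = ndimage.gaussian_filter(x, sigma=sigma_vox, mode="nearest")

    dz = volume.spacing[2]
    nz = x.shape[2]
    box = max(1, int(round(group.slice_thickness_mm / dz)))
    if box > 1:
        x = ndimage.uniform_filter1d(x, size=box, axis=2, mode="nearest")
    zoom = dz / group.slice_spacing_mm
    if abs(zoom - 1.0) > 1e-12:
        coarse = ndimage.zoom(x, (1, 1, zoom), order=1, mode="nearest", grid_mode=True)
        x = ndimage.zoom(
            coarse, (1, 1, nz / coarse.shape[2]), order=1, mode="nearest", grid_mode=True
        )
        if x.shape[2] != nz:  # guard against rounding in zoom output size
            x = x[:, :, :nz] if x.shape[2] > nz else np.pad(
                x, ((0, 0), (0, 0), (0, nz - x.shape[2])), mode="edge"
            )
    out.intensities = x
    return out


def simulate_study(
    seed: int,
    groups: Sequence[GroupConfig] | None = None,
    n_scans: int = 30,
    shape: tuple[int, int, int] = (64, 64, 48),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tissues: Sequence[TissueSpec] | None = None,
    noise_sd_hu: float = 5.0,
) -> dict[tuple[int, int], LabeledVolume]:
    """Generate a full test-retest study: ``{(group_id, scan_id): volume}``.

    Scan *s* shares the same underlying phantom realization across all
    groups (paired test-retest structure); acquisition noise is drawn
    independently per (group, scan).
    """
    if groups is None:
        groups = default_groups()
    study: dict[tuple[int, int], LabeledVolume] = {}
    for s in range(n_scans):
        phantom = generate_phantom(_child_seed(seed, 0, s), shape, spacing, tissues)
        for g in groups:
            study[(g.group_id, s)] = apply_acquisition(
                phantom, g, _child_seed(seed, g.group_id, s), noise_sd_hu=noise_sd_hu
            )
    return study


def feature_names(n_features: int) -> list[str]:
    return [f"f{i:03d}" for i in range(n_features)]


def simulate_feature_table(design: SimDesign) -> pd.DataFrame:
    """Draw a feature table from the location/scale batch-effect model.

    Returns a long-format DataFrame with key columns ``group, scan, roi``
    followed by the feature columns.  Ground-truth effects are attached in
    ``df.attrs`` (``gamma``/``delta`` with shape (n_rois, n_batches,
    n_features), plus ``alpha``, ``beta``, ``covariates``) for recovery
    tests.  Deterministic for a fixed ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n_b, n_f, n_r, n_s = (
        len(design.batch_ids),
        design.n_features,
        design.n_rois,
        design.n_per_batch,
    )
    gamma = design.broadcast_effect(design.gamma)
    delta = design.broadcast_effect(design.delta)
    alpha = np.broadcast_to(np.asarray(design.alpha, dtype=float), (n_f,))

    cov_term = np.zeros((n_s, n_f))
    if design.covariates is not None:
        X = np.asarray(design.covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        beta = np.asarray(design.beta, dtype=float)
        if beta.ndim == 1:
            beta = np.broadcast_to(beta[:, None], (X.shape[1], n_f))
        cov_term = X @ beta  # (n_samples, n_features)

    rows = []
    values = []
    for r in range(n_r):
        roi = r + 1
        for bi, b in enumerate(design.batch_ids):
            eps = rng.normal(0.0, design.noise_sd, size=(n_s, n_f))
            y = alpha[None, :] + cov_term + gamma[r, bi][None, :] + delta[r, bi][None, :] * eps
            for j in range(n_s):
                rows.append((b, j, roi))
            values.append(y)
    keys = pd.DataFrame(rows, columns=["group", "scan", "roi"])
    feats = pd.DataFrame(np.vstack(values), columns=feature_names(n_f))
    table = pd.concat([keys, feats], axis=1)
    table.attrs["gamma"] = gamma
    table.attrs["delta"] = delta
    table.attrs["alpha"] = np.array(alpha)
    table.attrs["beta"] = None if design.beta is None else np.asarray(design.beta, float)
    table.attrs["covariates"] = (
        None if design.covariates is None else np.asarray(design.covariates, float)
    )
    table.attrs["batch_ids"] = list(design.batch_ids)
    return table


def default_sim_design(seed: int = 0, n_per_batch: int = 30, n_rois: int = 4) -> SimDesign:
    """The default study-shaped simulation: 93 features x 8 batches.

    Batch effects: additive gamma ~ N(0, 3^2) and multiplicative delta ~
    LogNormal(0, 0.25) per (roi, batch, feature); a shared per-scan latent
    covariate (sd 1) with coefficient ~10 per feature carries the paired
    test-retest signal; unit noise sd.
    """
    rng = np.random.default_rng(_child_seed(seed, 9999))
    n_f, batches = 93, list(range(1, 9))
    gamma = rng.normal(0.0, 3.0, size=(n_rois, len(batches), n_f))
    delta = np.exp(rng.normal(0.0, 0.25, size=(n_rois, len(batches), n_f)))
    covariates = rng.normal(0.0, 1.0, size=(n_per_batch, 1))
    beta = rng.uniform(8.0, 12.0, size=n_f)[None, :] * np.ones((1, 1))
    alpha = rng.normal(0.0, 1.0, size=n_f)
    return SimDesign(
        n_features=n_f,
        batch_ids=batches,
        n_per_batch=n_per_batch,
        alpha=alpha,
        beta=beta,
        covariates=covariates,
        gamma=gamma,
        delta=delta,
        noise_sd=1.0,
        n_rois=n_rois,
        seed=_child_seed(seed, 1234),
    )
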