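"""Image standardization: isotropic resampling, background cropping,
fixed-shape resampling, HU clipping, ROI relabeling.

Intensities are interpolated linearly and masks with nearest neighbour
throughout, so no new mask labels can be introduced by resampling.
Intensities stay in HU here; rescaling to [0, 1] happens only at the GAN
boundary.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy import ndimage

from ctharmony.types import InvalidSpecError, LabeledVolume

DEFAULT_CLIP = (-45.0, 125.0)
DEFAULT_SHAPE = (256, 256, 246)
BACKGROUND_THRESHOLD_HU = -500.0  # air vs phantom material


class CropError(RuntimeError):
    """No foreground voxels above the background threshold."""


class UnknownLabelError(KeyError):
    """A mask label has no relabeling entry."""


def _zoom_pair(intens: np.ndarray, mask: np.ndarray, factors) -> tuple[np.ndarray, np.ndarray]:
    zi = ndimage.zoom(intens, factors, order=1, mode="nearest", grid_mode=True)
    zm = ndimage.zoom(mask, factors, order=0, mode="nearest", grid_mode=True)
    return zi, zm


def resample_isotropic(
    volume: LabeledVolume, target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> LabeledVolume:
    """Resample onto a grid with ``target_spacing`` (linear / nearest)."""
    factors = tuple(s / t for s, t in zip(volume.spacing, target_spacing))
    if all(abs(f - 1.0) <= 1e-12 for f in factors):
        return volume.copy()
    intens, mask = _zoom_pair(volume.intensities, volume.mask, factors)
    return LabeledVolume(intens, tuple(target_spacing), mask.astype(np.int16))


def standardize_volume(
    volume: LabeledVolume,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    target_shape: tuple[int, int, int] = DEFAULT_SHAPE,
    background_threshold: float = BACKGROUND_THRESHOLD_HU,
) -> LabeledVolume:
    """Resample to isotropic spacing, crop background, resample to a fixed grid.

    The crop keeps the tight bounding box of voxels above
    ``background_threshold`` (removing air / scanner bed).  The final
    resample forces the grid to ``target_shape``; the nominal spacing of
    the output is ``target_spacing`` scaled by the shape change.
    """
    iso = resample_isotropic(volume, target_spacing)
    intens, mask = iso.intensities, iso.mask

    # 2. background crop
    fg = intens > background_threshold
    if not fg.any():
        raise CropError("no voxels above background threshold; cannot crop")
    slices = ndimage.find_objects(fg.astype(np.int8))[0]
    intens, mask = intens[slices], mask[slices]

    # 3. fixed-shape resampling
    if tuple(intens.shape) != tuple(target_shape):
        factors = tuple(t / s for s, t in zip(intens.shape, target_shape))
        intens, mask = _zoom_pair(intens, mask, factors)
        # zoom rounds output size; enforce the exact grid
        intens = _fit_shape(intens, target_shape, fill=float(intens.min()))
        mask = _fit_shape(mask, target_shape, fill=0)
    return LabeledVolume(intens, tuple(target_spacing), mask.astype(np.int16))


def _fit_shape(arr: np.ndarray, shape, fill) -> np.ndarray:
    pads, slices = [], []
    for n, t in zip(arr.shape, shape):
        pads.append((0, max(0, t - n)))
        slices.append(slice(0, t))
    if any(p[1] for p in pads):
        arr = np.pad(arr, pads, mode="constant", constant_values=fill)
    return arr[tuple(slices)]


def clip_intensity(
    volume: LabeledVolume, lo: float = DEFAULT_CLIP[0], hi: float = DEFAULT_CLIP[1]
) -> LabeledVolume:
    """Clip every intensity into [lo, hi]; the mask is untouched."""
    if lo >= hi:
        raise InvalidSpecError(f"invalid clip range: lo={lo} >= hi={hi}")
    out = volume.copy()
    np.clip(out.intensities, lo, hi, out=out.intensities)
    return out


def relabel_rois(mask: np.ndarray, mapping: Mapping[int, int]) -> np.ndarray:
    """Relabel nonzero mask values per ``mapping``; 0 (background) is preserved.

    Every nonzero label present in the mask must have a mapping entry.
    """
    mask = np.asarray(mask)
    present = set(np.unique(mask).tolist()) - {0}
    missing = present - set(int(k) for k in mapping)
    if missing:
        raise UnknownLabelError(f"labels without mapping entry: {sorted(missing)}")
    out = np.zeros_like(mask)
    for old in present:
        out[mask == old] = mapping[int(old)]
    return out
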