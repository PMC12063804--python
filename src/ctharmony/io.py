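"""NIfTI / CSV / manifest input-output."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

import ctharmony
from ctharmony.types import LabeledVolume

KEY_COLUMNS = ["group", "scan", "roi"]


def _affine(spacing) -> np.ndarray:
    # RAS orientation, spacing on the diagonal
    return np.diag(list(spacing) + [1.0])


def write_nifti(volume: LabeledVolume, image_path, mask_path) -> None:
    aff = _affine(volume.spacing)
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), aff), str(image_path))
    nib.save(nib.Nifti1Image(volume.mask.astype(np.int16), aff), str(mask_path))


def read_nifti(image_path, mask_path) -> LabeledVolume:
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabeledVolume(
        np.asarray(img.dataobj, dtype=np.float64),
        spacing,
        np.asarray(msk.dataobj).astype(np.int16),
    )


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def software_versions() -> dict:
    import scipy
    import sklearn

    return {
        "ctharmony": ctharmony.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "nibabel": nib.__version__,
    }


def write_manifest(path, payload: dict) -> None:
    payload = dict(payload)
    payload.setdefault("software", software_versions())
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
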