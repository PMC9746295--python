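"""Reading and writing series, label maps, fields and closure labels.

Image and label series are stored as NIfTI volumes with the frames stacked
on the third axis; displacement-field series add a trailing axis of length 2
(index 0 = x/column displacement, index 1 = y/row displacement, pixel
units).  Closure labels are CSV with columns ``frame_index, closure``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .metrics import ClosureSeries

__all__ = [
    "save_image_series", "load_image_series",
    "save_label_series", "load_label_series",
    "save_field_series", "load_field_series",
    "save_closure_series", "load_closure_series",
]

_FIELD_DESC = b"frames on axis 2; trailing axis: 0=x(col) disp, 1=y(row) disp, px"


def _to_nifti(arr: np.ndarray, descrip: bytes | None = None) -> nib.Nifti1Image:
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    if descrip:
        img.header["descrip"] = descrip
    return img


def save_image_series(images: np.ndarray, path) -> None:
    """(T, H, W) float series -> NIfTI with frames stacked on the third axis."""
    arr = np.moveaxis(np.asarray(images, dtype=np.float32), 0, -1)
    nib.save(_to_nifti(arr), str(path))


def load_image_series(path) -> np.ndarray:
    arr = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float32)
    return np.moveaxis(arr, -1, 0)


def save_label_series(labels: np.ndarray, path) -> None:
    arr = np.moveaxis(np.asarray(labels, dtype=np.int16), 0, -1)
    nib.save(_to_nifti(arr), str(path))


def load_label_series(path) -> np.ndarray:
    arr = np.asanyarray(nib.load(str(path)).dataobj).astype(np.int16)
    return np.moveaxis(arr, -1, 0)


def save_field_series(fields: np.ndarray, path) -> None:
    """(T, H, W, 2) fields -> NIfTI (H, W, T, 2) with the convention in the header."""
    fields = np.asarray(fields, dtype=np.float32)
    if fields.ndim != 4 or fields.shape[-1] != 2:
        raise ValueError("expected a (T, H, W, 2) displacement-field series")
    arr = np.moveaxis(fields, 0, 2)
    nib.save(_to_nifti(arr, _FIELD_DESC), str(path))


def load_field_series(path) -> np.ndarray:
    arr = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    return np.moveaxis(arr, 2, 0)


def save_closure_series(closures: ClosureSeries, path) -> None:
    pd.DataFrame({
        "frame_index": np.arange(len(closures)),
        "closure": closures.to_array(),
    }).to_csv(path, index=False)


def load_closure_series(path) -> ClosureSeries:
    df = pd.read_csv(path)
    return ClosureSeries(tuple(int(v) for v in df["closure"]))
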