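"""Thin NIfTI wrappers (nibabel) with lossless array/affine round-trips."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


class NiftiIOError(IOError):
    pass


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a volume; returns (data array in file dtype, 4x4 affine)."""
    path = Path(path)
    if not path.exists():
        raise NiftiIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt header / truncated file
        raise NiftiIOError(f"failed to read NIfTI file {path}: {exc}") from exc
    return data, np.asarray(img.affine)


def write_nifti(volume: np.ndarray, affine: np.ndarray, path: str | Path,
                dtype=None) -> None:
    """Write ``volume`` with ``affine`` passed through untouched.

    Label volumes should be written as unsigned integers, probability maps
    as 32-bit floats; ``dtype`` casts before writing when given.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(volume)
    if dtype is not None:
        arr = arr.astype(dtype)
    img = nib.Nifti1Image(arr, np.asarray(affine, dtype=np.float64))
    img.header.set_data_dtype(arr.dtype)
    nib.save(img, str(path))
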