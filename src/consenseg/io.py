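"""NIfTI reading/writing for SUV volumes and binary masks.

NIfTI-1 (``.nii`` / ``.nii.gz``) is the sole supported format; volumes are
written as float32, masks as uint8 {0, 1}. DICOM / DICOM-RTSTRUCT input is a
non-goal — convert externally (e.g. dcm2niix, plastimatch) before use.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .grid import BinaryMask, ImageGrid, SUVVolume

__all__ = ["read_volume", "read_mask", "write_volume", "grid_from_affine"]


def grid_from_affine(shape, affine: np.ndarray) -> ImageGrid:
    """Decompose a NIfTI affine into spacing / origin / direction cosines."""
    M = np.asarray(affine, dtype=float)[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("affine encodes a zero-length voxel axis")
    direction = M / spacing
    return ImageGrid(
        shape=tuple(int(s) for s in shape),
        spacing=tuple(spacing),
        origin=tuple(np.asarray(affine, dtype=float)[:3, 3]),
        direction=direction,
    )


def _load_3d(path) -> tuple[np.ndarray, ImageGrid]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # tolerate trailing singleton dims (a common NIfTI quirk), reject true 4-D
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel 3-D image, got shape {data.shape}"
        )
    return data, grid_from_affine(data.shape, img.affine)


def read_volume(path) -> SUVVolume:
    """Read a 3-D NIfTI PET volume in SUV units.

    Non-finite voxels are rejected (their count is reported) rather than
    silently zeroed: NaNs in SUV data indicate an upstream conversion bug.
    """
    data, grid = _load_3d(path)
    data = np.asarray(data, dtype=np.float32)
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite voxel(s) in volume")
    return SUVVolume(grid, data)


def read_mask(path, threshold_nonbinary: bool = False) -> BinaryMask:
    """Read a 3-D NIfTI binary mask.

    Parameters
    ----------
    threshold_nonbinary
        When True, any value > 0.5 counts as occupied (useful for masks that
        went through interpolation). When False (default), values outside
        {0, 1} are an error.
    """
    data, grid = _load_3d(path)
    data = np.asarray(data)
    if threshold_nonbinary:
        occ = data > 0.5
    else:
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(
                f"{path}: mask contains non-binary values {uniq[:8]}; "
                "pass threshold_nonbinary=True to binarize at 0.5"
            )
        occ = data > 0
    return BinaryMask(grid, occ)


def write_volume(item, path) -> None:
    """Write a SUVVolume (float32) or BinaryMask (uint8 {0,1}) as NIfTI."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    if isinstance(item, BinaryMask):
        data = item.values.astype(np.uint8)
    elif isinstance(item, SUVVolume):
        data = item.values.astype(np.float32)
    else:
        raise TypeError(f"expected SUVVolume or BinaryMask, got {type(item).__name__}")
    img = nib.Nifti1Image(data, item.grid.affine)
    img.header.set_qform(item.grid.affine, code=1)
    img.header.set_sform(item.grid.affine, code=1)
    nib.save(img, str(path))
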