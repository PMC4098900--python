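"""Reading and writing volumes/masks as NRRD (default) or NIfTI-1.

Arrays are (z, y, x) in memory; files carry the per-axis spacing in mm.
Volumes are stored as float32 and masks as uint8 0/1 label grids. Readers
are strict: 3D only, and NIfTI files whose affine encodes a rotation or
axis flip are refused rather than silently reoriented (this package does
no world-coordinate resampling).
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .core import ImageVolume, SegMask

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]


def _is_nifti(path: str) -> bool:
    return str(path).endswith((".nii", ".nii.gz"))


def _is_nrrd(path: str) -> bool:
    return str(path).endswith((".nrrd", ".nhdr"))


def _read_nrrd(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.GetDimension()}D")
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(float(s) for s in img.GetSpacing()[::-1])
    return data, spacing


def _write_nrrd(path: str, data: np.ndarray, spacing) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    sitk.WriteImage(img, str(path), useCompression=False)


def _read_nifti(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.ndim}D")
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot))) or np.any(np.diag(rot) <= 0):
        raise ValueError(
            f"{path}: affine encodes a non-identity orientation; this package "
            "does not resample — reorient the file explicitly first"
        )
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(s) for s in np.diag(rot)[::-1])
    return np.ascontiguousarray(data.T), spacing  # stored (x, y, z) -> (z, y, x)


def _write_nifti(path: str, data: np.ndarray, spacing) -> None:
    affine = np.diag(list(spacing[::-1]) + [1.0])
    nib.save(nib.Nifti1Image(np.ascontiguousarray(data.T), affine), str(path))


def write_volume(volume: ImageVolume, path: str) -> None:
    """Write an intensity volume (float32) as NRRD or NIfTI-1."""
    data = volume.data.astype(np.float32)
    if _is_nrrd(path):
        _write_nrrd(path, data, volume.spacing)
    elif _is_nifti(path):
        _write_nifti(path, data, volume.spacing)
    else:
        raise ValueError(f"unsupported volume format: {path}")


def read_volume(path: str) -> ImageVolume:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_nrrd(path):
        data, spacing = _read_nrrd(path)
    elif _is_nifti(path):
        data, spacing = _read_nifti(path)
    else:
        raise ValueError(f"unsupported volume format: {path}")
    return ImageVolume(data.astype(np.float32), spacing)


def write_mask(mask: SegMask, path: str) -> None:
    """Write a binary mask as a uint8 0/1 label volume."""
    data = mask.data.astype(np.uint8)
    if _is_nrrd(path):
        _write_nrrd(path, data, mask.spacing)
    elif _is_nifti(path):
        _write_nifti(path, data, mask.spacing)
    else:
        raise ValueError(f"unsupported mask format: {path}")


def read_mask(path: str) -> SegMask:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_nrrd(path):
        data, spacing = _read_nrrd(path)
    elif _is_nifti(path):
        data, spacing = _read_nifti(path)
    else:
        raise ValueError(f"unsupported mask format: {path}")
    vals = np.unique(data)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError(f"{path}: mask voxels must be 0/1, found values {vals[:5]}")
    return SegMask(data.astype(bool), spacing)
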