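"""Core in-memory containers: image volumes and segmentation masks.

Arrays are indexed ``(z, y, x)`` (slice, row, column); ``spacing`` gives the
physical voxel size in millimetres per axis, in the same order. Masks are
boolean grids aligned voxel-for-voxel to their volume; no world-coordinate
resampling is performed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "SegMask", "voxel_volume"]


def voxel_volume(spacing: tuple[float, float, float]) -> float:
    """Physical volume of one voxel in mm^3."""
    return float(np.prod(spacing))


@dataclass
class ImageVolume:
    """A 3D scalar image (CT-like intensities in HU) with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume requires a 3D array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageVolume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SegMask:
    """A binary segmentation aligned to an :class:`ImageVolume` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"SegMask requires a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.n_voxels * voxel_volume(self.spacing)

    def check_aligned(self, volume: ImageVolume) -> None:
        if self.data.shape != volume.data.shape:
            raise ValueError(
                f"mask grid {self.data.shape} does not match volume grid {volume.data.shape}"
            )
        if not np.allclose(self.spacing, volume.spacing):
            raise ValueError(
                f"mask spacing {self.spacing} does not match volume spacing {volume.spacing}"
            )


def dice(a: SegMask | np.ndarray, b: SegMask | np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks."""
    a = a.data if isinstance(a, SegMask) else np.asarray(a, bool)
    b = b.data if isinstance(b, SegMask) else np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
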