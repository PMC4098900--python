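"""Assembly of the full 56-feature radiomic vector for one volume/mask pair."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import ImageVolume, SegMask
from .discretize import discretize
from .intensity import INTENSITY_FEATURE_NAMES, intensity_features
from .shape import SHAPE_FEATURE_NAMES, shape_features
from .texture import TEXTURE_FEATURE_NAMES, texture_features

__all__ = ["FEATURE_NAMES", "FEATURE_CATEGORIES", "extract_all"]

#: stable ordering of all 56 features: 15 intensity, 8 shape, 33 texture
FEATURE_NAMES: tuple[str, ...] = (
    INTENSITY_FEATURE_NAMES + SHAPE_FEATURE_NAMES + TEXTURE_FEATURE_NAMES
)

FEATURE_CATEGORIES: dict[str, str] = {
    **{n: "intensity" for n in INTENSITY_FEATURE_NAMES},
    **{n: "shape" for n in SHAPE_FEATURE_NAMES},
    **{n: "texture" for n in TEXTURE_FEATURE_NAMES},
}


def _bbox(mask: np.ndarray, pad: int = 1) -> tuple[slice, slice, slice]:
    coords = np.argwhere(mask)
    lo = np.maximum(coords.min(axis=0) - pad, 0)
    hi = np.minimum(coords.max(axis=0) + 1 + pad, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def extract_all(
    volume: ImageVolume | np.ndarray,
    mask: SegMask | np.ndarray,
    spacing: tuple[float, float, float] | None = None,
    bin_width: float = 25.0,
    distance: int = 1,
    surface_mode: str = "mesh",
) -> pd.Series:
    """Extract all 56 radiomic features as a named, ordered Series.

    ``volume``/``mask`` may be the package containers (which carry their
    spacing) or bare arrays plus an explicit ``spacing``. Undefined features
    (degenerate masks or matrices) are NaN, never silently dropped or
    zero-filled.
    """
    if isinstance(volume, ImageVolume):
        if spacing is None:
            spacing = volume.spacing
        volume = volume.data
    if isinstance(mask, SegMask):
        if spacing is None:
            spacing = mask.spacing
        mask = mask.data
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    if not mask.any():
        raise ValueError("extract_all: empty mask")

    # features are invariant to whole-voxel translation, so work on the
    # mask bounding box
    box = _bbox(mask)
    vol_c = volume[box]
    mask_c = mask[box]

    values: dict[str, float] = {}
    values.update(intensity_features(vol_c, mask_c, bin_width=bin_width))
    values.update(shape_features(mask_c, spacing, surface_mode=surface_mode))
    disc = discretize(vol_c, mask_c, bin_width=bin_width)
    values.update(texture_features(disc, distance=distance))
    return pd.Series([values[n] for n in FEATURE_NAMES], index=list(FEATURE_NAMES), dtype=float)
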