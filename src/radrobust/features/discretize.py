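"""Fixed-bin-width intensity discretization of the voxels inside a mask.

Texture matrices (and the histogram-based first-order features) operate on
gray *levels*, not raw HU values. Level assignment uses a fixed bin width
anchored at the in-mask minimum:

    level(v) = 1 + floor((I(v) - min_in_mask) / bin_width)

so level 1 always exists and L is the highest occupied level. A fixed width
(default 25 HU) keeps a level difference physically comparable across
tumors, which is what makes pooled texture comparisons meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedVolume", "discretize"]


@dataclass
class DiscretizedVolume:
    """Integer gray levels (1..L) on the mask voxels; 0 outside the mask."""

    levels: np.ndarray  # int grid, 0 outside mask
    mask: np.ndarray  # bool grid
    bin_width: float
    n_levels: int  # L
    min_intensity: float  # in-mask minimum used as the bin origin


def discretize(volume: np.ndarray, mask: np.ndarray, bin_width: float = 25.0) -> DiscretizedVolume:
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    if not mask.any():
        raise ValueError("discretize: empty mask")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    vals = volume[mask]
    vmin = float(vals.min())
    lev = np.zeros(volume.shape, dtype=np.int64)
    lev[mask] = 1 + np.floor((vals - vmin) / bin_width).astype(np.int64)
    return DiscretizedVolume(
        levels=lev,
        mask=mask,
        bin_width=float(bin_width),
        n_levels=int(lev[mask].max()),
        min_intensity=vmin,
    )
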