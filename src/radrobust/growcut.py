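"""GrowCut: competitive region-growing segmentation by cellular automaton.

Each voxel carries a class label and a strength in [0, 1]. Seeded voxels
start with strength 1; at every synchronous iteration a neighbour ``q``
attacks voxel ``p`` and conquers it iff

    g(|C_p - C_q|) * theta_q  >  theta_p,      g(x) = 1 - x / max_diff,

where ``C`` is image intensity, ``theta`` the strength, and ``max_diff`` the
intensity range over the region of interest (fixed before iterating). On
conquest ``p`` adopts ``q``'s label with strength ``g * theta_q``. The
automaton runs only inside a region of interest (ROI) built as the convex
hull of the seeded voxels plus a margin; it stops when a full sweep changes
no label. Strengths are non-decreasing, so termination is guaranteed for
finite grids (an iteration cap guards degenerate cases).

Updates are synchronous (all voxels read the previous state) and neighbour
offsets are visited in a fixed order, so results are fully deterministic.
Seeded voxels never change class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .core import ImageVolume, SegMask

__all__ = ["GrowCutResult", "build_roi", "segment", "postprocess", "neighbor_offsets"]


def neighbor_offsets(connectivity: int = 26) -> np.ndarray:
    """Neighbour displacement vectors, in a fixed deterministic order.

    ``connectivity=26`` gives all 26 face/edge/corner neighbours;
    ``connectivity=6`` the 6 face neighbours.
    """
    if connectivity not in (6, 26):
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    offs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    if connectivity == 6:
        offs = [o for o in offs if sum(abs(c) for c in o) == 1]
    return np.array(offs, dtype=int)


@dataclass
class GrowCutResult:
    """Final automaton state: class map, strengths, ROI and convergence info."""

    labels: np.ndarray
    strength: np.ndarray
    roi: np.ndarray
    iterations: int
    converged: bool


def build_roi(seeds: np.ndarray, margin_voxels: int = 2) -> np.ndarray:
    """Discrete convex hull of all labeled voxels, dilated by a margin.

    The hull is taken over the 8 cube corners of every labeled voxel (not
    just the centers), so degenerate seed sets — a single voxel, a straight
    stroke — still span a full-rank hull. The margin dilation uses the
    Chebyshev (26-connected) ball, clipped to the grid.
    """
    seeds = np.asarray(seeds)
    labeled = seeds > 0
    if not labeled.any():
        raise ValueError("build_roi: seeds contain no labeled voxel")
    if margin_voxels < 0:
        raise ValueError("margin_voxels must be >= 0")

    # only boundary voxels of the seed set can be hull vertices
    boundary = labeled & ~ndimage.binary_erosion(labeled)
    coords = np.argwhere(boundary)
    lo = np.argwhere(labeled).min(axis=0)
    hi = np.argwhere(labeled).max(axis=0)
    roi = np.zeros(seeds.shape, dtype=bool)
    if np.all(lo == hi):
        roi[tuple(lo)] = True
    else:
        # cube corners of each voxel: center +/- 0.5 per axis (full rank
        # even for a single voxel or a straight stroke)
        shifts = np.array(
            [(a, b, c) for a in (-0.5, 0.5) for b in (-0.5, 0.5) for c in (-0.5, 0.5)]
        )
        corners = (coords[:, None, :] + shifts[None, :, :]).reshape(-1, 3)
        eqs = ConvexHull(corners).equations
        zz, yy, xx = np.mgrid[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1]
        pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()]).astype(float)
        inside = (pts @ eqs[:, :3].T + eqs[:, 3] <= 1e-9).all(axis=1)
        roi[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1] = inside.reshape(
            hi[0] - lo[0] + 1, hi[1] - lo[1] + 1, hi[2] - lo[2] + 1
        )
    if margin_voxels > 0:
        roi = ndimage.binary_dilation(
            roi, structure=np.ones((3, 3, 3), bool), iterations=margin_voxels
        )
    return roi


def _bbox_slices(mask: np.ndarray, pad: int = 0) -> tuple[slice, slice, slice]:
    coords = np.argwhere(mask)
    lo = np.maximum(coords.min(axis=0) - pad, 0)
    hi = np.minimum(coords.max(axis=0) + 1 + pad, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def segment(
    volume: ImageVolume | np.ndarray,
    seeds: np.ndarray,
    margin_voxels: int = 2,
    max_iters: int = 500,
    connectivity: int = 26,
) -> GrowCutResult:
    """Run the GrowCut automaton to convergence (or the iteration cap).

    Parameters
    ----------
    volume
        Scalar intensity grid (finite values).
    seeds
        Integer label grid: 0 = unlabeled, 1..N = classes. At least one
        voxel per class present in ``seeds`` is required for N-class
        segmentation.
    margin_voxels
        ROI margin added around the convex hull of the seeds.
    max_iters
        Iteration cap; if reached without a change-free sweep the result is
        returned with ``converged=False``.
    """
    intens = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    seeds = np.asarray(seeds)
    if intens.shape != seeds.shape:
        raise ValueError(f"volume grid {intens.shape} != seeds grid {seeds.shape}")
    if not np.all(np.isfinite(intens)):
        raise ValueError("volume intensities must be finite")
    present = np.unique(seeds[seeds > 0])
    if present.size == 0:
        raise ValueError("seeds contain no labeled voxel")
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")

    roi_full = build_roi(seeds, margin_voxels)
    box = _bbox_slices(roi_full)
    roi = roi_full[box]
    C = intens[box].astype(np.float64)
    labels = seeds[box].astype(np.int32).copy()
    seeded = labels > 0
    strength = np.zeros_like(C)
    strength[seeded] = 1.0

    vals = C[roi]
    max_diff = float(vals.max() - vals.min()) if vals.size else 0.0
    offsets = neighbor_offsets(connectivity)

    # padded state arrays: border has strength 0, so it never attacks
    def pad(a, fill=0):
        return np.pad(a, 1, mode="constant", constant_values=fill)

    updatable = roi & ~seeded
    sz, sy, sx = C.shape
    views = [
        (slice(1 + dz, 1 + dz + sz), slice(1 + dy, 1 + dy + sy), slice(1 + dx, 1 + dx + sx))
        for dz, dy, dx in offsets
    ]
    # similarity weights are fixed by the image: precompute g per offset
    Cp = pad(C)
    if max_diff > 0:
        g_per_offset = [1.0 - np.abs(C - Cp[v]) / max_diff for v in views]
    else:
        g_per_offset = [np.ones_like(C) for _ in views]

    iterations = 0
    converged = False
    for iterations in range(1, max_iters + 1):
        Lp = pad(labels)
        Sp = pad(strength)
        best_val = np.zeros_like(C)
        best_lab = np.zeros_like(labels)
        for v, g in zip(views, g_per_offset):
            val = g * Sp[v]
            better = val > best_val  # strict: earlier offsets win ties
            best_val[better] = val[better]
            best_lab[better] = Lp[v][better]
        conquer = updatable & (best_val > strength) & (best_lab > 0)
        # conquer with a strictly greater strength: includes same-label
        # reinforcement, which propagates strength without a label change
        n_updates = int(np.count_nonzero(conquer))
        labels[conquer] = best_lab[conquer]
        strength[conquer] = best_val[conquer]
        # stop only when the whole state is a fixed point, so a converged
        # result is idempotent under one further sweep; strengths are
        # monotone and drawn from the finite set of seed-path products, so
        # this terminates
        if n_updates == 0:
            converged = True
            break

    out_labels = np.zeros(seeds.shape, dtype=np.int32)
    out_labels[box] = labels
    out_strength = np.zeros(seeds.shape, dtype=np.float64)
    out_strength[box] = strength
    return GrowCutResult(
        labels=out_labels,
        strength=out_strength,
        roi=roi_full,
        iterations=iterations,
        converged=converged,
    )


def postprocess(
    labels: np.ndarray,
    foreground_class: int = 1,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    connectivity: int = 26,
) -> SegMask:
    """Island removal: keep the largest connected foreground component.

    Components are 26-connected by default. If two components tie in size,
    the one whose first voxel occurs earliest in scan (linear-index) order
    is kept, which is deterministic.
    """
    fg = np.asarray(labels) == foreground_class
    if not fg.any():
        raise ValueError("postprocess: no foreground voxels to keep")
    structure = np.ones((3, 3, 3), bool) if connectivity == 26 else None
    comp, n = ndimage.label(fg, structure=structure)
    if n == 1:
        return SegMask(fg, spacing)
    sizes = ndimage.sum_labels(fg, comp, index=np.arange(1, n + 1))
    # ndimage.label assigns ids in scan order, so the lowest id among the
    # maximal sizes is the component encountered first
    keep = int(np.argmax(sizes)) + 1
    return SegMask(comp == keep, spacing)
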