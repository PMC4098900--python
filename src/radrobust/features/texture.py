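"""Texture features from gray-level co-occurrence and run-length matrices.

Both matrix families are built per direction over the 13 symmetric
displacement vectors of the 3D 26-neighborhood (each vector taken together
with its negation covers all 26 neighbors), at an inter-voxel distance of
one. Every matrix feature is computed per direction and then averaged
arithmetically over the 13 directions; directions on which a feature is
undefined (degenerate matrix, zero marginal variance, ...) are skipped, and
a feature undefined on all directions is reported as NaN.

GLCM entries are symmetric pair probabilities: the pair (p, p + d) is
counted in both orders and the matrix normalized to sum 1. GLRLM entry
(g, r) counts maximal runs of gray level g and length r along the
direction; runs are broken at the mask boundary. 22 GLCM features and 11
GLRLM features give the 33 texture features.

Logarithms are base 2 (entropies in bits) with 0 log 0 = 0.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedVolume

__all__ = [
    "DIRECTIONS_3D",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "TEXTURE_FEATURE_NAMES",
    "glc_matrix",
    "glcm_features",
    "glrl_matrix",
    "glrlm_features",
    "texture_features",
]


def _direction_set() -> np.ndarray:
    """The 13 symmetric 26-neighborhood directions (first nonzero component > 0)."""
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                d = (dz, dy, dx)
                if d == (0, 0, 0):
                    continue
                first = next(c for c in d if c != 0)
                if first > 0:
                    out.append(d)
    return np.array(out, dtype=int)


DIRECTIONS_3D: np.ndarray = _direction_set()

GLCM_FEATURE_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_entropy",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity_1",
    "homogeneity_2",
    "imc_1",
    "imc_2",
    "idmn",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "variance",
)

GLRLM_FEATURE_NAMES: tuple[str, ...] = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)

TEXTURE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"glcm_{n}" for n in GLCM_FEATURE_NAMES
) + tuple(f"glrlm_{n}" for n in GLRLM_FEATURE_NAMES)


def _offset_slices(shape, offset):
    """Slices (src, dst) so that arr[dst] = arr[src + offset], both in-grid."""
    src, dst = [], []
    for size, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, size - o))
            dst.append(slice(o, size))
        else:
            src.append(slice(-o, size))
            dst.append(slice(0, size + o))
    return tuple(src), tuple(dst)


def glc_matrix(
    disc: DiscretizedVolume, direction: np.ndarray, distance: int = 1
) -> np.ndarray | None:
    """Symmetric, normalized L x L co-occurrence matrix for one direction.

    Returns None when the direction yields no valid in-mask pair.
    """
    direction = np.asarray(direction, dtype=int)
    offset = direction * distance
    L = disc.n_levels
    src, dst = _offset_slices(disc.levels.shape, offset)
    a = disc.levels[src]
    b = disc.levels[dst]
    valid = disc.mask[src] & disc.mask[dst]
    if not valid.any():
        return None
    ai = a[valid] - 1
    bi = b[valid] - 1
    counts = np.zeros((L, L), dtype=np.float64)
    np.add.at(counts, (ai, bi), 1.0)
    counts = counts + counts.T  # count each pair in both orders
    return counts / counts.sum()


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(P: np.ndarray | None) -> dict[str, float]:
    """The 22 co-occurrence features of a normalized GLCM."""
    nan = float("nan")
    if P is None or P.size == 0 or P.sum() == 0:
        return {name: nan for name in GLCM_FEATURE_NAMES}
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    i = np.arange(1, L + 1)
    I, J = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # diagonal (i+j) and cross-diagonal (|i-j|) marginal distributions
    ksum = np.arange(2, 2 * L + 1)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (I + J).ravel() - 2, P.ravel())
    kdiff = np.arange(0, L)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(I - J).ravel(), P.ravel())

    HXY = _entropy2(P.ravel())
    HX = _entropy2(px)
    HY = _entropy2(py)
    pxpy = np.outer(px, py)
    pos = pxpy > 0
    HXY1 = float(-(P[pos] * np.log2(pxpy[pos])).sum())
    HXY2 = float(-(pxpy[pos] * np.log2(pxpy[pos])).sum())

    if sd_x > 0 and sd_y > 0:
        correlation = float(((I * J * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = nan
    hmax = max(HX, HY)
    imc1 = (HXY - HXY1) / hmax if hmax > 0 else nan
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))

    offdiag = I != J
    sum_average = float((ksum * p_sum).sum())
    cdev = I + J - mu_x - mu_y
    return {
        "autocorrelation": float((I * J * P).sum()),
        "cluster_prominence": float((cdev**4 * P).sum()),
        "cluster_shade": float((cdev**3 * P).sum()),
        "cluster_tendency": float((cdev**2 * P).sum()),
        "contrast": float(((I - J) ** 2 * P).sum()),
        "correlation": correlation,
        "difference_entropy": _entropy2(p_diff),
        "dissimilarity": float((np.abs(I - J) * P).sum()),
        "energy": float((P**2).sum()),
        "entropy": HXY,
        "homogeneity_1": float((P / (1.0 + np.abs(I - J))).sum()),
        "homogeneity_2": float((P / (1.0 + (I - J) ** 2)).sum()),
        "imc_1": imc1,
        "imc_2": imc2,
        "idmn": float((P / (1.0 + ((I - J) / L) ** 2)).sum()),
        "idn": float((P / (1.0 + np.abs(I - J) / L)).sum()),
        "inverse_variance": float((P[offdiag] / (I - J)[offdiag] ** 2).sum()),
        "maximum_probability": float(P.max()),
        "sum_average": sum_average,
        "sum_entropy": _entropy2(p_sum),
        "sum_variance": float(((ksum - sum_average) ** 2 * p_sum).sum()),
        "variance": float(((I - mu_x) ** 2 * P).sum()),
    }


def glrl_matrix(disc: DiscretizedVolume, direction: np.ndarray) -> np.ndarray | None:
    """L x Rmax run-length matrix for one direction.

    Entry (g-1, r-1) counts maximal runs of level g with length r; runs are
    broken wherever the line leaves the mask. Returns None for an empty
    mask.
    """
    direction = np.asarray(direction, dtype=int)
    levels = np.where(disc.mask, disc.levels, 0)
    shape = np.array(levels.shape)
    if not disc.mask.any():
        return None

    # start voxels: p - d falls outside the grid
    idx = np.indices(levels.shape).reshape(3, -1).T
    prev = idx - direction
    starts = idx[((prev < 0) | (prev >= shape)).any(axis=1)]
    # maximal number of steps along the direction from any start
    steps = int(
        min(
            (shape[k] if direction[k] != 0 else np.inf)
            for k in range(3)
        )
    )
    # lines as a (n_starts, steps) level array, 0-padded where out of grid
    ks = np.arange(steps)
    pos = starts[:, None, :] + ks[None, :, None] * direction  # (n, steps, 3)
    valid = ((pos >= 0) & (pos < shape)).all(axis=2)
    pos_clipped = np.clip(pos, 0, shape - 1)
    line_vals = levels[pos_clipped[..., 0], pos_clipped[..., 1], pos_clipped[..., 2]]
    line_vals = np.where(valid, line_vals, 0)

    # run-length encode all lines at once: separate them with a 0 column
    flat = np.concatenate(
        [line_vals, np.zeros((line_vals.shape[0], 1), dtype=line_vals.dtype)], axis=1
    ).ravel()
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    run_vals = flat[bounds[:-1]]
    run_lens = np.diff(bounds)
    keep = run_vals > 0
    run_vals = run_vals[keep]
    run_lens = run_lens[keep]
    if run_vals.size == 0:
        return None
    L = disc.n_levels
    Rmax = int(run_lens.max())
    R = np.zeros((L, Rmax), dtype=np.float64)
    np.add.at(R, (run_vals - 1, run_lens - 1), 1.0)
    return R


def glrlm_features(R: np.ndarray | None, n_voxels: int) -> dict[str, float]:
    """The 11 run-length features; ``n_voxels`` is the in-mask voxel count."""
    nan = float("nan")
    if R is None or R.size == 0 or R.sum() == 0:
        return {name: nan for name in GLRLM_FEATURE_NAMES}
    R = np.asarray(R, dtype=float)
    L, Rmax = R.shape
    g = np.arange(1, L + 1)[:, None].astype(float)
    r = np.arange(1, Rmax + 1)[None, :].astype(float)
    n_runs = R.sum()
    return {
        "short_run_emphasis": float((R / r**2).sum() / n_runs),
        "long_run_emphasis": float((R * r**2).sum() / n_runs),
        "gray_level_nonuniformity": float((R.sum(axis=1) ** 2).sum() / n_runs),
        "run_length_nonuniformity": float((R.sum(axis=0) ** 2).sum() / n_runs),
        "run_percentage": float(n_runs / n_voxels),
        "low_gray_level_run_emphasis": float((R / g**2).sum() / n_runs),
        "high_gray_level_run_emphasis": float((R * g**2).sum() / n_runs),
        "short_run_low_gray_level_emphasis": float((R / (g**2 * r**2)).sum() / n_runs),
        "short_run_high_gray_level_emphasis": float((R * g**2 / r**2).sum() / n_runs),
        "long_run_low_gray_level_emphasis": float((R * r**2 / g**2).sum() / n_runs),
        "long_run_high_gray_level_emphasis": float((R * g**2 * r**2).sum() / n_runs),
    }


def texture_features(disc: DiscretizedVolume, distance: int = 1) -> dict[str, float]:
    """All 33 texture features, averaged over the 13 symmetric directions.

    A feature's average skips directions on which it is undefined; if it is
    undefined on every direction the average itself is NaN.
    """
    n_voxels = int(disc.mask.sum())
    per_dir: dict[str, list[float]] = {name: [] for name in TEXTURE_FEATURE_NAMES}
    for direction in DIRECTIONS_3D:
        glcm = glc_matrix(disc, direction, distance=distance)
        for name, val in glcm_features(glcm).items():
            per_dir[f"glcm_{name}"].append(val)
        glrlm = glrl_matrix(disc, direction)
        for name, val in glrlm_features(glrlm, n_voxels).items():
            per_dir[f"glrlm_{name}"].append(val)
    out = {}
    for name, vals in per_dir.items():
        arr = np.asarray(vals, dtype=float)
        defined = arr[np.isfinite(arr)]
        out[name] = float(defined.mean()) if defined.size else float("nan")
    return out
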