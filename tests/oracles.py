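"""Independent brute-force oracles used by the test suite.

Everything here is written as naive explicit loops (or textbook linear
programming / breadth-first search), deliberately sharing no code with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# convex hull membership (for ROI checks)


def point_in_hull(point, hull_points, tol=1e-9) -> bool:
    """Is ``point`` a convex combination of ``hull_points``? (LP feasibility)"""
    pts = np.asarray(hull_points, dtype=float)
    m = len(pts)
    # minimize 0 s.t. sum_i w_i p_i = point, sum w = 1, w >= 0
    a_eq = np.vstack([pts.T, np.ones(m)])
    b_eq = np.concatenate([np.asarray(point, float), [1.0]])
    res = linprog(np.zeros(m), A_eq=a_eq, b_eq=b_eq, bounds=[(0, None)] * m,
                  method="highs")
    return bool(res.status == 0 and res.success)


def voxel_cube_corners(coords):
    """All cube-corner points (center +/- 0.5) of the given voxel coords."""
    out = []
    for c in coords:
        for dz, dy, dx in itertools.product((-0.5, 0.5), repeat=3):
            out.append((c[0] + dz, c[1] + dy, c[2] + dx))
    return np.array(out)


# ---------------------------------------------------------------------------
# texture matrices


def glcm_brute(levels, mask, direction, distance=1):
    """Co-occurrence counts by triple loop; normalized, symmetric."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    L = int(levels[mask].max())
    M = np.zeros((L, L))
    dz, dy, dx = (int(c) * distance for c in direction)
    nz, ny, nx = levels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                z2, y2, x2 = z + dz, y + dy, x + dx
                if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx and mask[z2, y2, x2]:
                    a = levels[z, y, x] - 1
                    b = levels[z2, y2, x2] - 1
                    M[a, b] += 1
                    M[b, a] += 1
    if M.sum() == 0:
        return None
    return M / M.sum()


def glcm_features_brute(P):
    """The 22 co-occurrence features evaluated by explicit loops."""
    L = P.shape[0]
    nan = float("nan")

    def rng():
        return range(1, L + 1)

    px = [sum(P[i - 1, j - 1] for j in rng()) for i in rng()]
    py = [sum(P[i - 1, j - 1] for i in rng()) for j in rng()]
    mu_x = sum(i * px[i - 1] for i in rng())
    mu_y = sum(j * py[j - 1] for j in rng())
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i - 1] for i in rng()))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j - 1] for j in rng()))

    p_sum = {k: 0.0 for k in range(2, 2 * L + 1)}
    p_diff = {k: 0.0 for k in range(0, L)}
    for i in rng():
        for j in rng():
            p_sum[i + j] += P[i - 1, j - 1]
            p_diff[abs(i - j)] += P[i - 1, j - 1]

    def ent(values):
        return -sum(v * math.log2(v) for v in values if v > 0)

    hxy = ent(P.ravel())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        P[i - 1, j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in rng() for j in rng() if px[i - 1] * py[j - 1] > 0
    )
    hxy2 = -sum(
        px[i - 1] * py[j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in rng() for j in rng() if px[i - 1] * py[j - 1] > 0
    )
    sa = sum(k * v for k, v in p_sum.items())

    f = {}
    f["autocorrelation"] = sum(i * j * P[i - 1, j - 1] for i in rng() for j in rng())
    for power, name in [(4, "cluster_prominence"), (3, "cluster_shade"),
                        (2, "cluster_tendency")]:
        f[name] = sum((i + j - mu_x - mu_y) ** power * P[i - 1, j - 1]
                      for i in rng() for j in rng())
    f["contrast"] = sum((i - j) ** 2 * P[i - 1, j - 1] for i in rng() for j in rng())
    if sd_x > 0 and sd_y > 0:
        f["correlation"] = (f["autocorrelation"] - mu_x * mu_y) / (sd_x * sd_y)
    else:
        f["correlation"] = nan
    f["difference_entropy"] = ent(p_diff.values())
    f["dissimilarity"] = sum(abs(i - j) * P[i - 1, j - 1] for i in rng() for j in rng())
    f["energy"] = sum(P[i - 1, j - 1] ** 2 for i in rng() for j in rng())
    f["entropy"] = hxy
    f["homogeneity_1"] = sum(P[i - 1, j - 1] / (1 + abs(i - j))
                             for i in rng() for j in rng())
    f["homogeneity_2"] = sum(P[i - 1, j - 1] / (1 + (i - j) ** 2)
                             for i in rng() for j in rng())
    f["imc_1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else nan
    f["imc_2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["idmn"] = sum(P[i - 1, j - 1] / (1 + ((i - j) / L) ** 2)
                    for i in rng() for j in rng())
    f["idn"] = sum(P[i - 1, j - 1] / (1 + abs(i - j) / L)
                   for i in rng() for j in rng())
    f["inverse_variance"] = sum(P[i - 1, j - 1] / (i - j) ** 2
                                for i in rng() for j in rng() if i != j)
    f["maximum_probability"] = max(P[i - 1, j - 1] for i in rng() for j in rng())
    f["sum_average"] = sa
    f["sum_entropy"] = ent(p_sum.values())
    f["sum_variance"] = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    f["variance"] = sum((i - mu_x) ** 2 * P[i - 1, j - 1] for i in rng() for j in rng())
    return f


def glrlm_brute(levels, mask, direction):
    """Run-length counts by walking every line voxel-by-voxel."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    shape = levels.shape
    d = tuple(int(c) for c in direction)
    L = int(levels[mask].max())

    def in_grid(p):
        return all(0 <= p[k] < shape[k] for k in range(3))

    starts = [
        p for p in itertools.product(*(range(s) for s in shape))
        if not in_grid(tuple(p[k] - d[k] for k in range(3)))
    ]
    runs = []
    for start in starts:
        p = start
        current_level, current_len = 0, 0
        while in_grid(p):
            lev = levels[p] if mask[p] else 0
            if lev == current_level:
                current_len += 1
            else:
                if current_level > 0:
                    runs.append((current_level, current_len))
                current_level, current_len = lev, 1
            p = tuple(p[k] + d[k] for k in range(3))
        if current_level > 0:
            runs.append((current_level, current_len))
    if not runs:
        return None
    rmax = max(r for _, r in runs)
    M = np.zeros((L, rmax))
    for g, r in runs:
        M[g - 1, r - 1] += 1
    return M


def glrlm_features_brute(R, n_voxels):
    """The 11 run-length features evaluated by explicit loops."""
    L, rmax = R.shape
    n_runs = R.sum()
    f = {k: 0.0 for k in (
        "short_run_emphasis", "long_run_emphasis",
        "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
        "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
        "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
    )}
    for g in range(1, L + 1):
        for r in range(1, rmax + 1):
            c = R[g - 1, r - 1]
            f["short_run_emphasis"] += c / r**2
            f["long_run_emphasis"] += c * r**2
            f["low_gray_level_run_emphasis"] += c / g**2
            f["high_gray_level_run_emphasis"] += c * g**2
            f["short_run_low_gray_level_emphasis"] += c / (g**2 * r**2)
            f["short_run_high_gray_level_emphasis"] += c * g**2 / r**2
            f["long_run_low_gray_level_emphasis"] += c * r**2 / g**2
            f["long_run_high_gray_level_emphasis"] += c * g**2 * r**2
    f = {k: v / n_runs for k, v in f.items()}
    f["gray_level_nonuniformity"] = sum(
        sum(R[g - 1, r - 1] for r in range(1, rmax + 1)) ** 2 for g in range(1, L + 1)
    ) / n_runs
    f["run_length_nonuniformity"] = sum(
        sum(R[g - 1, r - 1] for g in range(1, L + 1)) ** 2 for r in range(1, rmax + 1)
    ) / n_runs
    f["run_percentage"] = n_runs / n_voxels
    return f


# ---------------------------------------------------------------------------
# ICC by explicit sum-of-squares loops


def icc_brute(ratings, model):
    """ICC from explicit sum-of-squares loops ('twoway_absolute' or 'oneway')."""
    y = np.asarray(ratings, dtype=float)
    n, k = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(y[i, j] for j in range(k)) / k for i in range(n)]
    if model == "oneway":
        msr = k * sum((r - grand) ** 2 for r in row) / (n - 1)
        msw = sum((y[i, j] - row[i]) ** 2 for i in range(n) for j in range(k)) / (
            n * (k - 1))
        return (msr - msw) / (msr + (k - 1) * msw)
    col = [sum(y[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


# ---------------------------------------------------------------------------
# rank-sum p by Monte-Carlo permutation


def ranksum_p_montecarlo(x, y, n_perm=100_000, seed=0):
    """Two-sided rank-sum p-value by random permutation of group labels."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    combined = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(combined)) + 1.0
    nx = len(x)
    obs = ranks[:nx].sum()
    rng = np.random.default_rng(seed)
    stats = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(ranks)
        stats[i] = perm[:nx].sum()
    p_low = (stats <= obs).mean()
    p_high = (stats >= obs).mean()
    return min(1.0, 2.0 * min(p_low, p_high))
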