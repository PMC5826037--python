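"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the k-means oracle is
an exact dynamic program over all split points of the sorted values, the
thickness oracle enumerates every candidate sphere and tests coverage
directly, and the median oracle sorts each neighborhood.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def wcss(values, centers) -> float:
    """Within-cluster sum of squares for a 1D clustering by nearest center."""
    d = np.abs(np.asarray(values, float)[:, None] - np.asarray(centers)[None, :])
    return float((d.min(axis=1) ** 2).sum())


def dp_kmeans_wcss(values, n_classes: int) -> float:
    """Globally optimal 1D k-means WCSS via dynamic programming.

    Optimal clusters of sorted 1D data are contiguous runs, so the optimum
    is a DP over all split points with O(C n^2) prefix-sum cost queries.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    p1 = np.concatenate([[0.0], np.cumsum(x)])
    p2 = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        s = p1[None, :] - p1[:, None]
        cost = p2[None, :] - p2[:, None] - s * s / np.maximum(j - i, 1)
    cost[i >= j] = np.inf  # only runs x[i:j] with i < j are clusters

    dp = np.full(n + 1, np.inf)
    dp[0] = 0.0
    for _ in range(n_classes):
        dp = np.min(dp[:, None] + cost, axis=0)
    return float(dp[n])


def mixture_instance(seed: int, max_n: int = 500):
    """A three-component Gaussian mixture (balanced weights, well separated)
    as used for the k-means-versus-DP comparison."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(60, max_n))
    means = np.array([1000.0, 5000.0, 9000.0])
    comp = rng.integers(0, 3, size=n)
    return rng.normal(means[comp], 500.0)


def brute_force_thickness(mask: np.ndarray) -> np.ndarray:
    """Exhaustive sphere-fitting local thickness.

    Candidate spheres sit at every foreground voxel center with radius equal
    to the distance to the nearest background voxel center (volume border
    counts as background) minus half a voxel; every sphere/voxel coverage
    pair is tested directly.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    bg = np.argwhere(~padded) - 1.0
    fg = np.argwhere(mask).astype(float)
    r = np.sqrt(((fg[:, None, :] - bg[None, :, :]) ** 2).sum(2)).min(1) - 0.5
    d2 = ((fg[:, None, :] - fg[None, :, :]) ** 2).sum(2)
    covered = d2 <= (r[None, :] ** 2) + 1e-9
    th = np.where(covered, 2.0 * r[None, :], 0.0).max(1)
    out = np.zeros(mask.shape)
    out[mask] = th
    return out


def random_blob_mask(seed: int, shape=(12, 12, 12)) -> np.ndarray:
    """Random smooth binary blob (non-empty) for thickness stress tests."""
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.normal(size=shape), 1.8)
    mask = field > np.quantile(field, 0.7)
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return mask


def brute_force_median(data: np.ndarray, kernel: int) -> np.ndarray:
    """Median filter by explicit neighborhood sort with edge replication."""
    h = kernel // 2
    padded = np.pad(data, h, mode="edge")
    out = np.empty_like(data)
    for idx in np.ndindex(data.shape):
        block = padded[tuple(slice(i, i + kernel) for i in idx)]
        out[idx] = np.median(block)
    return out


def fcm_membership(x: float, centers, m: float = 2.0) -> np.ndarray:
    """Direct evaluation of the fuzzy c-means membership formula for a
    single point (no shared code with the package)."""
    centers = np.asarray(centers, dtype=float)
    d = np.abs(x - centers)
    if (d == 0).any():
        u = (d == 0).astype(float)
        return u / u.sum()
    inv = d ** (-2.0 / (m - 1.0))
    return inv / inv.sum()
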