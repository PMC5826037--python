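"""1D K-means initialization and fuzzy c-means on voxel intensities.

The feature space is the scalar voxel intensity, so both algorithms run on
the *value histogram* (unique values with counts) rather than per voxel: the
membership of a voxel depends only on its intensity, and every center update
is a weighted mean, so the histogram formulation is exact and turns a
multi-million-voxel update into one over at most 65536 bins for 16-bit data.

Fuzzy c-means minimises

    J(U, v) = sum_{c,k} u_{ck}^m (x_k - v_c)^2,   sum_c u_{ck} = 1,

by alternating the closed-form updates

    u_{ck} = [ sum_j (|x_k - v_c| / |x_k - v_j|)^{2/(m-1)} ]^{-1}
    v_c    = sum_k u_{ck}^m x_k / sum_k u_{ck}^m .

When a point coincides with one or more centers its unit membership is split
equally among the coinciding centers.  The objective is non-increasing across
iterations; convergence is declared when the largest center move, relative to
the intensity range of the data, drops below ``tol``.

Nothing here uses a random number generator: K-means is seeded at fixed
quantiles, so identical inputs give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CenterCollapseError, DegenerateInputError, ParameterError

__all__ = ["kmeans_init", "fcm", "FCMResult"]

_COLLAPSE_RTOL = 1e-9


def _as_weighted_values(x, weights):
    x = np.asarray(x, dtype=np.float64).ravel()
    if weights is None:
        weights = np.ones_like(x)
    else:
        weights = np.asarray(weights, dtype=np.float64).ravel()
        if weights.shape != x.shape:
            raise ParameterError("weights must match intensities in length")
    return x, weights


def _compress(x, w):
    """Collapse (values, weights) onto unique values with summed weights."""
    values, inverse = np.unique(x, return_inverse=True)
    counts = np.bincount(inverse, weights=w, minlength=values.size)
    return values, counts, inverse


def kmeans_init(intensities, n_classes: int, max_iter: int = 300,
                weights=None) -> np.ndarray:
    """Lloyd's algorithm on the 1D intensity distribution.

    Deterministic: centers are seeded at the ``(i + 0.5) / C`` quantiles of
    the data (falling back to quantiles of the distinct values if heavy ties
    make data quantiles coincide) and iterated to assignment stability.

    Returns the ascending class centers.
    """
    if n_classes < 1:
        raise ParameterError(f"n_classes must be >= 1, got {n_classes}")
    x, w = _as_weighted_values(intensities, weights)
    if x.size == 0:
        raise DegenerateInputError("no intensities to cluster")
    values, counts, _ = _compress(x, w)
    if values.size < n_classes:
        raise DegenerateInputError(
            f"{values.size} distinct intensity value(s) cannot support "
            f"{n_classes} classes"
        )
    if n_classes == 1:
        return np.array([np.average(values, weights=counts)])

    q = (np.arange(n_classes) + 0.5) / n_classes
    centers = _weighted_quantile(values, counts, q)
    if np.unique(centers).size < n_classes:
        centers = np.quantile(values, q)  # quantiles of the distinct values
    centers = np.sort(centers)

    assign = None
    for _ in range(max_iter):
        # nearest-center assignment via midpoint boundaries (centers sorted)
        boundaries = 0.5 * (centers[:-1] + centers[1:])
        new_assign = np.searchsorted(boundaries, values, side="right")
        mass = np.bincount(new_assign, weights=counts, minlength=n_classes)
        if (mass == 0).any():
            # deterministic re-seed: move each empty center to the distinct
            # value farthest from every non-empty center (lowest value wins
            # ties), then continue
            for c in np.flatnonzero(mass == 0):
                d = np.abs(values[:, None] - centers[None, :]).min(axis=1)
                centers[c] = values[np.argmax(d)]
            centers = np.sort(centers)
            continue
        sums = np.bincount(new_assign, weights=counts * values, minlength=n_classes)
        centers = np.sort(sums / mass)
        if assign is not None and np.array_equal(assign, new_assign):
            break
        assign = new_assign
    return centers


def _weighted_quantile(values, counts, q):
    cum = np.cumsum(counts)
    total = cum[-1]
    idx = np.searchsorted(cum, np.asarray(q) * total, side="left")
    return values[np.clip(idx, 0, values.size - 1)]


@dataclass
class FCMResult:
    """Converged fuzzy c-means state."""

    memberships: np.ndarray      #: (n_points, C), rows sum to 1
    centers: np.ndarray          #: ascending class centers
    n_iter: int
    objective: list = field(default_factory=list)  #: J after each iteration


def _membership_matrix(values: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d = np.abs(values[:, None] - centers[None, :])
    coincide = d == 0.0
    with np.errstate(divide="ignore", over="ignore"):
        w = d ** (-2.0 / (m - 1.0))
    u = np.empty_like(w)
    hit = coincide.any(axis=1)
    if hit.any():
        u[hit] = coincide[hit] / coincide[hit].sum(axis=1, keepdims=True)
    ok = ~hit
    if ok.any():
        # guard against overflow of d**-p for d close to (but not at) a center
        wf = w[ok]
        inf = ~np.isfinite(wf)
        rows_inf = inf.any(axis=1)
        u_ok = np.empty_like(wf)
        if rows_inf.any():
            u_ok[rows_inf] = inf[rows_inf] / inf[rows_inf].sum(axis=1, keepdims=True)
        fin = ~rows_inf
        if fin.any():
            u_ok[fin] = wf[fin] / wf[fin].sum(axis=1, keepdims=True)
        u[ok] = u_ok
    return u


def _check_collapse(centers: np.ndarray, scale: float) -> None:
    for i in range(len(centers) - 1):
        if abs(centers[i + 1] - centers[i]) <= _COLLAPSE_RTOL * max(scale, 1e-300):
            raise CenterCollapseError(i + 1, i + 2, float(centers[i]))


def fcm(intensities, centers_init, m: float = 2.0, tol: float = 1e-5,
        max_iter: int = 100, weights=None, membership_init=None) -> FCMResult:
    """Fuzzy c-means on scalar intensities.

    Parameters
    ----------
    intensities
        Flat array of in-mask intensities (any shape; raveled).
    centers_init
        Initial class centers (e.g. from :func:`kmeans_init`).
    m
        Fuzziness exponent, > 1.  The universal default is 2.
    tol
        Convergence threshold on the largest center move relative to the
        intensity range of the input.
    weights
        Optional per-point multiplicities (used internally to run on value
        histograms).
    membership_init
        Optional (n_points, C) membership matrix; when given, the first
        center update is computed from it instead of using ``centers_init``
        directly — this is how local refinement warm-starts from the global
        solution.

    Raises
    ------
    CenterCollapseError
        If two centers approach within 1e-9 of the intensity range.
    """
    if not m > 1:
        raise ParameterError(f"fuzziness m must be > 1, got {m}")
    if not tol > 0 or max_iter < 1:
        raise ParameterError("tol must be > 0 and max_iter >= 1")
    x, w = _as_weighted_values(intensities, weights)
    centers = np.sort(np.asarray(centers_init, dtype=np.float64).ravel())
    C = centers.size
    if C < 1:
        raise ParameterError("need at least one class center")

    values, counts, inverse = _compress(x, w)
    scale = float(values[-1] - values[0]) if values.size > 1 else 1.0
    if scale == 0.0:
        scale = 1.0

    if membership_init is not None:
        u0 = np.asarray(membership_init, dtype=np.float64)
        if u0.shape != (x.size, C):
            raise ParameterError("membership_init must have shape (n_points, C)")
        um0 = (u0 ** m) * w[:, None]
        denom = um0.sum(axis=0)
        upd = denom > 0
        centers = centers.copy()
        centers[upd] = (um0 * x[:, None]).sum(axis=0)[upd] / denom[upd]
        centers = np.sort(centers)

    objective: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        u = _membership_matrix(values, centers, m)
        um = (u ** m) * counts[:, None]
        objective.append(float((um * (values[:, None] - centers[None, :]) ** 2).sum()))
        denom = um.sum(axis=0)
        new_centers = centers.copy()
        upd = denom > 0
        new_centers[upd] = (um * values[:, None]).sum(axis=0)[upd] / denom[upd]
        new_centers = np.sort(new_centers)
        _check_collapse(new_centers, scale)
        delta = np.abs(new_centers - centers).max() / scale
        centers = new_centers
        if delta < tol:
            break

    u = _membership_matrix(values, centers, m)
    memberships = u[inverse]
    return FCMResult(memberships=memberships, centers=centers,
                     n_iter=n_iter, objective=objective)
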