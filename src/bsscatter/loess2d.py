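"""Two-dimensional LOESS: local quadratic regression with a k-NN span.

For every query point the k nearest samples (k = ceil(span_fraction * n),
inflated to at least 6, the number of quadratic basis terms) are weighted
by a tricube kernel of distance scaled to the k-th neighbour distance, and
a bivariate polynomial of degree 2 is fitted by weighted least squares and
evaluated at the query point.  Coordinates are centred at the query and
scaled by the k-th distance before the solve, which keeps the local normal
equations well conditioned; the fitted value is then simply the intercept.

Queries outside the convex hull of the samples (image borders, plate edge)
are extrapolated by the nearest local fit — the estimated scatter map must
cover the full field of view.

Samples tied with the k-th neighbour distance would receive exactly zero
tricube weight, so restricting the window to the first k neighbours is
equivalent to including all ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["LoessConfig", "loess_fit"]

log = logging.getLogger(__name__)

_N_TERMS = {0: 1, 1: 3, 2: 6}
_COND_LIMIT = 1e10


@dataclass(frozen=True)
class LoessConfig:
    """LOESS tuning: span as a fraction of all samples, polynomial degree.

    The default span of 1% of the samples is the smallest window that
    smooths sampling noise without flattening genuine scatter structure.
    """

    span_fraction: float = 0.01
    degree: int = 2
    weight_kernel: str = "tricube"

    def __post_init__(self) -> None:
        if not 0 < self.span_fraction <= 1:
            raise ValueError("span_fraction must lie in (0, 1]")
        if self.degree not in (0, 1, 2):
            raise ValueError("degree must be 0, 1 or 2")
        if self.weight_kernel != "tricube":
            raise ValueError("only the tricube kernel is supported")


def _design(u: np.ndarray, v: np.ndarray, degree: int) -> np.ndarray:
    """Stacked polynomial design matrices in scaled local coordinates."""
    cols = [np.ones_like(u)]
    if degree >= 1:
        cols += [u, v]
    if degree >= 2:
        cols += [u * u, u * v, v * v]
    return np.stack(cols, axis=-1)


def loess_fit(
    samples: np.ndarray,
    query_points: np.ndarray,
    cfg: LoessConfig = LoessConfig(),
) -> np.ndarray:
    """Evaluate the LOESS surface defined by ``samples`` at ``query_points``.

    Parameters
    ----------
    samples
        Array of shape (n, 3): columns are x, y, z (value).
    query_points
        Array of shape (m, 2): columns are x, y.

    Returns
    -------
    Fitted values, shape (m,). Deterministic.
    """
    samples = np.asarray(samples, dtype=float)
    query_points = np.asarray(query_points, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("samples must have shape (n, 3)")
    if query_points.ndim != 2 or query_points.shape[1] != 2:
        raise ValueError("query_points must have shape (m, 2)")
    n = samples.shape[0]
    if n < 6:
        raise ValueError("LOESS needs at least 6 samples")
    xy = samples[:, :2]
    z = samples[:, 2]
    k = int(np.ceil(cfg.span_fraction * n))
    k = min(n, max(k, _N_TERMS[cfg.degree]))

    tree = cKDTree(xy)
    dist, idx = tree.query(query_points, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]

    dmax = dist[:, -1].copy()
    degenerate = dmax <= 0  # all neighbours coincide with the query
    dmax[degenerate] = 1.0
    r = dist / dmax[:, None]
    w = np.clip(1.0 - r**3, 0.0, None) ** 3
    w[degenerate] = 1.0

    # local coordinates centred at the query, scaled by the span radius
    du = (xy[idx, 0] - query_points[:, None, 0]) / dmax[:, None]
    dv = (xy[idx, 1] - query_points[:, None, 1]) / dmax[:, None]
    zv = z[idx]

    out = np.empty(query_points.shape[0])
    todo = np.ones(query_points.shape[0], dtype=bool)
    for degree in range(cfg.degree, -1, -1):
        if not todo.any():
            break
        sel = np.flatnonzero(todo)
        X = _design(du[sel], dv[sel], degree)  # (m', k, p)
        Ww = w[sel][:, :, None]
        A = np.einsum("mkp,mkq->mpq", X * Ww, X)
        b = np.einsum("mkp,mk->mp", X * Ww, zv[sel])
        if degree == 0:
            wsum = A[:, 0, 0]
            safe = wsum > 0
            out[sel] = np.where(safe, b[:, 0] / np.where(safe, wsum, 1.0), zv[sel].mean(axis=1))
            todo[sel] = False
            break
        cond = np.linalg.cond(A)
        good = np.isfinite(cond) & (cond < _COND_LIMIT)
        if good.any():
            beta = np.linalg.solve(A[good], b[good][:, :, None])[:, :, 0]
            out[sel[good]] = beta[:, 0]
            todo[sel[good]] = False
        n_bad = int((~good).sum())
        if n_bad:
            log.debug("loess: %d rank-deficient local fits, falling back to degree %d", n_bad, degree - 1)
    return out
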