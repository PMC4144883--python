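"""Empirical semivariograms and ordinary/universal kriging solvers.

The experimental semivariogram of a 2-D field is the omnidirectional
average squared difference of values separated by a lag distance,

    gamma(h) = 1 / (2 N(h)) * sum (z(u) - z(u + h))^2,

binned over all unordered pixel pairs whose Euclidean distance falls in the
bin.  Coordinates are 0-based (row, col) in pixel units; lag bin ``b``
covers ((b - 0.5) * lag_width, (b + 0.5) * lag_width].

Kriging weights come from the standard variogram-form linear systems.
Ordinary kriging (OK) augments the neighbor-to-neighbor semivariance matrix
with the unit unbiasedness row (one Lagrange multiplier); universal kriging
(UK) adds polynomial drift-reproduction rows in the pixel coordinates
(degree 1: {1, r, c}; degree 2: {1, r, c, r^2, rc, c^2}).  With the
constant-only basis (degree 0) UK degenerates to OK.

No parametric variogram model is fitted: semivariance at off-bin distances
is linearly interpolated between populated lag centers, anchored at
gamma(0) = 0 and held constant beyond the last populated lag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VariogramTable",
    "KrigingSolution",
    "empirical_semivariogram",
    "semivariance_at",
    "ok_weights",
    "uk_weights",
    "drift_basis",
]

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-8


@dataclass(frozen=True)
class VariogramTable:
    """Experimental semivariogram: one row per lag bin.

    ``gamma`` is NaN for bins with no pixel pairs; ``pair_counts`` records
    the number of unordered pairs per bin.  gamma(0) = 0 is implied and not
    stored.
    """

    lags: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=np.float64)
        gamma = np.asarray(self.gamma, dtype=np.float64)
        counts = np.asarray(self.pair_counts, dtype=np.int64)
        if not (lags.shape == gamma.shape == counts.shape):
            raise ValueError("lags, gamma and pair_counts must have equal length")
        if lags.size and (np.any(lags <= 0) or np.any(np.diff(lags) <= 0)):
            raise ValueError("lags must be positive and strictly ascending")
        populated = counts > 0
        if np.any(gamma[populated] < 0):
            raise ValueError("semivariances must be nonnegative")
        for arr in (lags, gamma, counts):
            arr.setflags(write=False)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "pair_counts", counts)

    @property
    def populated(self) -> np.ndarray:
        return self.pair_counts > 0

    def to_csv(self, path: str | Path) -> None:
        """Write columns lag, gamma, pairs."""
        import pandas as pd

        pd.DataFrame(
            {"lag": self.lags, "gamma": self.gamma, "pairs": self.pair_counts}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class KrigingSolution:
    """Weights and Lagrange multipliers of one kriging solve."""

    weights: np.ndarray
    lagrange: np.ndarray
    method: str  # "OK" | "UK"
    drift_degree: int | None = None
    used_fallback: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        lam = np.asarray(self.lagrange, dtype=np.float64)
        w.setflags(write=False)
        lam.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "lagrange", lam)


def _lag_bin(distance: float, lag_width: float) -> int:
    """Bin index of a pair distance; bin b covers ((b-0.5)w, (b+0.5)w]."""
    return int(math.ceil(distance / lag_width - 0.5))


def empirical_semivariogram(
    field_values: np.ndarray, n_lags: int = 10, lag_width: float = 1.0
) -> VariogramTable:
    """Omnidirectional experimental semivariogram of a 2-D grid.

    All unordered pixel pairs whose Euclidean distance falls within the
    first ``n_lags`` bins contribute; pairs farther apart are ignored.
    Implemented by enumerating integer (drow, dcol) offsets, which visits
    exactly the same pair set as an all-pairs loop.
    """
    z = np.asarray(field_values, dtype=np.float64)
    if z.ndim != 2 or z.size < 2:
        raise ValueError("field must be 2-D with at least 2 pixels")
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if lag_width <= 0:
        raise ValueError("lag_width must be positive")

    n_rows, n_cols = z.shape
    max_d = (n_lags + 0.5) * lag_width
    max_off = int(math.floor(max_d))
    ssq = np.zeros(n_lags + 1)
    cnt = np.zeros(n_lags + 1, dtype=np.int64)
    for dr in range(0, min(max_off, n_rows - 1) + 1):
        dc_lo = 1 if dr == 0 else -min(max_off, n_cols - 1)
        for dc in range(dc_lo, min(max_off, n_cols - 1) + 1):
            dist = math.hypot(dr, dc)
            b = _lag_bin(dist, lag_width)
            if b < 1 or b > n_lags:
                continue
            if dc >= 0:
                a = z[: n_rows - dr, : n_cols - dc]
                bb = z[dr:, dc:]
            else:
                a = z[: n_rows - dr, -dc:]
                bb = z[dr:, : n_cols + dc]
            ssq[b] += float(np.sum((a - bb) ** 2))
            cnt[b] += a.size

    lags = lag_width * np.arange(1, n_lags + 1, dtype=np.float64)
    gamma = np.full(n_lags, np.nan)
    pop = cnt[1:] > 0
    gamma[pop] = ssq[1:][pop] / (2.0 * cnt[1:][pop])
    return VariogramTable(lags=lags, gamma=gamma, pair_counts=cnt[1:])


def semivariance_at(table: VariogramTable, h: float | np.ndarray) -> float | np.ndarray:
    """Semivariance at arbitrary distance(s) from an experimental table.

    Returns 0 at h = 0, linear interpolation between populated lag centers
    (anchored at the origin), and constant extrapolation beyond the last
    populated lag.
    """
    pop = table.populated & np.isfinite(table.gamma)
    if not pop.any():
        raise ValueError("variogram table has no populated lags")
    xp = np.concatenate(([0.0], table.lags[pop]))
    fp = np.concatenate(([0.0], table.gamma[pop]))
    h_arr = np.asarray(h, dtype=np.float64)
    if np.any(h_arr < 0):
        raise ValueError("lag distance must be nonnegative")
    out = np.interp(h_arr, xp, fp)
    if np.isscalar(h) or h_arr.ndim == 0:
        return float(out)
    return out


def drift_basis(coords: np.ndarray, degree: int) -> np.ndarray:
    """Polynomial drift basis evaluated at (row, col) coordinates.

    degree 0 -> {1}; degree 1 -> {1, r, c}; degree 2 -> {1, r, c, r^2, rc, c^2}.
    """
    pts = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    r, c = pts[:, 0], pts[:, 1]
    cols = [np.ones_like(r)]
    if degree >= 1:
        cols += [r, c]
    if degree >= 2:
        cols += [r * r, r * c, c * c]
    if degree not in (0, 1, 2):
        raise ValueError(f"drift degree must be 0, 1 or 2, got {degree}")
    return np.column_stack(cols)


def _check_geometry(neighbors: np.ndarray, target: np.ndarray) -> None:
    if neighbors.shape[0] < 1:
        raise ValueError("at least one neighbor is required")
    diff = neighbors[:, None, :] - neighbors[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, np.inf)
    if np.min(d) < 1e-12:
        raise ValueError("neighbors must be pairwise distinct")
    if np.min(np.sqrt(((neighbors - target) ** 2).sum(-1))) < 1e-12:
        raise ValueError("neighbors must be distinct from the target")


def _solve_kriging(A: np.ndarray, rhs: np.ndarray, tag: str) -> tuple[np.ndarray, bool]:
    """Solve the augmented system; pseudo-solution on singular matrices."""
    try:
        sol = np.linalg.solve(A, rhs)
        if np.isfinite(sol).all():
            resid = np.abs(A @ sol - rhs).max()
            scale = max(np.abs(rhs).max(), 1.0)
            if resid <= 1e-8 * scale:
                return sol, False
    except np.linalg.LinAlgError:
        pass
    logger.warning("singular-kriging: falling back to least-squares (%s)", tag)
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return sol, True


def ok_weights(
    neighbor_coords: np.ndarray,
    target_coord: tuple[float, float] | np.ndarray,
    variogram: VariogramTable,
) -> KrigingSolution:
    """Ordinary-kriging weights for one target from K neighbors.

    Solves the (K+1) x (K+1) augmented system with the unit unbiasedness
    row and one Lagrange multiplier; weights sum to 1.
    """
    P = np.asarray(neighbor_coords, dtype=np.float64).reshape(-1, 2)
    t = np.asarray(target_coord, dtype=np.float64).ravel()
    _check_geometry(P, t)
    K = P.shape[0]

    diff = P[:, None, :] - P[None, :, :]
    G = semivariance_at(variogram, np.sqrt((diff**2).sum(-1)))
    np.fill_diagonal(G, 0.0)

    A = np.zeros((K + 1, K + 1))
    A[:K, :K] = G
    A[K, :K] = 1.0
    A[:K, K] = 1.0
    rhs = np.empty(K + 1)
    rhs[:K] = semivariance_at(variogram, np.sqrt(((P - t) ** 2).sum(-1)))
    rhs[K] = 1.0

    sol, fallback = _solve_kriging(A, rhs, "OK")
    return KrigingSolution(
        weights=sol[:K], lagrange=sol[K:], method="OK", used_fallback=fallback
    )


def uk_weights(
    neighbor_coords: np.ndarray,
    target_coord: tuple[float, float] | np.ndarray,
    variogram: VariogramTable,
    drift_degree: int = 1,
) -> KrigingSolution:
    """Universal-kriging weights with a polynomial drift in pixel coordinates.

    The system extends OK with drift-reproduction constraints
    sum_j w_j f_l(u_j) = f_l(u) for every basis function f_l.  Degree 0
    (constant-only basis) reproduces ordinary kriging exactly.
    """
    P = np.asarray(neighbor_coords, dtype=np.float64).reshape(-1, 2)
    t = np.asarray(target_coord, dtype=np.float64).ravel()
    _check_geometry(P, t)
    K = P.shape[0]

    F = drift_basis(P, drift_degree)
    L = F.shape[1]
    if K < L:
        raise ValueError(
            f"need at least {L} neighbors for drift degree {drift_degree}, got {K}"
        )
    ft = drift_basis(t, drift_degree)[0]

    diff = P[:, None, :] - P[None, :, :]
    G = semivariance_at(variogram, np.sqrt((diff**2).sum(-1)))
    np.fill_diagonal(G, 0.0)

    M = K + L
    A = np.zeros((M, M))
    A[:K, :K] = G
    A[:K, K:] = F
    A[K:, :K] = F.T
    rhs = np.empty(M)
    rhs[:K] = semivariance_at(variogram, np.sqrt(((P - t) ** 2).sum(-1)))
    rhs[K:] = ft

    sol, fallback = _solve_kriging(A, rhs, f"UK degree {drift_degree}")
    return KrigingSolution(
        weights=sol[:K],
        lagrange=sol[K:],
        method="UK",
        drift_degree=drift_degree,
        used_fallback=fallback,
    )
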