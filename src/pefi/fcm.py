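"""Fuzzy c-means clustering of pixel intensities.

The image is partitioned into ``c`` fuzzy clusters by minimizing the
weighted squared-error objective

    J_m(U, V) = sum_i sum_k u_ik^m * |x_i - v_k|^2

subject to each pixel's memberships summing to one.  Clustering runs on the
scalar gray levels only (1-D feature space); spatial coordinates play no
role at this stage.  The alternating-optimization updates are the standard
ones: centers are the m-weighted means of the data, memberships the
inverse-distance ratios with exponent 2/(m-1).

Clusters are always relabeled so the centers ascend, which makes feature
positions comparable across images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import IntensityImage

__all__ = [
    "FuzzyPartition",
    "DegenerateImageError",
    "fcm_fit",
    "fcm_membership_update",
    "fcm_objective",
]

_ROW_SUM_TOL = 1e-9


class DegenerateImageError(ValueError):
    """Raised when the image has fewer distinct gray levels than clusters."""


@dataclass(frozen=True)
class FuzzyPartition:
    """Result of a fuzzy c-means fit on one image or window.

    Attributes
    ----------
    memberships : (n_pixels, c) array
        Membership grades in [0, 1]; rows sum to 1.  Pixel order is the
        row-major flattening of the source image.
    centers : (c,) array
        Cluster centers in [0, 1], strictly ascending.
    m : float
        Fuzzy weighting exponent (> 1).
    objective_trace : tuple of float
        Objective value after each completed iteration; non-increasing.
    """

    memberships: np.ndarray = field(repr=False)
    centers: np.ndarray
    m: float
    objective_trace: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        U = np.asarray(self.memberships, dtype=np.float64)
        V = np.asarray(self.centers, dtype=np.float64)
        if U.ndim != 2 or U.shape[1] != V.shape[0]:
            raise ValueError("memberships and centers have incompatible shapes")
        rows = U.sum(axis=1)
        if np.abs(rows - 1.0).max() > _ROW_SUM_TOL:
            raise ValueError("membership rows must sum to 1")
        if V.size > 1 and not np.all(np.diff(V) > 0):
            raise ValueError("centers must be strictly ascending")
        U.setflags(write=False)
        V.setflags(write=False)
        object.__setattr__(self, "memberships", U)
        object.__setattr__(self, "centers", V)

    @property
    def c(self) -> int:
        return self.centers.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.memberships.shape[0]


def fcm_membership_update(
    values: np.ndarray, centers: np.ndarray, m: float
) -> np.ndarray:
    """One membership update: inverse-distance ratios, exponent 2/(m-1).

    A pixel coinciding exactly with a center receives crisp membership to
    that center (the limit of the update as the distance vanishes).
    Coincident centers are a numerical error and are rejected before any
    division takes place.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    v = np.asarray(centers, dtype=np.float64).ravel()
    if v.size > 1 and np.min(np.abs(np.diff(np.sort(v)))) < 1e-12:
        raise FloatingPointError("coincident cluster centers in membership update")
    d = np.abs(x[:, None] - v[None, :])
    at_center = d < 1e-15
    U = np.zeros((x.size, v.size))
    crisp_rows = at_center.any(axis=1)
    if crisp_rows.any():
        U[crisp_rows] = at_center[crisp_rows].astype(np.float64)
    free = ~crisp_rows
    if free.any():
        p = 2.0 / (m - 1.0)
        with np.errstate(over="ignore", divide="ignore"):
            w = d[free] ** (-p)
        bad = ~np.isfinite(w).all(axis=1)
        w_sum = w.sum(axis=1, keepdims=True)
        Uf = w / w_sum
        if bad.any():
            # overflow: effectively at a center, fall back to crisp coding
            Uf[bad] = 0.0
            Uf[bad, np.argmin(d[free][bad], axis=1)] = 1.0
        U[free] = Uf
    return U


def fcm_objective(
    values: np.ndarray, memberships: np.ndarray, centers: np.ndarray, m: float
) -> float:
    """Weighted squared-error objective sum_i sum_k u_ik^m (x_i - v_k)^2."""
    x = np.asarray(values, dtype=np.float64).ravel()
    U = np.asarray(memberships, dtype=np.float64)
    v = np.asarray(centers, dtype=np.float64).ravel()
    if U.shape != (x.size, v.size):
        raise ValueError(
            f"membership shape {U.shape} does not match "
            f"{x.size} pixels x {v.size} clusters"
        )
    d2 = (x[:, None] - v[None, :]) ** 2
    return float(np.sum((U**m) * d2))


def fcm_fit(
    image: IntensityImage | np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyPartition:
    """Fit a fuzzy c-means partition to the gray levels of an image.

    Parameters
    ----------
    image : IntensityImage or array
        Gray levels in [0, 1]; flattened row-major.
    c : int
        Number of clusters (>= 2).  The image must contain at least ``c``
        distinct gray levels.
    m : float
        Fuzzy exponent, > 1.
    tol : float
        Convergence threshold on the maximum absolute membership change
        between successive iterations.
    max_iter : int
        Iteration cap.
    seed : int
        Seed for the random row-stochastic initialization of the
        membership matrix; required for reproducibility.

    Returns
    -------
    FuzzyPartition
        With clusters relabeled so centers ascend and the per-iteration
        objective trace attached.
    """
    if isinstance(image, IntensityImage):
        x = image.values.ravel()
    else:
        x = np.asarray(image, dtype=np.float64).ravel()
    if c < 2:
        raise ValueError(f"need at least 2 clusters, got c={c}")
    if m <= 1.0:
        raise ValueError(f"fuzzy exponent must exceed 1, got m={m}")
    if x.size == 0:
        raise ValueError("empty image")
    if np.unique(x).size < c:
        raise DegenerateImageError(
            f"image has {np.unique(x).size} distinct gray levels; "
            f"cannot form {c} clusters"
        )

    rng = np.random.default_rng(seed)
    U = rng.random((x.size, c))
    U /= U.sum(axis=1, keepdims=True)

    trace: list[float] = []
    for _ in range(max_iter):
        Um = U**m
        V = (Um * x[:, None]).sum(axis=0) / Um.sum(axis=0)
        U_new = fcm_membership_update(x, V, m)
        delta = np.abs(U_new - U).max()
        U = U_new
        trace.append(fcm_objective(x, U, V, m))
        if delta <= tol:
            break

    order = np.argsort(V)
    return FuzzyPartition(
        memberships=U[:, order],
        centers=V[order],
        m=float(m),
        objective_trace=tuple(trace),
    )
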