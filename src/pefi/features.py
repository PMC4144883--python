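"""Spatial-uncertainty texture features.

The feature of this package is the entropy of a fuzzy event with respect to
an indicator-kriged probability field (PEFI).  For one image window:

1. fuzzy c-means partitions the gray levels into ``c`` clusters
   (:mod:`pefi.fcm`);
2. each (cluster k, level alpha) pair yields a binary indicator field:
   pixel coded 1 iff its membership to cluster k is >= alpha;
3. every pixel is treated as unsampled and its class probability is
   estimated by ordinary or universal kriging from its K nearest coded
   neighbors, using the window's own experimental indicator semivariogram
   (:mod:`pefi.geostat`);
4. the kriged probabilities, normalized over the window, define a
   distribution P, and the feature entry is the fuzzy-event entropy

       H(mu_k; P) = - sum_i mu_k(x_i) p_i log2 p_i,   0 log 0 := 0.

Entries are ordered cluster-major then alpha ascending, giving a vector of
length c * |alphas| per window.  PEFI1 denotes the ordinary-kriging variant
and PEFI2 the universal-kriging (polynomial drift) variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .fcm import FuzzyPartition, fcm_fit
from .geostat import (
    VariogramTable,
    empirical_semivariogram,
    ok_weights,
    uk_weights,
)
from .image import IntensityImage

__all__ = [
    "IndicatorField",
    "KrigedProbabilityField",
    "PEFIVector",
    "indicator_code",
    "krige_probability_field",
    "fuzzy_event_entropy",
    "pefi_features",
    "scan_image",
    "feature_names",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHAS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class IndicatorField:
    """Binary field coding one (cluster, alpha-cut) of a fuzzy partition."""

    values: np.ndarray = field(repr=False)
    cluster_index: int
    alpha: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.uint8)
        if arr.ndim != 2:
            raise ValueError("indicator field must be 2-D")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("indicator values must be 0 or 1")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class KrigedProbabilityField:
    """Per-pixel kriged probability of cluster membership at one alpha."""

    values: np.ndarray = field(repr=False)
    method: str
    k_neighbors: int
    cluster_index: int
    alpha: float
    n_singular_fallbacks: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2 or arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("kriged probabilities must form a 2-D field in [0, 1]")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class PEFIVector:
    """Entropy feature vector of one window: cluster-major, alpha ascending."""

    entries: np.ndarray
    c: int
    m: float
    alphas: tuple[float, ...]
    k_neighbors: int
    method: str
    drift_degree: int | None
    n_lags: int
    window_shape: tuple[int, int]
    n_singular_fallbacks: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=np.float64)
        if arr.shape != (self.c * len(self.alphas),):
            raise ValueError("feature length must be c * number of alpha cuts")
        if np.any(arr < 0):
            raise ValueError("entropies must be nonnegative")
        arr.setflags(write=False)
        object.__setattr__(self, "entries", arr)


def feature_names(c: int, alphas: tuple[float, ...]) -> list[str]:
    """CSV column headers, H_k{cluster}_a{alpha}, cluster-major."""
    return [f"H_k{k}_a{a:g}" for k in range(c) for a in sorted(alphas)]


def indicator_code(
    partition: FuzzyPartition,
    cluster_index: int,
    alpha: float,
    shape: tuple[int, int],
) -> IndicatorField:
    """Code pixels 1 iff membership to the cluster is >= alpha (inclusive)."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if not 0 <= cluster_index < partition.c:
        raise ValueError(f"cluster index {cluster_index} out of range")
    mu = partition.memberships[:, cluster_index]
    if mu.size != shape[0] * shape[1]:
        raise ValueError("window shape does not match partition size")
    return IndicatorField(
        values=(mu >= alpha).astype(np.uint8).reshape(shape),
        cluster_index=cluster_index,
        alpha=float(alpha),
    )


@lru_cache(maxsize=16)
def _window_geometry(shape: tuple[int, int], k_neighbors: int):
    """Neighbor structure of a window, shared by all fields of that shape.

    For every pixel, the K nearest *other* pixels by Euclidean distance
    (ties broken by row-major scan order).  Because kriging weights depend
    on coordinates only through the relative neighbor offsets, pixels are
    grouped by offset pattern so one solve serves the whole group.
    """
    n_rows, n_cols = shape
    n = n_rows * n_cols
    if n <= k_neighbors:
        raise ValueError(
            f"window of {n} pixels too small for K={k_neighbors} neighbors"
        )
    coords = np.indices(shape).reshape(2, -1).T.astype(np.int64)  # row-major
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.iinfo(np.int64).max)
    neighbor_idx = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbors]
    offsets = coords[neighbor_idx] - coords[:, None, :]  # (n, K, 2)
    patterns, group_of = np.unique(
        offsets.reshape(n, -1), axis=0, return_inverse=True
    )
    patterns = patterns.reshape(-1, k_neighbors, 2)
    return coords, neighbor_idx, patterns, group_of


def _group_weights(
    patterns: np.ndarray,
    variogram: VariogramTable,
    method: str,
    drift_degree: int,
) -> tuple[np.ndarray, int]:
    """Solve one kriging system per unique offset pattern (target at origin)."""
    weights = np.empty((patterns.shape[0], patterns.shape[1]))
    n_fallback = 0
    target = np.zeros(2)
    for g, offs in enumerate(patterns):
        if method == "OK":
            sol = ok_weights(offs.astype(np.float64), target, variogram)
        else:
            sol = uk_weights(
                offs.astype(np.float64), target, variogram, drift_degree
            )
        weights[g] = sol.weights
        n_fallback += int(sol.used_fallback)
    return weights, n_fallback


def krige_probability_field(
    indicator: IndicatorField,
    k_neighbors: int = 5,
    method: str = "OK",
    drift_degree: int = 1,
    n_lags: int = 10,
    lag_width: float = 1.0,
) -> KrigedProbabilityField:
    """Estimate each pixel's class probability from its coded neighbors.

    Every pixel is treated as unsampled (leave-one-out) and estimated as the
    weighted sum of its K spatially nearest indicator values, with weights
    from the OK/UK system built on the window's own experimental indicator
    semivariogram.  Estimates are clamped to [0, 1].  A constant indicator
    field short-circuits to that constant without any solve.
    """
    if method not in ("OK", "UK"):
        raise ValueError(f"method must be 'OK' or 'UK', got {method!r}")
    z = indicator.values.astype(np.float64)
    n_rows, n_cols = z.shape
    if z.size <= k_neighbors:
        raise ValueError(
            f"window of {z.size} pixels too small for K={k_neighbors}"
        )

    if z.max() == z.min():
        return KrigedProbabilityField(
            values=np.full_like(z, z.flat[0]),
            method=method,
            k_neighbors=k_neighbors,
            cluster_index=indicator.cluster_index,
            alpha=indicator.alpha,
        )

    variogram = empirical_semivariogram(z, n_lags=n_lags, lag_width=lag_width)
    _, neighbor_idx, patterns, group_of = _window_geometry(
        (n_rows, n_cols), k_neighbors
    )
    group_w, n_fallback = _group_weights(
        patterns, variogram, method, drift_degree
    )
    if n_fallback:
        logger.warning(
            "singular-kriging: %d of %d local systems used least squares",
            n_fallback,
            patterns.shape[0],
        )
    est = np.einsum("nk,nk->n", group_w[group_of], z.ravel()[neighbor_idx])
    est = np.clip(est, 0.0, 1.0).reshape(n_rows, n_cols)
    return KrigedProbabilityField(
        values=est,
        method=method,
        k_neighbors=k_neighbors,
        cluster_index=indicator.cluster_index,
        alpha=indicator.alpha,
        n_singular_fallbacks=n_fallback,
    )


def fuzzy_event_entropy(
    memberships: np.ndarray, probabilities: np.ndarray
) -> float:
    """Entropy of a fuzzy event with respect to a probability field.

    The raw kriged values are normalized to a distribution over the window
    (p_i = F_i / sum_j F_j); if the total mass is zero the entropy is 0.
    Returns -sum_i mu_i p_i log2 p_i with 0 log 0 := 0 (bits).
    """
    mu = np.asarray(memberships, dtype=np.float64).ravel()
    p_raw = np.asarray(probabilities, dtype=np.float64).ravel()
    if mu.shape != p_raw.shape:
        raise ValueError("memberships and probabilities must have equal length")
    if np.any(p_raw < 0):
        raise ValueError("probabilities must be nonnegative")
    total = p_raw.sum()
    if total == 0.0:
        return 0.0
    p = p_raw / total
    pos = p > 0
    h = -np.sum(mu[pos] * p[pos] * np.log2(p[pos]))
    return float(max(h, 0.0))


def pefi_features(
    window: IntensityImage | np.ndarray,
    c: int = 3,
    m: float = 2.0,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    k_neighbors: int = 5,
    method: str = "OK",
    drift_degree: int = 1,
    n_lags: int = 10,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> PEFIVector:
    """Extract the entropy feature vector of one window.

    Runs one fuzzy c-means fit, then for every (cluster, alpha) pair codes
    the indicator field, kriges the probability field and evaluates the
    fuzzy-event entropy.  Deterministic given the seed.
    """
    if not isinstance(window, IntensityImage):
        window = IntensityImage(np.asarray(window, dtype=np.float64))
    alphas = tuple(sorted(float(a) for a in alphas))
    partition = fcm_fit(window, c=c, m=m, tol=tol, max_iter=max_iter, seed=seed)

    entries = np.empty(c * len(alphas))
    n_fallback = 0
    pos = 0
    for k in range(c):
        mu_k = partition.memberships[:, k]
        for alpha in alphas:
            ind = indicator_code(partition, k, alpha, window.shape)
            if not ind.values.any():
                logger.debug(
                    "empty indicator at cluster %d alpha %.2f; entropy 0", k, alpha
                )
                entries[pos] = 0.0
                pos += 1
                continue
            kp = krige_probability_field(
                ind,
                k_neighbors=k_neighbors,
                method=method,
                drift_degree=drift_degree,
                n_lags=n_lags,
            )
            n_fallback += kp.n_singular_fallbacks
            entries[pos] = fuzzy_event_entropy(mu_k, kp.values)
            pos += 1

    return PEFIVector(
        entries=entries,
        c=c,
        m=float(m),
        alphas=alphas,
        k_neighbors=k_neighbors,
        method=method,
        drift_degree=drift_degree if method == "UK" else None,
        n_lags=n_lags,
        window_shape=window.shape,
        n_singular_fallbacks=n_fallback,
    )


def scan_image(
    image: IntensityImage,
    window_shape: tuple[int, int],
    stride: tuple[int, int] | None = None,
    **feature_params,
) -> list[tuple[tuple[int, int], PEFIVector]]:
    """Slide a window over the image and extract one feature vector each.

    Windows are enumerated row-major at the given stride (default: tiling
    by the window shape); partial windows at the borders are skipped.
    """
    wr, wc = window_shape
    if wr > image.n_rows or wc > image.n_cols:
        raise ValueError(
            f"window {window_shape} larger than image {image.shape}"
        )
    if stride is None:
        stride = window_shape
    sr, sc = stride
    if sr < 1 or sc < 1:
        raise ValueError("stride must be positive")

    results = []
    for r0 in range(0, image.n_rows - wr + 1, sr):
        for c0 in range(0, image.n_cols - wc + 1, sc):
            vec = pefi_features(image.window((r0, c0), window_shape), **feature_params)
            results.append(((r0, c0), vec))
    return results
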