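"""Prototype-distance and k-NN classification of feature vectors.

The decision rule is nearest-prototype matching: a test vector is assigned
to the class whose trained prototype (class mean) it differs from the least
under the chosen distance (Euclidean or Mahalanobis with a pooled
within-class covariance).  A k-nearest-neighbor classifier and
sensitivity/specificity evaluation with stratified Monte-Carlo splits are
provided for multi-class problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "ClassPrototypes",
    "train_prototypes",
    "classify_distance",
    "knn_classify",
    "evaluate",
    "monte_carlo_splits",
    "monte_carlo_evaluate",
]


def _as_matrix(features) -> np.ndarray:
    rows = [
        f.entries if hasattr(f, "entries") else np.asarray(f, dtype=np.float64)
        for f in features
    ]
    return np.atleast_2d(np.asarray(rows, dtype=np.float64))


@dataclass(frozen=True)
class ClassPrototypes:
    """Per-class mean vectors plus a pooled, ridge-regularized covariance."""

    class_labels: tuple
    means: np.ndarray = field(repr=False)
    pooled_covariance: np.ndarray = field(repr=False)
    regularization: float

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=np.float64)
        cov = np.asarray(self.pooled_covariance, dtype=np.float64)
        if means.ndim != 2 or means.shape[0] != len(self.class_labels):
            raise ValueError("one mean vector per class is required")
        if cov.shape != (means.shape[1], means.shape[1]):
            raise ValueError("covariance shape does not match feature dimension")
        if np.abs(cov - cov.T).max() > 1e-12:
            raise ValueError("pooled covariance must be symmetric")
        means.setflags(write=False)
        cov.setflags(write=False)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "pooled_covariance", cov)


def train_prototypes(features, labels) -> ClassPrototypes:
    """Class means and pooled within-class covariance with a ridge.

    The covariance is the within-class scatter divided by (n - Q); the
    ridge added to its diagonal is 1e-6 * trace / d (or 1e-6 when all
    samples coincide), which keeps the Mahalanobis metric defined even for
    degenerate training sets.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have equal length")
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")

    n, d = X.shape
    means = np.empty((len(classes), d))
    scatter = np.zeros((d, d))
    for q, label in enumerate(classes):
        Xq = X[y == label]
        if Xq.shape[0] == 0:
            raise ValueError(f"class {label!r} has no samples")
        means[q] = Xq.mean(axis=0)
        centered = Xq - means[q]
        scatter += centered.T @ centered

    dof = max(n - len(classes), 1)
    cov = scatter / dof
    trace = float(np.trace(cov))
    ridge = 1e-6 * (trace / d) if trace > 0 else 1e-6
    cov = cov + ridge * np.eye(d)
    return ClassPrototypes(
        class_labels=classes,
        means=means,
        pooled_covariance=cov,
        regularization=ridge,
    )


def classify_distance(feature, prototypes: ClassPrototypes, metric: str = "euclidean"):
    """Assign the class whose prototype is nearest; ties go to the lowest index.

    With ``metric='mahalanobis'`` distances use the inverse of the pooled
    covariance, which must be positive definite after the ridge.
    """
    x = feature.entries if hasattr(feature, "entries") else np.asarray(feature)
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.shape[0] != prototypes.means.shape[1]:
        raise ValueError("feature dimension does not match prototypes")
    diff = prototypes.means - x[None, :]
    if metric == "euclidean":
        d2 = (diff**2).sum(axis=1)
    elif metric == "mahalanobis":
        try:
            factor = cho_factor(prototypes.pooled_covariance)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "pooled covariance is not positive definite"
            ) from exc
        d2 = np.einsum("qd,dq->q", diff, cho_solve(factor, diff.T))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return prototypes.class_labels[int(np.argmin(d2))]


def knn_classify(feature, training_features, training_labels, k: int = 3):
    """Majority vote among the k nearest training samples (Euclidean).

    Distance ties are broken by training-set order; vote ties go to the
    tied class whose nearest member is closest.
    """
    X = _as_matrix(training_features)
    y = np.asarray(training_labels)
    if k < 1 or k > X.shape[0]:
        raise ValueError(f"k={k} must be between 1 and the training size {X.shape[0]}")
    x = feature.entries if hasattr(feature, "entries") else np.asarray(feature)
    x = np.asarray(x, dtype=np.float64).ravel()
    d = np.sqrt(((X - x[None, :]) ** 2).sum(axis=1))
    order = np.lexsort((np.arange(X.shape[0]), d))[:k]
    votes: dict = {}
    for rank, idx in enumerate(order):
        label = y[idx].item() if hasattr(y[idx], "item") else y[idx]
        if label not in votes:
            votes[label] = [0, rank]  # count, rank of nearest member
        votes[label][0] += 1
    best = max(votes.items(), key=lambda kv: (kv[1][0], -kv[1][1]))
    return best[0]


def evaluate(predictions, truth, positive_label=None) -> dict:
    """Classification metrics as percentages.

    Returns total accuracy and per-class accuracy; for binary problems also
    sensitivity (true-positive rate on ``positive_label``, by default the
    larger of the two labels) and specificity (true-negative rate).
    """
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predictions and truth must have equal length")
    labels = sorted(set(true.tolist()))
    extra = set(pred.tolist()) - set(labels)
    if extra:
        raise ValueError(f"predicted labels {extra} never occur in the truth")

    correct = pred == true
    per_class = {
        label: 100.0 * float(correct[true == label].mean()) for label in labels
    }
    metrics: dict = {
        "accuracy": 100.0 * float(correct.mean()),
        "per_class_accuracy": per_class,
        "sensitivity": None,
        "specificity": None,
    }
    if len(labels) == 2:
        pos = positive_label if positive_label is not None else labels[1]
        if pos not in labels:
            raise ValueError(f"positive label {pos!r} not among {labels}")
        neg = labels[0] if pos == labels[1] else labels[1]
        metrics["sensitivity"] = per_class[pos]
        metrics["specificity"] = per_class[neg]
        metrics["positive_label"] = pos
    return metrics


def monte_carlo_splits(
    labels, n_splits: int = 10, train_fraction: float = 0.5, seed: int = 0
):
    """Seeded stratified train/test splits (default 50/50 per class, 10 reps)."""
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = sorted(set(y.tolist()))
    splits = []
    for _ in range(n_splits):
        train_idx, test_idx = [], []
        for label in classes:
            idx = np.flatnonzero(y == label)
            if idx.size < 2:
                raise ValueError(f"class {label!r} needs >= 2 samples to split")
            perm = rng.permutation(idx)
            n_train = max(1, min(idx.size - 1, int(round(idx.size * train_fraction))))
            train_idx.extend(perm[:n_train])
            test_idx.extend(perm[n_train:])
        splits.append((np.sort(np.array(train_idx)), np.sort(np.array(test_idx))))
    return splits


def monte_carlo_evaluate(
    features,
    labels,
    classifier: str = "prototype",
    metric: str = "euclidean",
    knn_k: int = 3,
    n_splits: int = 10,
    seed: int = 0,
    positive_label=None,
) -> dict:
    """Mean metrics over seeded stratified Monte-Carlo train/test splits."""
    X = _as_matrix(features)
    y = np.asarray(labels)
    split_metrics = []
    for train_idx, test_idx in monte_carlo_splits(y, n_splits=n_splits, seed=seed):
        if classifier == "prototype":
            protos = train_prototypes(X[train_idx], y[train_idx])
            pred = [classify_distance(x, protos, metric=metric) for x in X[test_idx]]
        elif classifier == "knn":
            pred = [
                knn_classify(x, X[train_idx], y[train_idx], k=knn_k)
                for x in X[test_idx]
            ]
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
        split_metrics.append(
            evaluate(np.asarray(pred), y[test_idx], positive_label=positive_label)
        )

    mean = {}
    for key in ("accuracy", "sensitivity", "specificity"):
        vals = [sm[key] for sm in split_metrics if sm[key] is not None]
        mean[key] = float(np.mean(vals)) if vals else None
    return {"splits": split_metrics, "mean": mean, "n_splits": n_splits}
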