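"""Classification harness: KNN on rate features and on VP distance matrices.

The headline protocol is stratified 5-fold cross-validation with a
PCA(3) + KNN(5) decoder on spike counts (rate code) or a precomputed-
distance KNN on population Victor-Purpura matrices (temporal code).  An
80/20 holdout split is available as an alternative protocol.  KNN ties are
broken deterministically in favor of the label of the closest neighbor
among the tied classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, pairwise_distances
from sklearn.model_selection import StratifiedKFold, train_test_split

from .coding import pca_reduce, spike_count_features
from .encoder import PopulationResponse

__all__ = [
    "EvalConfig",
    "EvalResult",
    "chance_level",
    "knn_rate",
    "knn_temporal",
    "subpopulation_eval",
]


@dataclass(frozen=True)
class EvalConfig:
    k_neighbors: int = 5
    test_fraction: float = 0.2
    n_folds: int = 5
    seed: int = 0
    n_components: int = 3
    protocol: str = "cv"  # "cv" | "holdout"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.protocol not in ("cv", "holdout"):
            raise ValueError("protocol must be 'cv' or 'holdout'")


@dataclass(frozen=True)
class EvalResult:
    accuracy: float
    per_fold: tuple[float, ...]
    confusion: np.ndarray
    classes: tuple
    condition: str = ""


def chance_level(n_classes: int) -> float:
    """Expected accuracy of label guessing: 1/n_classes."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 1.0 / n_classes


def _knn_predict(D: np.ndarray, y_train: np.ndarray, k: int) -> np.ndarray:
    """KNN vote from a (n_test, n_train) distance matrix.

    Tie-break: among vote-tied classes, the class of the nearest tied
    neighbor wins — deterministic for fixed data.
    """
    preds = []
    for row in D:
        order = np.argsort(row, kind="stable")[:k]
        votes: dict = {}
        for idx in order:
            votes[y_train[idx]] = votes.get(y_train[idx], 0) + 1
        top = max(votes.values())
        tied = {lab for lab, v in votes.items() if v == top}
        for idx in order:  # nearest neighbor belonging to a tied class
            if y_train[idx] in tied:
                preds.append(y_train[idx])
                break
    return np.asarray(preds)


def _check_folds(y: np.ndarray, train_idx: np.ndarray, classes: np.ndarray, k: int) -> None:
    y_tr = y[train_idx]
    missing = set(classes) - set(y_tr)
    if missing:
        raise ValueError(f"classes {sorted(map(str, missing))} absent from a training fold")
    if len(y_tr) < k:
        raise ValueError("fewer training samples than k_neighbors")


def _splits(y: np.ndarray, config: EvalConfig):
    if config.protocol == "cv":
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
        yield from skf.split(np.zeros(len(y)), y)
    else:
        idx = np.arange(len(y))
        tr, te = train_test_split(
            idx, test_size=config.test_fraction, random_state=config.seed, stratify=y
        )
        yield tr, te


def _evaluate(distance_fn, y: np.ndarray, config: EvalConfig, condition: str) -> EvalResult:
    """Shared fold loop; ``distance_fn(train_idx, test_idx)`` yields the
    (n_test, n_train) distance matrix for one split."""
    classes = np.unique(y)
    per_fold = []
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for train_idx, test_idx in _splits(y, config):
        _check_folds(y, train_idx, classes, config.k_neighbors)
        D = distance_fn(train_idx, test_idx)
        pred = _knn_predict(D, y[train_idx], config.k_neighbors)
        per_fold.append(float(np.mean(pred == y[test_idx])))
        conf += confusion_matrix(y[test_idx], pred, labels=classes)
    return EvalResult(
        accuracy=float(np.mean(per_fold)),
        per_fold=tuple(per_fold),
        confusion=conf,
        classes=tuple(classes),
        condition=condition,
    )


def knn_rate(
    features: np.ndarray,
    labels: Sequence,
    config: EvalConfig | None = None,
    condition: str = "rate",
) -> EvalResult:
    """Rate-code decoder: per-fold PCA(3) on spike counts, then KNN(5).

    The PCA axes are fitted on each training fold only, so held-out trials
    never leak into the projection.
    """
    config = config or EvalConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)

    def distance_fn(train_idx, test_idx):
        Xt = pca_reduce(X[train_idx], config.n_components)
        Xe = pca_reduce(X[test_idx], config.n_components, fit_on=X[train_idx])
        return pairwise_distances(Xe, Xt, metric="euclidean")

    return _evaluate(distance_fn, y, config, condition)


def knn_temporal(
    distances: np.ndarray,
    labels: Sequence,
    config: EvalConfig | None = None,
    condition: str = "temporal",
) -> EvalResult:
    """Temporal-code decoder: KNN on a precomputed population VP matrix."""
    config = config or EvalConfig()
    D = np.asarray(distances, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    y = np.asarray(labels)

    def distance_fn(train_idx, test_idx):
        return D[np.ix_(test_idx, train_idx)]

    return _evaluate(distance_fn, y, config, condition)


def subpopulation_eval(
    responses: Sequence[PopulationResponse],
    labels: Sequence,
    subset: Sequence[str],
    window_ms: tuple[float, float] = (0.0, 500.0),
    config: EvalConfig | None = None,
) -> EvalResult:
    """Rate-code evaluation restricted to the named afferent kinds.

    ``subset`` is any non-empty combination of "SA1", "RA1", "NOC"; the
    full set reproduces the whole-population evaluation.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    filtered = [r.by_kind(subset) for r in responses]
    if len(filtered[0].trains) == 0:
        raise ValueError(f"no channels of kinds {subset}")
    X = spike_count_features(filtered, window_ms)
    return knn_rate(X, labels, config, condition="+".join(subset))
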