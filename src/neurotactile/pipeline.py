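"""Scikit-learn style estimators wrapping the tactile pipeline.

``TactileEncoder`` (trials -> spike responses) and ``SpikeCountFeaturizer``
(responses -> count matrix) are transformers; ``RateCodeClassifier``
(PCA + KNN on counts) and ``TemporalCodeClassifier`` (KNN on population
Victor-Purpura distances) are classifiers.  All follow the fit/transform/
predict contract with trailing-underscore fitted attributes, so they
compose with sklearn pipelines and model selection; the module-level
functions in :mod:`neurotactile.classify` stay thin wrappers over the same
machinery.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances
from sklearn.utils.validation import check_is_fitted

from .classify import _knn_predict
from .coding import (
    DEFAULT_Q_PER_MS,
    spike_count_features,
    vp_distance,
    windowed_times,
)
from .encoder import NociceptorSpec, PopulationResponse, encode_dataset, nociceptor_gains
from .innervation import build_innervation
from .stimuli import GridSpec, TrialRecord

__all__ = [
    "TactileEncoder",
    "SpikeCountFeaturizer",
    "RateCodeClassifier",
    "TemporalCodeClassifier",
]


class TactileEncoder(BaseEstimator, TransformerMixin):
    """Transformer: pressure-frame trials -> population spike responses.

    ``fit`` draws the random innervation map (receptive fields) and the
    per-nociceptor gain jitter from ``random_state``; ``transform`` encodes
    trials deterministically through the Izhikevich front-end.

    Parameters
    ----------
    n_sa, n_ra, n_noc : population sizes (defaults 6, 12, 5 -> 23 channels).
    mean_taxels : mean receptive-field size in taxels.
    noc_threshold_adc : taxel count a nociceptor requires for NoT.
    fixed_point : run the Q13.18 hardware-equivalent datapath.
    random_state : seed for innervation and nociceptor gains.
    """

    def __init__(
        self,
        n_sa: int = 6,
        n_ra: int = 12,
        n_noc: int = 5,
        mean_taxels: float = 3.0,
        noc_threshold_adc: int = 512,
        fixed_point: bool = False,
        random_state: int = 0,
    ):
        self.n_sa = n_sa
        self.n_ra = n_ra
        self.n_noc = n_noc
        self.mean_taxels = mean_taxels
        self.noc_threshold_adc = noc_threshold_adc
        self.fixed_point = fixed_point
        self.random_state = random_state

    def fit(self, X: Sequence[TrialRecord], y=None) -> "TactileEncoder":
        grid = X[0].grid if len(X) else GridSpec()
        self.innervation_map_ = build_innervation(
            n_sa=self.n_sa,
            n_ra=self.n_ra,
            mean_taxels=self.mean_taxels,
            grid=grid,
            seed=self.random_state,
        )
        self.noc_spec_ = NociceptorSpec(threshold_adc=self.noc_threshold_adc, n_noc=self.n_noc)
        self.noc_gains_ = nociceptor_gains(self.n_noc, seed=self.random_state)
        self.n_channels_ = self.n_noc + self.n_sa + self.n_ra
        return self

    def transform(self, X: Sequence[TrialRecord]) -> list[PopulationResponse]:
        check_is_fitted(self, "innervation_map_")
        return encode_dataset(
            X,
            self.innervation_map_,
            self.noc_spec_,
            noc_gain_seed=self.random_state,
            fixed_point=self.fixed_point,
        )


class SpikeCountFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer: spike responses -> windowed per-channel count matrix."""

    def __init__(
        self,
        window_ms: tuple[float, float] = (0.0, 500.0),
        kinds: tuple[str, ...] | None = None,
    ):
        self.window_ms = window_ms
        self.kinds = kinds

    def fit(self, X: Sequence[PopulationResponse], y=None) -> "SpikeCountFeaturizer":
        self.n_channels_ = len(self._filter(X)[0].trains)
        return self

    def _filter(self, X: Sequence[PopulationResponse]) -> list[PopulationResponse]:
        if self.kinds is None:
            return list(X)
        return [r.by_kind(self.kinds) for r in X]

    def transform(self, X: Sequence[PopulationResponse]) -> np.ndarray:
        check_is_fitted(self, "n_channels_")
        return spike_count_features(self._filter(X), self.window_ms)


class RateCodeClassifier(BaseEstimator, ClassifierMixin):
    """PCA + KNN decoder on spike-count features.

    PCA (default 3 components) is fitted on the training counts only; test
    samples are classified by majority vote among the ``n_neighbors``
    nearest training samples in the projected space, ties broken by the
    nearest tied neighbor.
    """

    def __init__(self, n_neighbors: int = 5, n_components: int = 3):
        self.n_neighbors = n_neighbors
        self.n_components = n_components

    def fit(self, X: np.ndarray, y: Sequence) -> "RateCodeClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        k = min(self.n_components, X.shape[0], X.shape[1])
        self.pca_ = PCA(n_components=k).fit(X)
        self.X_train_ = self.pca_.transform(X)
        self.y_train_ = y
        self.classes_ = np.unique(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "pca_")
        Z = self.pca_.transform(np.asarray(X, dtype=float))
        D = pairwise_distances(Z, self.X_train_, metric="euclidean")
        return _knn_predict(D, self.y_train_, self.n_neighbors)


class TemporalCodeClassifier(BaseEstimator, ClassifierMixin):
    """KNN decoder on population Victor-Purpura distances.

    ``fit`` stores the training responses; ``predict`` computes the
    labeled-line VP distance (sum over matched channels) from each test
    response to every training response and votes among the nearest
    ``n_neighbors``.
    """

    def __init__(
        self,
        n_neighbors: int = 5,
        q: float = DEFAULT_Q_PER_MS,
        window_ms: tuple[float, float] | None = None,
    ):
        self.n_neighbors = n_neighbors
        self.q = q
        self.window_ms = window_ms

    def fit(self, X: Sequence[PopulationResponse], y: Sequence) -> "TemporalCodeClassifier":
        self.X_train_ = list(X)
        self.y_train_ = np.asarray(y)
        self.classes_ = np.unique(self.y_train_)
        return self

    def _distances(self, X: Sequence[PopulationResponse]) -> np.ndarray:
        window = self.window_ms or (0.0, float(self.X_train_[0].duration_ms))
        D = np.zeros((len(X), len(self.X_train_)))
        for i, r in enumerate(X):
            for j, s in enumerate(self.X_train_):
                D[i, j] = sum(
                    vp_distance(
                        windowed_times(a, window), windowed_times(b, window), self.q
                    )
                    for a, b in zip(r.trains, s.trains)
                )
        return D

    def predict(self, X: Sequence[PopulationResponse]) -> np.ndarray:
        check_is_fitted(self, "X_train_")
        return _knn_predict(self._distances(X), self.y_train_, self.n_neighbors)
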