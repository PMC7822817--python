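"""Decoding front-ends: rate code (spike counts) and temporal code (VP distance).

Rate coding summarizes each trial by windowed per-channel spike counts,
optionally compressed to three principal components.  Temporal coding
compares trials by the Victor-Purpura (VP) spike-train metric: the minimal
cost of editing one train into the other with insertions/deletions (cost 1)
and shifts (cost q per ms).  Small q ignores timing (the VP distance tends
to the absolute count difference); large q only credits near-coincident
spikes.  Population-level distances sum the per-channel (labeled-line)
distances, since afferents are physically distinct fibers.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .encoder import PopulationResponse, SpikeTrain

__all__ = [
    "DEFAULT_Q_PER_MS",
    "spike_count_features",
    "vp_distance",
    "population_vp_matrix",
    "pca_reduce",
    "windowed_times",
]

#: Default VP cost parameter (1/ms): a 20 ms coincidence window, mid-range
#: temporal precision for 2.5 s trials.
DEFAULT_Q_PER_MS = 0.05


def _vp_dp_python(t1: np.ndarray, t2: np.ndarray, q: float) -> float:
    n, m = len(t1), len(t2)
    G = np.empty((n + 1, m + 1))
    G[:, 0] = np.arange(n + 1)
    G[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            G[i, j] = min(
                G[i - 1, j] + 1.0,
                G[i, j - 1] + 1.0,
                G[i - 1, j - 1] + q * abs(t1[i - 1] - t2[j - 1]),
            )
    return float(G[n, m])


try:  # numba accelerates the O(n*m) DP; the pure-python path is the fallback
    from numba import njit

    _vp_dp = njit(cache=False)(_vp_dp_python)
except ImportError:  # pragma: no cover
    _vp_dp = _vp_dp_python


def vp_distance(
    t1: SpikeTrain | np.ndarray | Sequence[float],
    t2: SpikeTrain | np.ndarray | Sequence[float],
    q: float = DEFAULT_Q_PER_MS,
) -> float:
    """Victor-Purpura distance between two sorted spike trains.

    Exact minimal edit cost by dynamic programming: ``G[i, j]`` is the cost
    of transforming the first ``i`` spikes of one train into the first ``j``
    of the other, with moves delete (+1), insert (+1) or shift
    (+q*|t1_i - t2_j|).  A metric for every q >= 0 (a pseudometric at q=0).
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    a = np.asarray(t1.times_ms if isinstance(t1, SpikeTrain) else t1, dtype=float)
    b = np.asarray(t2.times_ms if isinstance(t2, SpikeTrain) else t2, dtype=float)
    for x in (a, b):
        if x.size > 1 and np.any(np.diff(x) <= 0):
            raise ValueError("spike trains must be strictly increasing")
    if a.size == 0 or b.size == 0:
        return float(a.size + b.size)
    return float(_vp_dp(a, b, float(q)))


def windowed_times(train: SpikeTrain, window_ms: tuple[float, float]) -> np.ndarray:
    """Spike times falling inside the closed window [start, end]."""
    lo, hi = window_ms
    t = train.times_ms
    return t[(t >= lo) & (t <= hi)]


def spike_count_features(
    responses: Sequence[PopulationResponse],
    window_ms: tuple[float, float] = (0.0, 500.0),
) -> np.ndarray:
    """(n_trials, n_channels) matrix of spike counts in [start, end].

    Windows are measured from contact onset (trial time zero).  Counts are
    cumulative in the window length, the basic rate-code feature.
    """
    lo, hi = window_ms
    if hi < lo:
        raise ValueError("window end must not precede window start")
    if not responses:
        raise ValueError("responses must be non-empty")
    n_ch = len(responses[0].trains)
    X = np.zeros((len(responses), n_ch), dtype=float)
    for i, resp in enumerate(responses):
        if len(resp.trains) != n_ch:
            raise ValueError("all responses must share the channel layout")
        for j, train in enumerate(resp.trains):
            X[i, j] = len(windowed_times(train, (lo, hi)))
    return X


def population_vp_matrix(
    responses: Sequence[PopulationResponse],
    q: float = DEFAULT_Q_PER_MS,
    window_ms: tuple[float, float] | None = None,
) -> np.ndarray:
    """Pairwise trial distances: labeled-line sum of per-channel VP distances.

    Channels are matched one-to-one across trials (no spike exchange between
    physically distinct afferents) and their VP distances added.  Returns a
    symmetric (n_trials, n_trials) matrix with zero diagonal.
    """
    n = len(responses)
    n_ch = len(responses[0].trains)
    for r in responses:
        if len(r.trains) != n_ch:
            raise ValueError("all responses must share the channel layout")
    if window_ms is None:
        window_ms = (0.0, float(max(r.duration_ms for r in responses)))
    trains = [
        [np.asarray(windowed_times(t, window_ms), dtype=float) for t in r.trains]
        for r in responses
    ]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            total = 0.0
            for ch in range(n_ch):
                a, b = trains[i][ch], trains[j][ch]
                if a.size == 0 or b.size == 0:
                    total += a.size + b.size
                else:
                    total += _vp_dp(a, b, float(q))
            D[i, j] = D[j, i] = total
    return D


def pca_reduce(
    features: np.ndarray,
    n_components: int = 3,
    fit_on: np.ndarray | None = None,
) -> np.ndarray:
    """Project features onto the top principal axes.

    The projection is fitted on ``fit_on`` when given (the training split —
    held-out trials must not influence the axes) and applied to
    ``features``.  Degenerate all-identical features are flagged.
    """
    fit_data = features if fit_on is None else fit_on
    if np.allclose(fit_data, fit_data[0]):
        warnings.warn("degenerate features: all rows identical; PCA is meaningless")
    k = min(n_components, fit_data.shape[0], fit_data.shape[1])
    pca = PCA(n_components=k)
    pca.fit(fit_data)
    return pca.transform(features)
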