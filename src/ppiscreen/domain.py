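"""Applicability domain by Euclidean nearest-neighbor distance.

A QSAR prediction is only trustworthy for queries that resemble the training
chemistry.  The domain model computes, for every training compound, the
Euclidean distance to its nearest training neighbor (self excluded) and
forms the threshold ``mean + Z * sd`` of those distances (Z = 0.5 by
default).  A query whose nearest-training-neighbor distance is *strictly
greater* than the threshold is flagged unreliable; a distance exactly at the
threshold is still reliable.

Distances are computed in the same normalized, variance-filtered descriptor
space the classifiers use.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["ApplicabilityDomain"]


class ApplicabilityDomain(BaseEstimator):
    """Nearest-neighbor distance applicability domain.

    Parameters
    ----------
    z : float, default=0.5
        Multiplier on the standard deviation of within-training
        nearest-neighbor distances.

    Attributes
    ----------
    d_mean_, d_sigma_ : float
        Mean and (population) standard deviation of the training
        nearest-neighbor distances.
    threshold_ : float
        ``d_mean_ + z * d_sigma_``.
    """

    def __init__(self, z: float = 0.5):
        self.z = z

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training compounds")
        nn = NearestNeighbors(n_neighbors=2).fit(X)
        dist, _ = nn.kneighbors(X)
        d = dist[:, 1]  # column 0 is the self-distance (0)
        self._nn_index_ = nn
        self.train_nn_distances_ = d
        self.d_mean_ = float(d.mean())
        self.d_sigma_ = float(d.std())
        self.threshold_ = self.d_mean_ + self.z * self.d_sigma_
        return self

    def distances(self, X) -> np.ndarray:
        """Euclidean distance from each query to its nearest training compound."""
        check_is_fitted(self)
        X = validate_data(self, X, dtype=float, reset=False)
        dist, _ = self._nn_index_.kneighbors(X, n_neighbors=1)
        return dist[:, 0]

    def predict(self, X) -> np.ndarray:
        """Boolean reliability per query: True iff distance <= threshold."""
        return self.distances(X) <= self.threshold_

    def assess(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(distances, reliable) for a batch of queries."""
        d = self.distances(X)
        return d, d <= self.threshold_
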