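"""Fuzzy c-means clustering and cluster-stratified train/test splitting.

Before modeling, the labeled compound set is softly clustered in descriptor
space (fuzzy c-means, 5 clusters by default) and each cluster is split
80:20, so the held-out test set covers the same regions of chemical space as
the training set rather than a random slice of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, check_random_state, validate_data

logger = logging.getLogger(__name__)

__all__ = ["FuzzyCMeans", "SplitResult", "stratified_cluster_split"]


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering (Bezdek's alternating optimization).

    Each point holds a membership weight in every cluster; the weights are
    non-negative and sum to 1 per point.  Updates alternate between

    - centroids: membership^m-weighted means of the points, and
    - memberships: ``u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1))``

    until the largest centroid shift drops below ``tol`` or ``max_iter`` is
    reached.  The objective ``J = sum_ij u_ij^m d_ij^2`` is non-increasing
    across iterations and is recorded in ``objective_history_``.

    Parameters
    ----------
    n_clusters : int, default=5
    m : float, default=2.0
        Fuzziness exponent; must be > 1 (m -> 1 recovers hard k-means).
    tol : float, default=1e-6
        Convergence threshold on the max absolute centroid shift.
    max_iter : int, default=300
    random_state : int, RandomState or None
        Seeds the random membership initialization.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    membership_ : ndarray of shape (n_samples, n_clusters)
    labels_ : hard assignment by maximum membership
    n_iter_ : int
    converged_ : bool
    objective_history_ : list of float
    """

    def __init__(self, n_clusters: int = 5, m: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 300, random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        # squared Euclidean distances, shape (n, c)
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 0.0
        power = 1.0 / (self.m - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** -power
            u = inv / inv.sum(axis=1, keepdims=True)
        # a point coinciding with a centroid belongs to it outright
        rows = zero.any(axis=1)
        if rows.any():
            u[rows] = 0.0
            first = zero[rows].argmax(axis=1)
            u[np.flatnonzero(rows), first] = 1.0
        return u

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        c, n = self.n_clusters, X.shape[0]
        if c < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.m <= 1:
            raise ValueError("fuzziness m must be > 1")
        if n < c:
            raise ValueError(f"n_samples={n} < n_clusters={c}")
        rng = check_random_state(self.random_state)

        if c == 1:
            self.cluster_centers_ = X.mean(axis=0, keepdims=True)
            self.membership_ = np.ones((n, 1))
            self.labels_ = np.zeros(n, dtype=int)
            self.n_iter_, self.converged_ = 0, True
            self.objective_history_ = [float(((X - self.cluster_centers_) ** 2).sum())]
            return self

        u = rng.random_sample((n, c))
        u /= u.sum(axis=1, keepdims=True)
        centers = np.zeros((c, X.shape[1]))
        self.objective_history_ = []
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            um = u ** self.m
            new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
            u = self._memberships(X, new_centers)
            d2 = ((X[:, None, :] - new_centers[None, :, :]) ** 2).sum(axis=2)
            self.objective_history_.append(float((u ** self.m * d2).sum()))
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < self.tol:
                self.converged_ = True
                break
        self.cluster_centers_ = centers
        self.membership_ = u
        self.labels_ = u.argmax(axis=1)
        self.n_iter_ = it
        return self

    def predict(self, X):
        """Hard cluster assignment (max membership) for new points."""
        check_is_fitted(self)
        X = validate_data(self, X, dtype=float, reset=False)
        return self._memberships(X, self.cluster_centers_).argmax(axis=1)

    def soft_predict(self, X):
        """Membership matrix for new points."""
        check_is_fitted(self)
        X = validate_data(self, X, dtype=float, reset=False)
        return self._memberships(X, self.cluster_centers_)


@dataclass
class SplitResult:
    """A cluster-stratified train/test partition of compound ids."""

    train_ids: list[str]
    test_ids: list[str]
    cluster_of: dict[str, int] = field(repr=False)
    train_fraction: float = 0.8


def stratified_cluster_split(labels, ids, train_fraction: float = 0.8,
                             seed: int | None = None) -> SplitResult:
    """Split ids train/test at ``train_fraction`` within each cluster.

    ``labels`` are hard cluster assignments (e.g. ``FuzzyCMeans.labels_``,
    i.e. maximum membership).  The training size per cluster is rounded half
    up.  Deterministic under ``seed``; empty clusters are skipped with a
    warning.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    ids = [str(i) for i in ids]
    labels = np.asarray(labels)
    if len(ids) != len(labels):
        raise ValueError("ids and labels length mismatch")
    rng = np.random.RandomState(seed)
    train: list[str] = []
    test: list[str] = []
    for k in range(int(labels.max()) + 1):
        members = [ids[i] for i in np.flatnonzero(labels == k)]
        if not members:
            logger.warning("cluster %d is empty; skipped", k)
            continue
        order = rng.permutation(len(members))
        n_train = int(np.floor(train_fraction * len(members) + 0.5))  # round half up
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return SplitResult(
        train_ids=train,
        test_ids=test,
        cluster_of={cid: int(k) for cid, k in zip(ids, labels)},
        train_fraction=train_fraction,
    )
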