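"""The consensus QSAR classifier and its validation metrics.

Three member pipelines — gain-ratio ranking into k-NN (k=3), CFS best-first
into 1-NN, and info-gain ranking into a random forest — each vote
active/inactive; the consensus is the majority of the three votes (ties are
impossible with three binary voters).  Validation follows the usual screening
conventions with *active* as the positive class: precision, sensitivity,
specificity and accuracy from a confusion matrix over a held-out test set.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, validate_data

from .feature_selection import CfsSubsetSelector, GainRatioRanker, InfoGainRanker

__all__ = [
    "ConsensusClassifier",
    "ConfusionMatrix",
    "ValidationMetrics",
    "evaluate",
    "metrics_from_confusion",
    "round_half_away",
]

ACTIVE, INACTIVE = "active", "inactive"


class ConsensusClassifier(ClassifierMixin, BaseEstimator):
    """Majority-vote ensemble of three feature-selected classifiers.

    Members (each a selector + classifier sklearn Pipeline):

    1. ``knn``   — gain-ratio top-n ranking -> k-nearest neighbors (k=3),
    2. ``nn``    — CFS best-first subset    -> nearest neighbor (k=1),
    3. ``forest``— info-gain top-n ranking  -> random forest (100 trees).

    Distances are Euclidean, so input should be the prepared (normalized,
    variance-filtered) descriptor matrix.

    Parameters
    ----------
    n_neighbors : int, default=3
        k for the k-NN member (the 1-NN member is always k=1).
    top_n : int, default=30
        Features kept by each ranker.
    n_estimators : int, default=100
        Trees in the random forest.
    cfs_stale_limit : int, default=5
        Best-first stopping patience for the CFS member.
    random_state : int or None
        Seeds the forest; the other members are deterministic.

    Attributes
    ----------
    members_ : dict of name -> fitted Pipeline
    classes_ : ndarray of class labels
    selected_features_ : dict of name -> list of selected column indices
    """

    def __init__(self, n_neighbors: int = 3, top_n: int = 30, n_estimators: int = 100,
                 cfs_stale_limit: int = 5, random_state=None):
        self.n_neighbors = n_neighbors
        self.top_n = top_n
        self.n_estimators = n_estimators
        self.cfs_stale_limit = cfs_stale_limit
        self.random_state = random_state

    def _member_templates(self):
        return {
            "knn": Pipeline([
                ("select", GainRatioRanker(top_n=self.top_n)),
                ("clf", KNeighborsClassifier(n_neighbors=self.n_neighbors)),
            ]),
            "nn": Pipeline([
                ("select", CfsSubsetSelector(stale_limit=self.cfs_stale_limit)),
                ("clf", KNeighborsClassifier(n_neighbors=1)),
            ]),
            "forest": Pipeline([
                ("select", InfoGainRanker(top_n=self.top_n)),
                ("clf", RandomForestClassifier(n_estimators=self.n_estimators,
                                               random_state=self.random_state)),
            ]),
        }

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain fewer than 2 classes")
        self.members_ = {}
        self.selected_features_ = {}
        for name, pipe in self._member_templates().items():
            fitted = clone(pipe).fit(X, y)
            self.members_[name] = fitted
            mask = fitted.named_steps["select"].get_support()
            self.selected_features_[name] = list(np.flatnonzero(mask))
        return self

    def predict_votes(self, X):
        """Per-member predictions, shape (n_samples, 3), member order knn/nn/forest."""
        check_is_fitted(self)
        X = validate_data(self, X, dtype=float, reset=False)
        return np.column_stack([self.members_[m].predict(X) for m in ("knn", "nn", "forest")])

    def predict(self, X):
        votes = self.predict_votes(X)
        pos = self.classes_[-1]
        n_pos = (votes == pos).sum(axis=1)
        # 3 binary voters: majority is well defined, never a tie
        assert set(np.unique(n_pos)) <= {0, 1, 2, 3}
        return np.where(n_pos >= 2, pos, self.classes_[0])


@dataclass
class ConfusionMatrix:
    """2x2 confusion counts with *active* as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class ValidationMetrics:
    """Precision, sensitivity, specificity, accuracy (None when undefined)."""

    precision: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None

    def rounded(self, ndigits: int = 3) -> "ValidationMetrics":
        r = lambda v: None if v is None else round_half_away(v, ndigits)
        return ValidationMetrics(r(self.precision), r(self.sensitivity),
                                 r(self.specificity), r(self.accuracy))


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed QSAR tables)."""
    if x < 0:
        return -round_half_away(-x, ndigits)
    q = Fraction(x).limit_denominator(10 ** 12) * 10 ** ndigits
    n = q.numerator // q.denominator
    if q - n >= Fraction(1, 2):
        n += 1
    return n / 10 ** ndigits


def evaluate(model, X_test, y_test, positive: str = ACTIVE) -> ConfusionMatrix:
    """Confusion matrix of a fitted classifier over a test set."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X_test)
    tp = int(((pred == positive) & (y_test == positive)).sum())
    fn = int(((pred != positive) & (y_test == positive)).sum())
    fp = int(((pred == positive) & (y_test != positive)).sum())
    tn = int(((pred != positive) & (y_test != positive)).sum())
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def metrics_from_confusion(cm: ConfusionMatrix) -> ValidationMetrics:
    """Precision, sensitivity, specificity, accuracy from 2x2 counts.

    A metric with a zero denominator is reported as None (undefined), not 0.
    """
    ratio = lambda num, den: None if den == 0 else num / den
    return ValidationMetrics(
        precision=ratio(cm.tp, cm.tp + cm.fp),
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        accuracy=ratio(cm.tp + cm.tn, cm.n),
    )
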