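"""Entropy-based feature selection: info-gain / gain-ratio rankers and CFS.

The three classifier pipelines each get their own selector, in the Weka
tradition:

- gain-ratio ranking (top-n) for the k-NN member,
- correlation-based feature subset selection (CFS) with best-first search
  for the 1-NN member,
- information-gain ranking (top-n) for the random-forest member.

All measures operate on discretized columns.  Continuous descriptors are cut
by Fayyad-Irani MDL-based binary splitting; when MDL accepts no cut the
column falls back to 10 equal-frequency bins.
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "FeatureSelectionResult",
    "mdl_discretize",
    "entropy",
    "info_gain",
    "gain_ratio",
    "symmetric_uncertainty",
    "cfs_merit",
    "rank_features",
    "select_cfs",
    "GainRatioRanker",
    "InfoGainRanker",
    "CfsSubsetSelector",
]


# ---------------------------------------------------------------------------
# entropy primitives (bits)

def entropy(labels) -> float:
    """Shannon entropy in bits of a discrete label vector."""
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    nx, ny = xi.max() + 1, yi.max() + 1
    return np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)


def _entropy_from_counts(counts: np.ndarray) -> float:
    c = counts[counts > 0].astype(float)
    p = c / c.sum()
    return float(-(p * np.log2(p)).sum())


def info_gain(x_disc, y) -> float:
    """IG(y; x) = H(y) - H(y|x) for discrete x."""
    joint = _joint_counts(np.asarray(x_disc), np.asarray(y))
    n = joint.sum()
    h_y = _entropy_from_counts(joint.sum(axis=0))
    h_y_given_x = 0.0
    for row in joint:
        nr = row.sum()
        if nr:
            h_y_given_x += (nr / n) * _entropy_from_counts(row)
    return h_y - h_y_given_x


def gain_ratio(x_disc, y) -> float:
    """IG normalized by the feature's own entropy; 0 when H(x) = 0."""
    h_x = entropy(x_disc)
    if h_x == 0.0:
        return 0.0
    return info_gain(x_disc, y) / h_x


def symmetric_uncertainty(x_disc, y_disc) -> float:
    """SU = 2 IG / (H(x) + H(y)); 0 when both entropies vanish."""
    h_x, h_y = entropy(x_disc), entropy(y_disc)
    if h_x + h_y == 0.0:
        return 0.0
    return 2.0 * info_gain(x_disc, y_disc) / (h_x + h_y)


# ---------------------------------------------------------------------------
# discretization

def _class_counts(y: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, minlength=n_classes)


def _ent(counts: np.ndarray) -> float:
    return _entropy_from_counts(counts)


def _mdl_cuts(x: np.ndarray, y: np.ndarray, n_classes: int, lo: int, hi: int,
              cuts: list[float]) -> None:
    """Recursive MDL-accepted binary splits of x[lo:hi] (x sorted)."""
    n = hi - lo
    if n < 2:
        return
    xs, ys = x[lo:hi], y[lo:hi]
    total = _class_counts(ys, n_classes)
    h_s = _ent(total)
    # candidate cut points: boundaries between distinct adjacent values
    best = None
    left = np.zeros(n_classes, dtype=int)
    for i in range(n - 1):
        left[ys[i]] += 1
        if xs[i] == xs[i + 1]:
            continue
        right = total - left
        nl = i + 1
        e = (nl * _ent(left) + (n - nl) * _ent(right)) / n
        if best is None or e < best[0]:
            best = (e, i, _ent(left), _ent(right), left.copy(), right.copy())
    if best is None:
        return
    e_split, i, h1, h2, c1, c2 = best
    gain = h_s - e_split
    k = int((total > 0).sum())
    k1 = int((c1 > 0).sum())
    k2 = int((c2 > 0).sum())
    delta = np.log2(3.0 ** k - 2.0) - (k * h_s - k1 * h1 - k2 * h2)
    if gain <= (np.log2(n - 1) + delta) / n:
        return
    cut = (xs[i] + xs[i + 1]) / 2.0
    _mdl_cuts(x, y, n_classes, lo, lo + i + 1, cuts)
    cuts.append(cut)
    _mdl_cuts(x, y, n_classes, lo + i + 1, hi, cuts)


def mdl_discretize(x, y, fallback_bins: int = 10) -> np.ndarray:
    """Discretize a numeric column by Fayyad-Irani MDL splitting.

    Returns integer bin codes.  When MDL accepts no cut at the top level the
    column is cut into ``fallback_bins`` equal-frequency bins instead.
    """
    x = np.asarray(x, dtype=float)
    y_codes = np.unique(y, return_inverse=True)[1]
    order = np.argsort(x, kind="mergesort")
    cuts: list[float] = []
    _mdl_cuts(x[order], y_codes[order], int(y_codes.max()) + 1, 0, len(x), cuts)
    if not cuts:
        qs = np.unique(np.quantile(x, np.linspace(0, 1, fallback_bins + 1)[1:-1]))
        cuts = list(qs)
    return np.searchsorted(np.sort(cuts), x, side="right")


def _discretize_matrix(X: np.ndarray, y) -> np.ndarray:
    return np.column_stack([mdl_discretize(X[:, j], y) for j in range(X.shape[1])])


# ---------------------------------------------------------------------------
# ranking and CFS

@dataclass
class FeatureSelectionResult:
    """Selected descriptor names with the scores that chose them."""

    method: str
    selected: list[str]
    scores: dict = field(default_factory=dict)


def rank_features(X, y, feature_names=None, measure: str = "info_gain",
                  top_n: int = 30) -> FeatureSelectionResult:
    """Rank features by info gain or gain ratio on MDL-discretized columns.

    Descending stable sort; the top ``top_n`` names are returned.  With a
    single-class ``y`` every score is 0 and a warning is issued.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if top_n > X.shape[1]:
        raise ValueError("top_n exceeds the number of features")
    score_fn = {"info_gain": info_gain, "gain_ratio": gain_ratio}[measure]
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: all feature scores are 0")
        scores = np.zeros(X.shape[1])
    else:
        Xd = _discretize_matrix(X, y)
        scores = np.array([score_fn(Xd[:, j], y) for j in range(X.shape[1])])
    order = np.argsort(-scores, kind="mergesort")  # stable: ties keep column order
    sel = [feature_names[j] for j in order[:top_n]]
    return FeatureSelectionResult(
        method=f"{measure}_ranker",
        selected=sel,
        scores={feature_names[j]: float(scores[j]) for j in range(X.shape[1])},
    )


def cfs_merit(subset, su_cf: np.ndarray, su_ff) -> float:
    """CFS subset merit ``k r_cf / sqrt(k + k(k-1) r_ff)``.

    ``r_cf`` is the mean feature-class symmetric uncertainty over the subset
    and ``r_ff`` the mean pairwise feature-feature SU; a single-feature
    subset's merit reduces to its own class correlation.
    """
    subset = list(subset)
    k = len(subset)
    if k == 0:
        return 0.0
    r_cf = float(np.mean([su_cf[j] for j in subset]))
    if k == 1:
        return r_cf
    pairs = list(itertools.combinations(subset, 2))
    r_ff = float(np.mean([su_ff(a, b) for a, b in pairs]))
    denom = np.sqrt(k + k * (k - 1) * r_ff)
    return k * r_cf / denom if denom > 0 else 0.0


def select_cfs(X, y, feature_names=None, stale_limit: int = 5) -> FeatureSelectionResult:
    """Correlation-based feature subset selection with best-first search.

    Forward best-first over subsets, expanding the most promising open
    subset by one feature at a time and stopping after ``stale_limit``
    consecutive expansions that fail to improve the best merit seen.
    Correlations are symmetric uncertainties on MDL-discretized columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    Xd = _discretize_matrix(X, y)
    su_cf = np.array([symmetric_uncertainty(Xd[:, j], y) for j in range(p)])
    ff_cache: dict[tuple[int, int], float] = {}

    def su_ff(a: int, b: int) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in ff_cache:
            ff_cache[key] = symmetric_uncertainty(Xd[:, key[0]], Xd[:, key[1]])
        return ff_cache[key]

    evaluated: dict[frozenset, float] = {frozenset(): 0.0}
    best_subset, best_merit = frozenset(), 0.0
    # max-heap on merit; tie-break on insertion order for determinism
    counter = itertools.count()
    open_heap = [(-0.0, next(counter), frozenset())]
    stale = 0
    while open_heap and stale < stale_limit:
        _, _, current = heapq.heappop(open_heap)
        improved = False
        for j in range(p):
            if j in current:
                continue
            cand = current | {j}
            if cand in evaluated:
                continue
            merit = cfs_merit(cand, su_cf, su_ff)
            evaluated[cand] = merit
            heapq.heappush(open_heap, (-merit, next(counter), cand))
            if merit > best_merit + 1e-12:
                best_subset, best_merit = cand, merit
                improved = True
        if improved:
            stale = 0
        else:
            stale += 1
    sel_idx = sorted(best_subset)
    return FeatureSelectionResult(
        method="cfs_best_first",
        selected=[feature_names[j] for j in sel_idx],
        scores={"merit": best_merit},
    )


# ---------------------------------------------------------------------------
# sklearn transformer fronts

class _BaseEntropySelector(SelectorMixin, BaseEstimator):
    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_mask_

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y)
        result = self._select(X, y)
        names = [f"x{j}" for j in range(X.shape[1])]
        chosen = set(result.selected)
        self.support_mask_ = np.array([n in chosen for n in names])
        self.selection_ = result
        return self


class GainRatioRanker(_BaseEntropySelector):
    """Keep the ``top_n`` features by gain ratio (feeds the k-NN member)."""

    def __init__(self, top_n: int = 30):
        self.top_n = top_n

    def _select(self, X, y):
        return rank_features(X, y, measure="gain_ratio", top_n=min(self.top_n, X.shape[1]))


class InfoGainRanker(_BaseEntropySelector):
    """Keep the ``top_n`` features by information gain (feeds the forest)."""

    def __init__(self, top_n: int = 30):
        self.top_n = top_n

    def _select(self, X, y):
        return rank_features(X, y, measure="info_gain", top_n=min(self.top_n, X.shape[1]))


class CfsSubsetSelector(_BaseEntropySelector):
    """CFS best-first subset selection (feeds the 1-NN member)."""

    def __init__(self, stale_limit: int = 5):
        self.stale_limit = stale_limit

    def _select(self, X, y):
        return select_cfs(X, y, stale_limit=self.stale_limit)
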