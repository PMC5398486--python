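import itertools

import numpy as np
import pytest

from ppiscreen.feature_selection import (CfsSubsetSelector, GainRatioRanker,
                                         InfoGainRanker, cfs_merit, entropy,
                                         gain_ratio, info_gain, mdl_discretize,
                                         rank_features, select_cfs,
                                         symmetric_uncertainty,
                                         _discretize_matrix)


class TestEntropyMeasures:
    def test_feature_identical_to_labels_gains_full_entropy(self):
        y = np.array([0, 1] * 40)
        assert info_gain(y, y) == pytest.approx(entropy(y)) == pytest.approx(1.0)

    def test_constant_feature_gains_nothing(self):
        y = np.array([0, 1] * 10)
        assert info_gain(np.zeros(20), y) == pytest.approx(0.0)
        assert gain_ratio(np.zeros(20), y) == 0.0  # H(X)=0 guard, not a NaN

    def test_info_gain_matches_entropy_arithmetic(self):
        """Joint counts [[30,10],[10,30]] on balanced y of n=80.

        Direct arithmetic: H(y) = 1 bit; each x-bin holds 40 samples split
        30/10, so H(y|x) = H(0.75) = 0.811278...; IG = 0.188722 bits.
        """
        x = np.repeat([0, 0, 1, 1], [30, 10, 10, 30])
        y = np.repeat([0, 1, 0, 1], [30, 10, 10, 30])
        h_cond = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert info_gain(x, y) == pytest.approx(1.0 - h_cond)
        assert info_gain(x, y) == pytest.approx(0.1887219, abs=1e-6)

    def test_symmetric_uncertainty_bounds_and_symmetry(self, rng):
        x = rng.integers(0, 3, 200)
        y = rng.integers(0, 2, 200)
        su = symmetric_uncertainty(x, y)
        assert 0.0 <= su <= 1.0
        assert su == pytest.approx(symmetric_uncertainty(y, x))
        assert symmetric_uncertainty(x, x) == pytest.approx(1.0)


class TestDiscretization:
    def test_informative_column_gets_the_right_cut(self):
        y = np.array([0] * 50 + [1] * 50)
        x = np.concatenate([np.linspace(0, 1, 50), np.linspace(2, 3, 50)])
        codes = mdl_discretize(x, y)
        assert len(np.unique(codes)) == 2
        assert info_gain(codes, y) == pytest.approx(1.0)

    def test_uninformative_column_falls_back_to_equal_frequency(self, rng):
        x = rng.normal(size=300)
        y = rng.integers(0, 2, 300)
        codes = mdl_discretize(x, y, fallback_bins=10)
        assert len(np.unique(codes)) == 10


class TestRankers:
    def test_informative_features_ranked_first(self, rng):
        y = rng.integers(0, 2, 200)
        X = rng.normal(size=(200, 10))
        X[:, 3] += 3.0 * y
        X[:, 7] -= 3.0 * y
        for measure in ("info_gain", "gain_ratio"):
            res = rank_features(X, y, measure=measure, top_n=2)
            assert set(res.selected) == {"x3", "x7"}

    def test_stable_descending_order(self):
        y = np.array([0, 1] * 30)
        X = np.column_stack([y, np.zeros(60), y])  # x0 and x2 tie, x1 scores 0
        res = rank_features(X, y, measure="info_gain", top_n=3)
        assert res.selected == ["x0", "x2", "x1"]

    def test_single_class_scores_zero_with_warning(self):
        with pytest.warns(UserWarning, match="single-class"):
            res = rank_features(np.random.default_rng(0).normal(size=(30, 4)),
                                np.zeros(30), top_n=2)
        assert all(v == 0.0 for v in res.scores.values())

    def test_transformer_front_selects_same_columns(self, rng):
        y = rng.integers(0, 2, 150)
        X = rng.normal(size=(150, 8))
        X[:, 5] += 4.0 * y
        sel = InfoGainRanker(top_n=1).fit(X, y)
        assert list(np.flatnonzero(sel.get_support())) == [5]
        assert GainRatioRanker(top_n=1).fit(X, y).transform(X).shape == (150, 1)


class TestCfs:
    @pytest.fixture(scope="class")
    def planted(self):
        rng = np.random.default_rng(7)
        n = 200
        y = rng.integers(0, 2, n)
        x0 = y + rng.normal(0, 0.3, n)
        x1 = -y.astype(float) + rng.normal(0, 0.3, n)
        X = np.column_stack([x0, x1, x0, x1, rng.normal(size=(n, 4))])  # exact dups at 2,3
        return X, y

    def test_single_feature_merit_reduces_to_class_correlation(self, planted):
        X, y = planted
        Xd = _discretize_matrix(X, y)
        su_cf = np.array([symmetric_uncertainty(Xd[:, j], y) for j in range(X.shape[1])])
        su_ff = lambda a, b: symmetric_uncertainty(Xd[:, a], Xd[:, b])
        assert cfs_merit([0], su_cf, su_ff) == pytest.approx(su_cf[0])

    def test_best_first_matches_exhaustive_optimum(self, planted):
        X, y = planted
        res = select_cfs(X, y)
        Xd = _discretize_matrix(X, y)
        p = X.shape[1]
        su_cf = np.array([symmetric_uncertainty(Xd[:, j], y) for j in range(p)])
        cache = {}

        def su_ff(a, b):
            k = (min(a, b), max(a, b))
            if k not in cache:
                cache[k] = symmetric_uncertainty(Xd[:, k[0]], Xd[:, k[1]])
            return cache[k]

        best_merit = max(
            cfs_merit(sub, su_cf, su_ff)
            for r in range(1, p + 1)
            for sub in itertools.combinations(range(p), r)
        )
        assert res.scores["merit"] == pytest.approx(best_merit)

    def test_adding_exact_duplicate_never_increases_merit(self, planted):
        X, y = planted
        Xd = _discretize_matrix(X, y)
        su_cf = np.array([symmetric_uncertainty(Xd[:, j], y) for j in range(X.shape[1])])
        su_ff = lambda a, b: symmetric_uncertainty(Xd[:, a], Xd[:, b])
        # columns 2 and 3 are exact copies of 0 and 1; for subsets of signal
        # features a duplicate adds redundancy without new class information,
        # so the merit cannot rise (it may rise for subsets padded with noise
        # columns, where a duplicate legitimately lifts the mean correlation)
        for sub in ([0], [1], [0, 1]):
            base = cfs_merit(sub, su_cf, su_ff)
            for dup, orig in ((2, 0), (3, 1)):
                if orig in sub and dup not in sub:
                    assert cfs_merit(sub + [dup], su_cf, su_ff) <= base + 1e-12
        # in particular the best-first optimum contains no duplicate pair
        selected = {int(n[1:]) for n in select_cfs(X, y).selected}
        assert not ({0, 2} <= selected or {1, 3} <= selected)

    def test_selector_front(self, planted):
        X, y = planted
        sel = CfsSubsetSelector().fit(X, y)
        chosen = set(np.flatnonzero(sel.get_support()))
        assert chosen & {0, 1, 2, 3}          # signal columns found
        assert not chosen & {4, 5, 6, 7}      # pure-noise columns excluded
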