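import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from echoclick.stats import (
    broken_stick,
    centroid_distances,
    group_dispersion,
    pca_broken_stick,
    permanova,
    permdisp,
    zscore_and_distance,
)


def _table(X, cols=("a", "b")):
    return pd.DataFrame(X, columns=list(cols))


class TestZscoreDistance:
    def test_identical_rows_distance_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        d = zscore_and_distance(_table(X), ("a", "b"))
        assert d[0, 1] == pytest.approx(0.0)

    def test_columns_standardized(self, rng):
        X = rng.normal(5, 3, size=(40, 3))
        t = _table(X, ("a", "b", "c"))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        expect = squareform(pdist(Z))
        got = zscore_and_distance(t, ("a", "b", "c"))
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_three_point_hand_computation(self):
        # column a: 0, 1, 2 -> z = -1, 0, 1; column b constant-free: 0, 2, 4 -> z = -1, 0, 1
        X = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0]])
        d = zscore_and_distance(_table(X), ("a", "b"))
        assert d[0, 1] == pytest.approx(np.sqrt(2.0))
        assert d[0, 2] == pytest.approx(2 * np.sqrt(2.0))

    def test_zero_variance_column_rejected(self):
        X = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_and_distance(_table(X), ("a", "b"))


def _exhaustive_permanova_p(dist, labels):
    """Brute-force permutation p over all distinct label arrangements."""
    from echoclick.stats import _group_indices, _pseudo_f

    n = len(labels)
    d2 = dist**2
    f_obs = _pseudo_f(d2, _group_indices(np.asarray(labels)), n)
    f_all = []
    for perm in set(itertools.permutations(labels)):
        f_all.append(_pseudo_f(d2, _group_indices(np.asarray(perm)), n))
    return np.mean([f >= f_obs - 1e-12 for f in f_all]), f_obs


class TestPermanova:
    def test_identical_groups_give_zero_f(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        X = np.vstack([pts, pts])
        dist = squareform(pdist(X))
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = permanova(dist, labels, n_perm=199, rng=np.random.default_rng(0))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_matches_exhaustive_enumeration(self, rng):
        X = rng.normal(size=(6, 2))
        X[3:] += 1.5
        dist = squareform(pdist(X))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        p_exact, f_obs = _exhaustive_permanova_p(dist, labels)
        res = permanova(dist, labels, n_perm=4999, rng=np.random.default_rng(1))
        assert res.statistic == pytest.approx(f_obs)
        assert res.p_value == pytest.approx(p_exact, abs=0.03)

    def test_minimum_p_with_999_permutations(self, small_event_table):
        dist = zscore_and_distance(small_event_table)
        res = permanova(dist, small_event_table["species"].to_numpy(), n_perm=999,
                        rng=np.random.default_rng(2))
        assert res.p_value == pytest.approx(0.001)
        assert res.df_between == 1 and res.df_within == 79

    def test_single_group_rejected(self):
        dist = np.zeros((3, 3))
        with pytest.raises(ValueError):
            permanova(dist, np.array(["a", "a", "a"]))

    def test_invariances(self, rng):
        X = rng.normal(size=(10, 3))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        f0 = permanova(squareform(pdist(X)), labels, n_perm=9, rng=np.random.default_rng(0)).statistic
        order = rng.permutation(10)
        f1 = permanova(squareform(pdist(X[order])), labels[order], n_perm=9,
                       rng=np.random.default_rng(0)).statistic
        f2 = permanova(squareform(pdist(X + 7.5)), labels, n_perm=9,
                       rng=np.random.default_rng(0)).statistic
        assert f1 == pytest.approx(f0)
        assert f2 == pytest.approx(f0)

    def test_null_p_values_are_valid(self, rng):
        """Under label exchangeability the test is at most nominal size."""
        hits = 0
        reps = 200
        for _ in range(reps):
            X = rng.normal(size=(8, 2))
            labels = np.array(["a"] * 4 + ["b"] * 4)
            res = permanova(squareform(pdist(X)), labels, n_perm=99, rng=rng)
            hits += res.p_value <= 0.05
        assert hits / reps <= 0.10


class TestPermdisp:
    def test_mirror_groups_equal_dispersion(self):
        pts = np.array([[1.0, 0.0], [2.0, 1.0], [3.0, -1.0], [0.5, 0.5]])
        X = np.vstack([pts, -pts])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        res = permdisp(squareform(pdist(X)), labels, n_perm=199, rng=np.random.default_rng(0))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.9

    def test_scaling_one_group_increases_f(self, rng):
        A = rng.normal(size=(6, 2))
        B = rng.normal(size=(6, 2))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        f1 = permdisp(squareform(pdist(np.vstack([A, B]))), labels, n_perm=9,
                      rng=np.random.default_rng(0)).statistic
        f2 = permdisp(squareform(pdist(np.vstack([A, 3 * B]))), labels, n_perm=9,
                      rng=np.random.default_rng(0)).statistic
        assert f2 > f1

    def test_matches_exhaustive_enumeration(self, rng):
        from echoclick.stats import _anova_f, _group_indices

        X = rng.normal(size=(7, 2))
        X[4:] *= 2.5
        labels = np.array(["a"] * 4 + ["b"] * 3)
        dist = squareform(pdist(X))
        z = centroid_distances(dist, labels)
        f_obs = _anova_f(z, _group_indices(labels))
        f_all = [
            _anova_f(z, _group_indices(np.asarray(perm)))
            for perm in set(itertools.permutations(labels))
        ]
        p_exact = np.mean([f >= f_obs - 1e-12 for f in f_all])
        res = permdisp(dist, labels, n_perm=4999, rng=np.random.default_rng(3))
        assert res.statistic == pytest.approx(f_obs)
        assert res.p_value == pytest.approx(p_exact, abs=0.03)

    def test_singleton_group_rejected(self):
        dist = squareform(pdist(np.arange(8.0).reshape(4, 2)))
        with pytest.raises(ValueError):
            permdisp(dist, np.array(["a", "b", "b", "b"]))


class TestPcaBrokenStick:
    def test_two_perfectly_correlated_variables(self):
        x = np.linspace(0, 1, 30)
        t = _table(np.c_[x, 2 * x + 1])
        res = pca_broken_stick(t, ("a", "b"))
        assert res.proportions[0] == pytest.approx(1.0)
        assert res.proportions[1] == pytest.approx(0.0, abs=1e-12)
        assert res.significant[0] and not res.significant[1]

    def test_broken_stick_closed_form_p3(self):
        b = broken_stick(3)
        np.testing.assert_allclose(b, [0.6111, 0.2778, 0.1111], atol=1e-4)
        assert b.sum() == pytest.approx(1.0)

    def test_independent_variables_no_significant_pc(self, rng):
        X = rng.normal(size=(4000, 5))
        t = _table(X, tuple("abcde"))
        res = pca_broken_stick(t, tuple("abcde"))
        assert not res.significant.any()

    def test_eigenvalues_sorted_and_proportions_sum(self, small_event_table):
        res = pca_broken_stick(small_event_table)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert res.proportions.sum() == pytest.approx(1.0)
        assert res.broken_stick.sum() == pytest.approx(1.0)

    def test_constant_column_rejected(self):
        t = _table(np.c_[np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError):
            pca_broken_stick(t, ("a", "b"))


class TestSpeciesPattern:
    def test_differentiation_and_dispersion_on_synthetic_data(self, small_event_table):
        dist = zscore_and_distance(small_event_table)
        labels = small_event_table["species"].to_numpy()
        res = permanova(dist, labels, n_perm=999, rng=np.random.default_rng(7))
        assert res.p_value == pytest.approx(0.001)
        disp = group_dispersion(dist, labels)
        assert disp["beluga"] > disp["narwhal"]
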