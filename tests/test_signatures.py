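import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cavesong.features import FeatureTable
from cavesong.signatures import (acoustic_space, compare_groups, geo_cluster,
                                 pdfa, _loo_lda_predict)
from cavesong.signatures import test_assumptions as check_assumptions


def make_table(groups_to_values, feature="f"):
    rows = []
    for g, values in groups_to_values.items():
        for v in np.asarray(values, float).ravel():
            rows.append({feature: v, "group": g})
    df = pd.DataFrame(rows)
    return FeatureTable(df=df, event_type="single", feature_names=[feature])


def matrix_table(X, groups, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["group"] = groups
    return FeatureTable(df=df, event_type="single", feature_names=names)


class TestAssumptions:
    def test_identical_groups_homoscedastic(self, rng):
        x = rng.normal(size=30)
        flags = check_assumptions(make_table({"a": x, "b": x.copy()}), "f")
        assert not flags.heteroscedastic

    def test_zero_variance_degenerate(self, rng):
        flags = check_assumptions(
            make_table({"a": np.ones(10), "b": rng.normal(size=10)}), "f")
        assert flags.heteroscedastic
        assert flags.degenerate is not None

    def test_normality_type_one_error_calibrated(self):
        """Groups drawn from one normal: flags fire at about the alpha rate."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            table = make_table({"a": rng.normal(size=50)})
            # bypass the >=2 group precondition by pairing with a clean group
            table = make_table({"a": rng.normal(size=50),
                                "b": rng.normal(size=50)})
            flags = check_assumptions(table, "f")
            hits += flags.normality_rejected["a"]
        assert 0.02 <= hits / n_rep <= 0.09

    def test_exponential_group_detected(self):
        rng = np.random.default_rng(8)
        hits = sum(
            check_assumptions(
                make_table({"a": rng.exponential(size=100),
                            "b": rng.normal(size=100)}),
                "f").normality_rejected["a"]
            for _ in range(20))
        assert hits >= 19  # power > 0.9


class TestKruskalWallisDunn:
    def test_identical_samples(self):
        cmp = compare_groups(make_table({"a": [1, 2, 3], "b": [1, 2, 3]}), "f",
                             check_assumptions=False)
        assert cmp.h_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == 1.0
        assert cmp.exact

    def test_exact_p_matches_brute_force(self):
        """Exhaustive oracle: recompute H for all 8!/4!4! group labelings
        with scipy and count those at least as extreme."""
        a, b = [1.0, 2.0, 3.0, 4.0], [10.0, 11.0, 12.0, 13.0]
        pooled = np.array(a + b)
        h_obs = stats.kruskal(a, b).statistic
        count = total = 0
        for comb in itertools.combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(comb)] = True
            h = stats.kruskal(pooled[mask], pooled[~mask]).statistic
            total += 1
            count += h >= h_obs - 1e-12
        oracle_p = count / total
        assert oracle_p == pytest.approx(2 / 70)
        cmp = compare_groups(make_table({"a": a, "b": b}), "f",
                             check_assumptions=False)
        assert cmp.exact
        assert cmp.h_statistic == pytest.approx(h_obs)
        assert cmp.p_value == pytest.approx(oracle_p)

    def test_three_group_exact_separated(self):
        table = make_table({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        cmp = compare_groups(table, "f", check_assumptions=False)
        assert cmp.h_statistic == pytest.approx(7.2)
        # 3! fully separated orderings out of 9!/(3!3!3!) labelings
        assert cmp.p_value == pytest.approx(6 / 1680)

    def test_monotone_transform_invariance(self, rng):
        groups = {g: rng.normal(loc=i, size=20) for i, g in enumerate("abc")}
        c1 = compare_groups(make_table(groups), "f", check_assumptions=False)
        c2 = compare_groups(
            make_table({g: np.exp(v) for g, v in groups.items()}), "f",
            check_assumptions=False)
        assert c1.h_statistic == pytest.approx(c2.h_statistic)
        for pair in c1.pairwise:
            assert c1.pairwise[pair] == pytest.approx(c2.pairwise[pair])

    def test_dunn_z_tests_against_hand_computation(self):
        """No ties, 3 groups of 3: mean ranks 2, 5, 8; pooled rank variance
        N(N+1)/12 = 7.5; z_ab = 3/sqrt(5), z_ac = 6/sqrt(5)."""
        table = make_table({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        cmp = compare_groups(table, "f", adjust="none",
                             check_assumptions=False)
        z_ab = 3 / math.sqrt(7.5 * (2 / 3))
        z_ac = 6 / math.sqrt(7.5 * (2 / 3))
        assert cmp.pairwise[("a", "b")] == pytest.approx(
            2 * stats.norm.sf(z_ab), rel=1e-6)
        assert cmp.pairwise[("a", "c")] == pytest.approx(
            2 * stats.norm.sf(z_ac), rel=1e-6)
        bonf = compare_groups(table, "f", adjust="bonferroni",
                              check_assumptions=False)
        assert bonf.pairwise[("a", "c")] == pytest.approx(
            min(1.0, 3 * 2 * stats.norm.sf(z_ac)), rel=1e-6)

    def test_chi2_path_for_larger_samples(self, rng):
        groups = {g: rng.normal(loc=i * 0.3, size=40)
                  for i, g in enumerate("abcd")}
        cmp = compare_groups(make_table(groups), "f", check_assumptions=False)
        assert not cmp.exact
        h, p = stats.kruskal(*groups.values())
        assert cmp.h_statistic == pytest.approx(h)
        assert cmp.p_value == pytest.approx(p)

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_groups(make_table({"a": rng.normal(size=5)}), "f",
                           check_assumptions=False)


class TestAcousticSpace:
    def test_collinear_data_one_axis(self, rng):
        t = rng.normal(size=(100, 1))
        X = np.hstack([t, 2 * t])
        space = acoustic_space(matrix_table(X, ["g"] * 100), n_axes=2)
        assert space.explained_variance[0] == pytest.approx(1.0)

    def test_variance_conservation(self, rng):
        X = rng.normal(size=(80, 4))
        space = acoustic_space(matrix_table(X, ["g"] * 80), n_axes=4)
        Z = (X - X.mean(0)) / X.std(0)
        total = np.var(space.scores[[f"pc{i+1}" for i in range(4)]].to_numpy(),
                       axis=0).sum()
        assert total == pytest.approx(np.var(Z, axis=0).sum())

    def test_scores_zero_mean_and_orthonormal_axes(self, rng):
        X = rng.normal(size=(60, 3))
        space = acoustic_space(matrix_table(X, ["g"] * 60), n_axes=3)
        coords = space.coordinates()
        np.testing.assert_allclose(coords.mean(axis=0), 0, atol=1e-10)
        L = space.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(3), atol=1e-10)
        ev = space.explained_variance
        assert np.all(np.diff(ev) <= 1e-12) and ev.sum() <= 1 + 1e-9

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(50, 3))
        groups = ["a"] * 25 + ["b"] * 25
        s1 = acoustic_space(matrix_table(X, groups))
        perm = rng.permutation(50)
        s2 = acoustic_space(matrix_table(X[perm], list(np.array(groups)[perm])))
        np.testing.assert_allclose(np.abs(s2.loadings.to_numpy()),
                                   np.abs(s1.loadings.to_numpy()), atol=1e-9)

    def test_ellipse_coverage(self):
        rng = np.random.default_rng(9)
        n = 2000
        X = np.vstack([rng.normal(0, 1, size=(n, 2)),
                       rng.normal(4, 1, size=(n, 2))])
        groups = ["a"] * n + ["b"] * n
        space = acoustic_space(matrix_table(X, groups), n_axes=2)
        for g in ("a", "b"):
            pts = space.scores[space.scores["group"] == g][
                ["pc1", "pc2"]].to_numpy()
            cover = space.ellipses[g].contains(pts).mean()
            assert 0.93 <= cover <= 0.97

    def test_constant_column_dropped_with_warning(self, rng):
        X = np.hstack([rng.normal(size=(40, 2)), np.ones((40, 1))])
        with pytest.warns(UserWarning, match="constant"):
            space = acoustic_space(matrix_table(X, ["g"] * 40))
        assert len(space.features) == 2


class TestPDFA:
    def test_perfect_separation(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(20, 2)),
                       rng.normal(10, 1, size=(20, 2))])
        y = ["a"] * 20 + ["b"] * 20
        res = pdfa(X, y, n_permutations=199, seed=1)
        assert res.overall_reclassification == 1.0
        assert res.p_value == pytest.approx(1 / 200)
        assert res.confusion.loc["a", "a"] == 20

    def test_loo_matches_sklearn_oracle(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.model_selection import LeaveOneOut

        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 3, size=60)
        while np.bincount(y, minlength=3).min() < 3:
            y = rng.integers(0, 3, size=60)
        mine, reg = _loo_lda_predict(X, y, 3)
        assert not reg
        ref = np.empty(60, dtype=int)
        for tr, te in LeaveOneOut().split(X):
            model = LinearDiscriminantAnalysis().fit(X[tr], y[tr])
            ref[te] = model.predict(X[te])
        np.testing.assert_array_equal(mine, ref)

    def test_chance_level_on_null(self):
        rng = np.random.default_rng(10)
        n, insignificant = 60, 0
        for rep in range(10):
            X = rng.normal(size=(n, 3))
            y = np.repeat(list("abcd"), n // 4)
            res = pdfa(X, y, n_permutations=99, seed=rep)
            se = math.sqrt(0.25 * 0.75 / n)
            assert abs(res.overall_reclassification - 0.25) <= 4 * se
            insignificant += res.p_value > 0.05
        assert insignificant >= 8

    def test_joint_permutation_equivariance(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(15, 2)),
                       rng.normal(1.5, 1, size=(15, 2))])
        y = np.array(["a"] * 15 + ["b"] * 15)
        r1 = pdfa(X, y, n_permutations=10, seed=0)
        perm = rng.permutation(30)
        r2 = pdfa(X[perm], y[perm], n_permutations=10, seed=0)
        assert r1.overall_reclassification == pytest.approx(
            r2.overall_reclassification)

    def test_small_group_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            pdfa(X, ["a", "a", "a", "b", "b"], n_permutations=9, seed=0)


class TestGeoCluster:
    def _table(self, medians_by_group, n=20, sd=1e-6):
        rng = np.random.default_rng(2)
        rows, groups = [], []
        for g, m in medians_by_group.items():
            rows.append(np.asarray(m) + sd * rng.normal(size=(n, len(m))))
            groups += [g] * n
        X = np.vstack(rows)
        return matrix_table(X, groups)

    def test_two_groups_single_merge(self):
        table = self._table({"a": [0.0, 0.0], "b": [1.0, 1.0]})
        coords = {"a": (-99.0, 22.0), "b": (-98.5, 22.4)}
        geo = geo_cluster(table, coords)
        assert geo.linkage_matrix.shape == (1, 4)
        med = geo.medians
        expect = float(np.linalg.norm(med.loc["a"] - med.loc["b"]))
        assert geo.linkage_matrix[0, 2] == pytest.approx(expect)

    def test_near_groups_merge_first(self):
        table = self._table({"a": [0.0, 0.0], "b": [0.0, 0.1],
                             "c": [10.0, 10.0]})
        coords = {g: (float(i), float(i)) for i, g in enumerate("abc")}
        geo = geo_cluster(table, coords)
        first = geo.linkage_matrix[0]
        assert sorted(first[:2].astype(int)) == [0, 1]  # a and b merge first

    def test_duplicate_medians_zero_height(self):
        table = self._table({"a": [1.0, 2.0], "b": [1.0, 2.0]}, sd=0.0)
        geo = geo_cluster(table, {"a": (0, 0), "b": (1, 1)})
        assert geo.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_newick_round_trips_with_dendropy(self):
        import dendropy

        table = self._table({"a": [0.0, 0.0], "b": [0.0, 0.5],
                             "c": [3.0, 3.0], "d": [3.0, 3.6]})
        coords = {g: (float(i), 0.0) for i, g in enumerate("abcd")}
        geo = geo_cluster(table, coords)
        tree = dendropy.Tree.get(data=geo.newick, schema="newick")
        leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
        assert leaves == ["a", "b", "c", "d"]

    def test_missing_coordinates_rejected(self):
        table = self._table({"a": [0.0, 0.0], "b": [1.0, 1.0]})
        with pytest.raises(KeyError):
            geo_cluster(table, {"a": (0, 0)})
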