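import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from microvar.stats import (
    StatsError,
    betadisper,
    bh_adjust,
    dunn_posthoc,
    kruskal_wallis,
    permanova,
    t_test,
    two_way_anova,
)


def euclid_dm(values):
    x = np.asarray(values, dtype=float)[:, None]
    return DistanceMatrix(squareform(pdist(x)), ids=[f"s{i}" for i in range(len(values))])


def enumeration_p(values, groups):
    """Independent exhaustive-permutation oracle via classical one-way F."""
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)

    def f_stat(labels):
        grand = x.mean()
        ssb = sum(
            (x[labels == lv]).size * (x[labels == lv].mean() - grand) ** 2
            for lv in np.unique(labels)
        )
        ssw = sum(
            ((x[labels == lv] - x[labels == lv].mean()) ** 2).sum()
            for lv in np.unique(labels)
        )
        a, n = np.unique(labels).size, x.size
        return (ssb / (a - 1)) / (ssw / (n - a))

    f_obs = f_stat(g)
    count = total = 0
    for perm in itertools.permutations(range(x.size)):
        count += f_stat(g[list(perm)]) >= f_obs - 1e-12
        total += 1
    return count / total


class TestPermanova:
    def test_pseudo_f_equals_classical_anova_on_fixture(self):
        res = permanova(euclid_dm([0, 1, 10, 11]), ["A", "A", "B", "B"], n_perm="all")
        assert res.statistic == pytest.approx(200.0)
        assert res.p_value == pytest.approx(1 / 3)
        assert res.r_squared == pytest.approx(100 / 101)

    @pytest.mark.parametrize("seed", range(5))
    def test_anova_equivalence_on_random_1d_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=9)
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        res = permanova(euclid_dm(x), groups, n_perm=9, rng=rng)
        f_ref = sps.f_oneway(x[:3], x[3:6], x[6:]).statistic
        assert res.statistic == pytest.approx(f_ref)

    @pytest.mark.parametrize("n,seed", [(6, 0), (7, 1), (8, 2)])
    def test_exhaustive_matches_independent_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        groups = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
        res = permanova(euclid_dm(x), groups, n_perm="all")
        assert res.p_value == pytest.approx(enumeration_p(x, groups))

    def test_statistic_matches_skbio(self, rng):
        tab = rng.random((10, 5)) + 0.01
        D = DistanceMatrix(squareform(pdist(tab, "braycurtis")),
                           ids=[f"s{i}" for i in range(10)])
        groups = ["A"] * 5 + ["B"] * 5
        mine = permanova(D, groups, n_perm=9, rng=rng)
        ref = skbio_permanova(D, grouping=groups, permutations=9)
        assert mine.statistic == pytest.approx(ref["test statistic"])

    def test_permutation_floor(self, rng):
        x = [0, 0.1, 0.2, 10, 10.1, 10.2]
        res = permanova(euclid_dm(x), ["A"] * 3 + ["B"] * 3, n_perm=999, rng=rng)
        assert res.p_value >= 1 / 1000

    def test_degenerate_within_variance(self):
        D = DistanceMatrix(np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                                     [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float),
                           ids=list("abcd"))
        with pytest.warns(UserWarning):
            res = permanova(D, ["A", "A", "B", "B"], n_perm=9)
        assert math.isnan(res.statistic)

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatsError):
            permanova(euclid_dm([1, 2, 3]), ["A", "B"])


class TestBetadisper:
    def test_one_dimensional_reduction(self, rng):
        """On Euclidean 1-D data the dispersion distance is |x - centroid|."""
        x = np.array([0.0, 1.0, 2.0, 10.0, 12.0, 14.0])
        groups = ["A"] * 3 + ["B"] * 3
        _, dist = betadisper(euclid_dm(x), groups, n_perm=49, rng=rng)
        expected = np.abs(x - np.array([1, 1, 1, 12, 12, 12]))
        np.testing.assert_allclose(dist.to_numpy(), expected, atol=1e-9)

    def test_matches_vegan_on_frozen_fixture(self, rng):
        """Distances and F frozen from R vegan::betadisper (type='centroid')
        on this exact non-Euclidean Bray-Curtis matrix."""
        from microvar.diversity import bray_curtis_matrix

        tab = pd.DataFrame(
            [[5, 0, 3, 0, 1, 9], [2, 4, 0, 6, 0, 1],
             [0, 7, 2, 1, 5, 0], [8, 1, 0, 3, 2, 4]],
            columns=[f"s{i}" for i in range(6)],
        )
        D = bray_curtis_matrix(tab)
        res, dist = betadisper(D, ["g1"] * 3 + ["g2"] * 3, n_perm=99, rng=rng)
        vegan_dist = [0.422308662356, 0.458188063793, 0.414274721170,
                      0.372506846759, 0.408560574064, 0.408560574064]
        np.testing.assert_allclose(dist.to_numpy(), vegan_dist, atol=1e-8)
        assert res.statistic == pytest.approx(3.760254, abs=1e-5)

    def test_identical_groups_degenerate(self):
        D = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.warns(UserWarning):
            res, dist = betadisper(D, ["A", "A", "B", "B"], n_perm=9)
        np.testing.assert_allclose(dist.to_numpy(), 0.0)
        assert math.isnan(res.statistic)

    def test_singleton_group_warns(self, rng):
        with pytest.warns(UserWarning):
            _, dist = betadisper(euclid_dm([0, 1, 5]), ["A", "A", "B"],
                                 n_perm=9, rng=rng)
        assert dist.iloc[2] == pytest.approx(0.0)


class TestKruskalWallis:
    def test_hand_fixture(self):
        res = kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert res.statistic == pytest.approx(2.4)

    def test_all_equal_values(self):
        res = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=15).astype(float)  # ties guaranteed
        g = rng.choice(["a", "b", "c"], size=15).tolist()
        if len(set(g)) < 3:
            g[:3] = ["a", "b", "c"]
        mine = kruskal_wallis(x, g)
        ref = sps.kruskal(*[x[np.array(g) == lv] for lv in sorted(set(g))])
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            kruskal_wallis([1, 2], ["a", "a"])


class TestDunn:
    def test_hand_fixture(self):
        res = dunn_posthoc([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert len(res) == 1
        assert abs(res[0].statistic) == pytest.approx(2 / math.sqrt(5 / 3), abs=1e-4)

    def test_identical_groups(self):
        res = dunn_posthoc([3, 3, 3, 3], ["a", "a", "b", "b"])
        assert res[0].statistic == 0.0
        assert res[0].p_value == 1.0

    def test_three_groups_bh_family(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        res = dunn_posthoc(x, ["a", "b", "c"] * 4)
        assert len(res) == 3
        raw = np.array([r.p_value for r in res])
        adj = np.array([r.p_adjusted for r in res])
        np.testing.assert_allclose(adj, bh_adjust(raw))
        # adjusted p's preserve the raw ordering
        assert (np.argsort(raw) == np.argsort(adj)).all() or len(set(adj)) < 3

    def test_unknown_adjustment_rejected(self):
        with pytest.raises(StatsError):
            dunn_posthoc([1, 2, 3, 4], ["a", "a", "b", "b"], adjust="bonferroni")


class TestTwoWayAnova:
    def test_hand_fixture(self):
        values = [1, 3, 2, 4, 5, 7, 6, 8]
        fa = ["a1"] * 4 + ["a2"] * 4
        fb = ["b1", "b1", "b2", "b2"] * 2
        ra, rb = two_way_anova(values, fa, fb)
        assert ra.statistic == pytest.approx(20.0)
        assert rb.statistic == pytest.approx(1.25)
        assert ra.df == (1, 5) and rb.df == (1, 5)

    def test_null_factor_gives_zero_f(self):
        values = [1.0, 2.0, 2.0, 1.0, 3.0, 4.0, 4.0, 3.0]
        fa = ["a1", "a1", "a1", "a1", "a2", "a2", "a2", "a2"]
        fb = ["b1", "b2", "b1", "b2"] * 2  # both b level means equal (2.5)
        _, rb = two_way_anova(values, fa, fb)
        assert rb.statistic == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [1, 4, 5, 6])
    def test_matches_statsmodels_type2(self, seed):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "y": rng.normal(size=12),
            "a": rng.choice(["x", "y"], 12),
            "b": rng.choice(["u", "v", "w"], 12),
        })
        if df.groupby(["a", "b"]).size().reindex(
            pd.MultiIndex.from_product([["x", "y"], ["u", "v", "w"]]), fill_value=0
        ).eq(0).any():
            pytest.skip("random draw left an empty cell")
        ra, rb = two_way_anova(df["y"], df["a"], df["b"])
        fit = smf.ols("y ~ C(a) + C(b)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert ra.statistic == pytest.approx(ref.loc["C(a)", "F"], abs=1e-8)
        assert rb.statistic == pytest.approx(ref.loc["C(b)", "F"], abs=1e-8)
        assert ra.p_value == pytest.approx(ref.loc["C(a)", "PR(>F)"], abs=1e-8)

    def test_empty_cell_rejected(self):
        with pytest.raises(StatsError):
            two_way_anova([1, 2, 3, 4], ["a", "a", "b", "b"], ["u", "u", "u", "u"])


class TestTTest:
    def test_hand_fixture(self):
        res = t_test([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.22474, abs=1e-5)
        assert res.df == (4,)

    def test_matches_scipy(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=6)
        mine = t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)

    def test_identical_samples(self):
        res = t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_p_monotone_in_shift(self):
        base = np.array([0.0, 1.0, 2.0, 3.0])
        ps = [t_test(base, base + shift).p_value for shift in (1, 5, 20)]
        assert ps[0] > ps[1] > ps[2]

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            res = t_test([1, 1, 1], [2, 2, 2])
        assert math.isnan(res.statistic)


class TestBH:
    def test_hand_fixture(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.03, 0.04]), [0.015, 0.04, 0.04]
        )

    def test_single_and_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(20)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_monotone_and_idempotent_on_sorted(self, rng):
        p = np.sort(rng.random(10))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()
        np.testing.assert_allclose(bh_adjust(adj), bh_adjust(adj))

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.2])
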