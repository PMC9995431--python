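import numpy as np
import pandas as pd
import pytest

from pollindex import (
    correlation_matrix,
    describe,
    element_profile_clustering,
    hca_ward,
    mann_whitney,
    normality_test,
    summary_table,
)
from pollindex.reference import ELEMENTS


class TestDescribe:
    def test_quartiles_linear_interpolation(self):
        out = describe([1, 2, 3, 4, 5])
        assert out["Q1"] == 2.0 and out["Med"] == 3.0 and out["Q3"] == 4.0

    def test_cv_is_sd_over_mean(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(5.0, 0.8, size=66)
        out = describe(x)
        assert out["CV"] == pytest.approx(np.std(x, ddof=1) / np.mean(x))

    def test_constant_sample(self):
        out = describe([7.0] * 10)
        assert out["SD"] == 0.0 and out["CV"] == 0.0
        assert np.isnan(out["Skewness"]) and np.isnan(out["Kurtosis"])

    def test_single_value_sentinels(self):
        out = describe([3.0])
        assert out["n"] == 1
        assert np.isnan(out["SD"]) and np.isnan(out["CV"])

    def test_skewness_kurtosis_bias_corrected(self):
        x = pd.Series([1.0, 2.0, 4.0, 8.0, 16.0])
        out = describe(x)
        assert out["Skewness"] == pytest.approx(x.skew())
        assert out["Kurtosis"] == pytest.approx(x.kurt())


class TestNormalityTest:
    def test_lognormal_rejected_in_most_seeds(self):
        rejections = 0
        for seed in range(200):
            x = np.random.default_rng(seed).lognormal(0.0, 1.0, size=66)
            _, p = normality_test(x)
            rejections += p < 0.05
        assert rejections >= 190  # >= 95%

    def test_normal_accepted_in_most_seeds(self):
        accepted = 0
        for seed in range(200):
            x = np.random.default_rng(seed).normal(0.0, 1.0, size=66)
            _, p = normality_test(x)
            accepted += p > 0.05
        assert accepted >= 180  # >= 90%

    def test_affine_invariance(self):
        x = np.random.default_rng(5).normal(size=50)
        w1, _ = normality_test(x)
        w2, _ = normality_test(3.0 * x + 11.0)
        assert w1 == pytest.approx(w2, rel=1e-9)

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])


class TestMannWhitney:
    def test_identical_groups_no_shift(self):
        x = list(range(20))
        _, p = mann_whitney(x, x)
        assert p > 0.99

    def test_complete_separation(self):
        u, p = mann_whitney(range(1, 11), range(11, 21))
        assert u == 0.0
        assert p < 0.001

    def test_power_under_one_sd_shift(self):
        rejections = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, size=30)
            b = rng.normal(1.0, 1.0, size=30)
            _, p = mann_whitney(a, b)
            rejections += p < 0.05
        assert rejections / 500 >= 0.90


class TestCorrelationMatrix:
    def _frame(self, x, y):
        return pd.DataFrame({"Zn": x, "Cu": y})

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + 0.3 * rng.normal(size=30)
        base = correlation_matrix(self._frame(x, y), elements=["Zn", "Cu"]).r.iloc[0, 1]
        warped = correlation_matrix(
            self._frame(np.exp(x), y**3), elements=["Zn", "Cu"]
        ).r.iloc[0, 1]
        assert warped == pytest.approx(base)

    def test_exponential_relationship(self):
        x = np.linspace(0, 5, 20)
        res = correlation_matrix(self._frame(x, np.exp(x)), elements=["Zn", "Cu"])
        assert res.r.iloc[0, 1] == pytest.approx(1.0)
        pear = correlation_matrix(self._frame(x, np.exp(x)), elements=["Zn", "Cu"], method="pearson")
        assert pear.r.iloc[0, 1] < 1.0

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        res = correlation_matrix(self._frame(x, -x), elements=["Zn", "Cu"])
        assert res.r.iloc[0, 1] == pytest.approx(-1.0)

    def test_hand_ranked_five_point_set(self):
        # ranks of y are (2, 1, 4, 3, 5): sum d^2 = 4, rho = 1 - 24/120 = 0.8
        res = correlation_matrix(
            self._frame([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]), elements=["Zn", "Cu"]
        )
        assert res.r.iloc[0, 1] == pytest.approx(0.8)

    def test_constant_column_flagged_undefined(self):
        res = correlation_matrix(self._frame([1, 2, 3, 4], [5, 5, 5, 5]), elements=["Zn", "Cu"])
        assert np.isnan(res.r.iloc[0, 1])
        assert res.strength.iloc[0, 1] == "undefined"
        assert bool(res.nonsignificant.iloc[0, 1])

    def test_strength_cuts(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        strong = correlation_matrix(self._frame(x, x + 0.1 * rng.normal(size=200)), elements=["Zn", "Cu"])
        assert strong.strength.iloc[0, 1] == "strong"

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            correlation_matrix(self._frame([1, 2], [3, 4]), elements=["Zn", "Cu"])


def _brute_force_ward_3(points):
    """Exhaustive Ward criterion over the three possible first merges."""
    pts = [np.asarray(p, dtype=float) for p in points]

    def delta_ess(a, b):
        a, b = np.atleast_2d(a), np.atleast_2d(b)
        ca, cb = a.mean(0), b.mean(0)
        return len(a) * len(b) / (len(a) + len(b)) * float(((ca - cb) ** 2).sum())

    pairs = [(0, 1), (0, 2), (1, 2)]
    first = min(pairs, key=lambda ij: delta_ess(pts[ij[0]], pts[ij[1]]))
    h1 = delta_ess(pts[first[0]], pts[first[1]])
    rest = ({0, 1, 2} - set(first)).pop()
    merged = np.vstack([pts[first[0]], pts[first[1]]])
    h2 = delta_ess(merged, pts[rest])
    return first, h1, h2


class TestWardClustering:
    def test_identical_profiles_merge_at_zero(self):
        tree = hca_ward([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], labels=list("abc"))
        assert tree.heights[0] == pytest.approx(0.0)

    def test_three_point_line_against_brute_force(self):
        tree = hca_ward([[0.0], [1.0], [10.0]], labels=list("abc"))
        (first, h1, h2) = _brute_force_ward_3([[0.0], [1.0], [10.0]])
        assert first == (0, 1)
        assert tree.merges[0][:2] == (frozenset("a"), frozenset("b"))
        assert tree.heights[0] == pytest.approx(h1)  # 0.5
        assert tree.heights[1] == pytest.approx(h2)  # 60.1667

    def test_random_three_leaf_instances_match_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            pts = rng.normal(size=(3, 4))
            tree = hca_ward(pts, labels=list("abc"))
            _, h1, h2 = _brute_force_ward_3(pts)
            assert tree.heights[0] == pytest.approx(h1)
            assert tree.heights[1] == pytest.approx(h2)

    def test_heights_monotone_and_conserve_total_variance(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(12, 5))
        tree = hca_ward(X, labels=[f"o{i}" for i in range(12)])
        h = tree.heights
        assert np.all(np.diff(h) >= -1e-9)
        total_ess = float(((X - X.mean(0)) ** 2).sum())
        assert h.sum() == pytest.approx(total_ess)

    def test_outlying_profile_joins_last(self):
        X = np.vstack([np.random.default_rng(4).normal(1.0, 0.1, size=(5, 3)),
                       np.full((1, 3), 50.0)])
        tree = hca_ward(X, labels=list("abcdef"))
        a, b = tree.top_split()
        assert frozenset("f") in (a, b)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            hca_ward([[0.0], [1.0]], labels=["x", "x"])

    def test_newick_serialization(self):
        tree = hca_ward([[0.0], [1.0], [10.0]], labels=list("abc"))
        nwk = tree.to_newick()
        assert nwk.endswith(";") and "a" in nwk and "(" in nwk


class TestElementProfileClustering:
    def test_cadmium_like_element_separates_at_top(self, ucc, replica):
        tree = element_profile_clustering(replica[replica.side == "left"], ucc)
        a, b = tree.top_split()
        assert frozenset(["Cd"]) in (a, b)

    def test_proportional_elements_merge_first(self, ucc):
        rng = np.random.default_rng(6)
        zn = rng.lognormal(5.0, 0.5, size=12)
        df = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(12)],
                "distance_m": list(np.repeat([0.5, 2.5, 10.0, 50.0], 3)),
                "Zn": zn,
                # identical PI profile: concentration scaled by background ratio
                "Cu": zn * ucc.background("Cu") / ucc.background("Zn"),
                "Cd": rng.lognormal(1.0, 1.0, size=12),
            }
        )
        tree = element_profile_clustering(df, ucc)
        first_a, first_b, h = tree.merges[0]
        assert {first_a, first_b} == {frozenset(["Zn"]), frozenset(["Cu"])}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_sides_cluster_independently(self, ucc, replica):
        left = element_profile_clustering(replica, ucc, side="left")
        left_only = element_profile_clustering(replica[replica.side == "left"], ucc)
        assert np.allclose(left.linkage, left_only.linkage)


def test_summary_table_row_layout(replica):
    table = summary_table(replica, elements=list(ELEMENTS))
    rows = list(table.loc["left"].index)
    assert rows[:11] == ["Min", "Max", "Mean", "SD", "Q1", "Med", "Q3", "Skewness", "Kurtosis", "CV", "n"]
    assert table.loc[("left", "n"), "Zn"] == 66
    assert table.loc[("right", "n"), "Zn"] == 55
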