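"""Univariate tests against brute-force / textbook oracles, plus the screen."""

import numpy as np
import pytest
from scipy import stats

from chemoclass import (
    anova_tukey,
    categorical_test,
    compare_two_groups,
    confounder_screen,
    kruskal_wallis,
)
from oracles import anova_f_ss, fisher_2x2_enumeration, kruskal_h, t_pooled, welch_t


class TestCompareTwoGroups:
    def test_identical_groups_p_one(self):
        vals = np.r_[np.ones(5), np.ones(5)]
        labels = np.r_[np.zeros(5), np.ones(5)]
        cmp = compare_two_groups(vals, labels, method="t_test")
        assert cmp.statistic == 0.0
        assert cmp.p_value == 1.0

    def test_t_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.normal(0, 1, int(rng.integers(3, 20)))
            b = rng.normal(0.5, 1.5, int(rng.integers(3, 20)))
            cmp = compare_two_groups(
                np.r_[a, b], np.r_[np.zeros(a.size), np.ones(b.size)], method="t_test"
            )
            t_ref, p_ref = t_pooled(a, b)
            assert cmp.statistic == pytest.approx(t_ref, abs=1e-10)
            assert cmp.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_welch_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 3, 8)
        cmp = compare_two_groups(
            np.r_[a, b], np.r_[np.zeros(12), np.ones(8)], method="welch"
        )
        t_ref, p_ref = welch_t(a, b)
        assert cmp.statistic == pytest.approx(t_ref, abs=1e-10)
        assert cmp.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_mann_whitney_exact_no_overlap(self):
        """[1,2,3] vs [4,5,6]: U = 0, exact two-sided p = 2/20 = 0.1."""
        cmp = compare_two_groups(
            [1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"], method="mann_whitney"
        )
        assert cmp.statistic == 0.0
        assert cmp.p_value == pytest.approx(0.1, abs=1e-12)
        assert cmp.notes["mann_whitney_mode"] == "exact"

    def test_mann_whitney_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(3, 8)))
            b = rng.normal(size=int(rng.integers(3, 8)))
            cmp = compare_two_groups(
                np.r_[a, b], np.r_[np.zeros(a.size), np.ones(b.size)],
                method="mann_whitney",
            )
            ref = stats.mannwhitneyu(a, b, method="exact")
            assert cmp.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_mann_whitney_normal_approximation_large_groups(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 20), rng.normal(0.8, 1, 25)
        cmp = compare_two_groups(
            np.r_[a, b], np.r_[np.zeros(20), np.ones(25)], method="mann_whitney"
        )
        assert cmp.notes["mann_whitney_mode"] == "normal_tie_corrected"
        ref = stats.mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
        assert cmp.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_auto_gate_records_choice(self):
        rng = np.random.default_rng(4)
        normal_vals = np.r_[rng.normal(0, 1, 15), rng.normal(1, 1, 15)]
        labels = np.r_[np.zeros(15), np.ones(15)]
        cmp = compare_two_groups(normal_vals, labels, method="auto")
        assert cmp.notes["auto_choice"] == cmp.method
        skewed = np.r_[rng.lognormal(0, 2, 15), rng.lognormal(1.5, 2, 15)]
        cmp2 = compare_two_groups(skewed, labels, method="auto")
        assert cmp2.method == "mann_whitney"

    def test_group_size_preconditions(self):
        with pytest.raises(ValueError):
            compare_two_groups([1.0, 2.0, 3.0], ["a", "a", "b"])
        with pytest.raises(ValueError, match="two groups"):
            compare_two_groups([1.0, 2, 3, 4, 5, 6], ["a", "a", "b", "b", "c", "c"])

    def test_relabeling_preserves_statistic_magnitude(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=20)
        labels = np.array(["x"] * 10 + ["y"] * 10)
        c1 = compare_two_groups(vals, labels, method="t_test")
        c2 = compare_two_groups(vals, np.where(labels == "x", "y", "x"), method="t_test")
        assert abs(c1.statistic) == pytest.approx(abs(c2.statistic), abs=1e-12)
        assert c1.p_value == pytest.approx(c2.p_value, abs=1e-12)


class TestAnovaTukey:
    def test_subgroup_sizes_give_df_2_38(self):
        """Group sizes 6/14/21 yield ANOVA df (2, 38)."""
        rng = np.random.default_rng(6)
        vals = rng.normal(size=41)
        labels = np.r_[np.zeros(6), np.ones(14), np.full(21, 2.0)]
        cmp = anova_tukey(vals, labels)
        assert cmp.notes["df"] == (2, 38)

    def test_identical_groups_all_p_one(self):
        vals = np.ones(12)
        labels = np.r_[np.zeros(4), np.ones(4), np.full(4, 2.0)]
        cmp = anova_tukey(vals, labels)
        assert cmp.statistic == 0.0
        assert cmp.p_value == 1.0
        assert (cmp.pairwise["p_adj"] == 1.0).all()

    def test_f_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            sizes = rng.integers(3, 12, size=3)
            groups = [rng.normal(m, 1, n) for m, n in zip((0, 0.5, 1.2), sizes)]
            vals = np.concatenate(groups)
            labels = np.concatenate([np.full(n, i) for i, n in enumerate(sizes)])
            cmp = anova_tukey(vals, labels)
            f_ref, df1, df2 = anova_f_ss(groups)
            assert cmp.statistic == pytest.approx(f_ref, abs=1e-10)
            assert cmp.notes["df"] == (df1, df2)

    def test_tukey_matches_scipy_tukey_hsd(self):
        """Independent oracle: scipy's own Tukey HSD on unequal-n groups."""
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 1, n) for m, n in ((0, 6), (0.8, 14), (1.5, 21))]
        vals = np.concatenate(groups)
        labels = np.concatenate([np.full(g.size, i) for i, g in enumerate(groups)])
        cmp = anova_tukey(vals, labels)
        ref = stats.tukey_hsd(*groups)
        pairs = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
        for (i, j), row in pairs.items():
            assert cmp.pairwise["p_adj"].iloc[row] == pytest.approx(
                ref.pvalue[i, j], abs=1e-8
            )

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey([1.0, 2, 3, 4, 5], ["a", "a", "b", "b", "c"])


class TestKruskalWallis:
    def test_identical_values_p_one(self):
        cmp = kruskal_wallis(np.ones(9), np.r_[np.zeros(3), np.ones(3), np.full(3, 2.0)])
        assert cmp.statistic == 0.0
        assert cmp.p_value == 1.0

    def test_h_matches_rank_sum_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            sizes = rng.integers(3, 10, size=3)
            groups = [np.round(rng.normal(m, 1, n), 1) for m, n in zip((0, 0.3, 1), sizes)]
            vals = np.concatenate(groups)
            labels = np.concatenate([np.full(n, i) for i, n in enumerate(sizes)])
            cmp = kruskal_wallis(vals, labels)
            assert cmp.statistic == pytest.approx(kruskal_h(groups), abs=1e-10)

    def test_monotone_shifted_groups_significant(self):
        rng = np.random.default_rng(10)
        groups = [rng.uniform(0, 1, 10), rng.uniform(2, 3, 10), rng.uniform(4, 5, 10)]
        vals = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], 10)
        assert kruskal_wallis(vals, labels).p_value < 0.01


class TestCategorical:
    def test_uniform_table_chi_square_zero(self):
        cmp = categorical_test([[10, 10], [10, 10]], method="chi_square")
        assert cmp.statistic == 0.0
        assert cmp.p_value == 1.0

    def test_fisher_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            table = rng.integers(1, 12, size=(2, 2))
            cmp = categorical_test(table, method="fisher_exact")
            assert cmp.p_value == pytest.approx(
                fisher_2x2_enumeration(table), abs=1e-12
            )

    def test_doubling_cells_preserves_odds_ratio(self):
        t = np.array([[3, 7], [9, 2]])
        a = categorical_test(t, method="fisher_exact")
        b = categorical_test(2 * t, method="fisher_exact")
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_auto_picks_fisher_for_small_expected_cells(self):
        cmp = categorical_test([[1, 9], [8, 2]], method="auto")
        assert cmp.method == "fisher_exact"
        cmp2 = categorical_test([[30, 20], [25, 35]], method="auto")
        assert cmp2.method == "chi_square"

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            categorical_test([[0, 0], [5, 3]])


class TestConfounderScreen:
    def test_duplicated_feature_as_covariate_perfect_correlation(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        out = confounder_screen(x, continuous_covariates={"self": x})
        pear = out[(out.covariate == "self") & (out.method == "pearson")].iloc[0]
        assert pear.statistic == pytest.approx(1.0, abs=1e-12)
        assert pear.p_value < 1e-10

    def test_constant_feature_not_evaluable_or_p_one(self):
        rng = np.random.default_rng(13)
        strat = (rng.random(20) < 0.5).astype(int)
        out = confounder_screen(
            np.ones(20),
            labels_by_stratum={"drug": strat},
            continuous_covariates={"age": rng.normal(50, 10, 20)},
        )
        for _, row in out.iterrows():
            assert (not row.evaluable) or row.p_value == 1.0

    def test_empty_stratum_reported_not_raised(self):
        rng = np.random.default_rng(14)
        out = confounder_screen(
            rng.normal(size=10), labels_by_stratum={"always": np.ones(10)}
        )
        assert not out.iloc[0].evaluable

    def test_null_covariate_p_values_uniform(self):
        """Independent covariate vs pure-noise feature: p ~ U(0,1) (KS check)."""
        rng = np.random.default_rng(15)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=40)
            strat = np.r_[np.zeros(20), np.ones(20)]
            cmp = compare_two_groups(x, strat, method="t_test")
            pvals.append(cmp.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_bh_adjustment_column_present_when_requested(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=24)
        out = confounder_screen(
            x,
            labels_by_stratum={"drug": np.r_[np.zeros(12), np.ones(12)]},
            continuous_covariates={"age": rng.normal(50, 5, 24)},
            adjust="bh",
        )
        assert "p_adjusted_bh" in out.columns
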