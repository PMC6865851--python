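"""OPLS-DA core: NIPALS contracts, PLS1 equivalence oracle, VIP scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemoclass import fit_oplsda, predict, rank_vip, vip_scores
from conftest import random_two_class
from oracles import nipals_pls1, vip_brute


def scaled(X):
    return (X - X.mean(0)) / X.std(0, ddof=1)


class TestFitOplsda:
    def test_self_separating_single_feature(self):
        """X's one column equals the centered class code: training is perfect."""
        y = np.array([0] * 5 + [1] * 5)
        X = (y - y.mean()).astype(float)[:, None]
        model = fit_oplsda(X, y, n_orthogonal=0, scaling="center")
        yhat, pred = predict(model, X)
        assert np.all(pred == y)
        assert abs(np.corrcoef(model.t, y)[0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonality_invariants(self, small_planted_fm):
        fm, labels = small_planted_fm
        model = fit_oplsda(fm.values, labels, n_orthogonal=3)
        assert np.linalg.norm(model.w) == pytest.approx(1.0, abs=1e-12)
        yc = (labels == np.unique(labels)[1]).astype(float)
        yc = yc - yc.mean()
        for j in range(model.n_orthogonal):
            assert abs(model.w @ model.W_o[:, j]) < 1e-8
            assert np.linalg.norm(model.W_o[:, j]) == pytest.approx(1.0, abs=1e-10)
            t_o = model.T_o[:, j]
            assert abs(np.corrcoef(t_o, yc)[0, 1]) < 1e-6

    @pytest.mark.parametrize("n_orthogonal", [0, 1, 2, 3])
    def test_fitted_values_equal_pls1(self, n_orthogonal):
        """OPLS with k orthogonal components fits y exactly like (k+1)-component PLS1."""
        rng = np.random.default_rng(17)
        X, y = random_two_class(rng, n0=8, n1=9, p=12, effect=1.0)
        model = fit_oplsda(X, y, n_orthogonal=n_orthogonal)
        yhat, _ = predict(model, X)
        yc = (y - y.mean()).astype(float)
        oracle = nipals_pls1(scaled(X), yc, n_orthogonal + 1) + y.mean()
        np.testing.assert_allclose(yhat, oracle, atol=1e-6)

    def test_pls1_equivalence_many_random_instances(self):
        """The subspace-equivalence property holds on >= 50 random instances."""
        rng = np.random.default_rng(100)
        for trial in range(50):
            n0 = int(rng.integers(5, 10))
            n1 = int(rng.integers(5, 10))
            p = int(rng.integers(4, 15))
            k = int(rng.integers(0, 3))
            X, y = random_two_class(rng, n0=n0, n1=n1, p=p, effect=0.5)
            model = fit_oplsda(X, y, n_orthogonal=k)
            yhat, _ = predict(model, X)
            oracle = nipals_pls1(scaled(X), y - y.mean(), k + 1) + y.mean()
            np.testing.assert_allclose(yhat, oracle, atol=1e-6, err_msg=f"trial {trial}")

    def test_no_predictive_direction_error(self):
        """y orthogonal to every column of scaled X raises."""
        y = np.array([0, 0, 1, 1])
        # columns symmetric within classes -> zero covariance with y after centering
        X = np.array([[1.0, 2.0], [-1.0, -2.0], [1.0, 2.0], [-1.0, -2.0]])
        with pytest.raises(ValueError, match="no predictive direction"):
            fit_oplsda(X, y, n_orthogonal=0, scaling="center")

    def test_one_class_absent_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="two classes"):
            fit_oplsda(X, np.zeros(6))

    def test_scale_equivariance_under_unit_variance(self, small_planted_fm):
        """Multiplying a raw column by a positive constant changes nothing."""
        fm, labels = small_planted_fm
        X2 = fm.values.copy()
        X2[:, 10] *= 37.5
        m1 = fit_oplsda(fm.values, labels)
        m2 = fit_oplsda(X2, labels)
        np.testing.assert_allclose(m1.w, m2.w, atol=1e-10)
        np.testing.assert_allclose(m1.t, m2.t, atol=1e-8)
        np.testing.assert_allclose(
            vip_scores(m1).vip, vip_scores(m2).vip, atol=1e-10
        )


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self, small_planted_fm):
        fm, labels = small_planted_fm
        model = fit_oplsda(fm.values, labels, n_orthogonal=1)
        yhat, _ = predict(model, fm.values)
        np.testing.assert_allclose(yhat, model.q * model.t + model.y_mean, atol=1e-10)

    def test_column_mean_row_predicts_label_mean(self, small_planted_fm):
        fm, labels = small_planted_fm
        model = fit_oplsda(fm.values, labels, n_orthogonal=1)
        yhat, _ = predict(model, model.column_means)
        assert yhat[0] == pytest.approx(model.y_mean, abs=1e-10)

    def test_feature_mismatch_rejected(self, small_planted_fm):
        fm, labels = small_planted_fm
        model = fit_oplsda(fm.values, labels)
        with pytest.raises(ValueError, match="feature mismatch"):
            predict(model, np.zeros((2, 7)))

    def test_holdout_accuracy_on_clean_planted_effect(self):
        """Zero-noise 2x planted shift, 20 vs 20: held-out accuracy is 1.0."""
        from chemoclass import SpectraConfig, generate_feature_matrix

        cfg = SpectraConfig(
            n_per_class=(20, 20),
            planted_effects=((8, 0, 2.0), (11, 0, 2.0)),
            noise_sd=0.0,
            seed=5,
        )
        fm, labels = generate_feature_matrix(cfg)
        # zero noise makes many columns constant: use centering only
        train = np.r_[0:15, 20:35]
        test = np.r_[15:20, 35:40]
        model = fit_oplsda(fm.values[train], labels[train], scaling="center")
        _, pred = predict(model, fm.values[test])
        assert np.mean(pred == labels[test]) == 1.0


class TestVIP:
    def test_single_feature_vip_is_one(self):
        y = np.array([0] * 4 + [1] * 4)
        X = (y + np.random.default_rng(1).normal(0, 0.1, 8)).astype(float)[:, None]
        model = fit_oplsda(X, y, n_orthogonal=0)
        assert vip_scores(model).vip[0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_columns_share_vip(self):
        rng = np.random.default_rng(2)
        y = np.array([0] * 6 + [1] * 6)
        col = rng.normal(size=12) + y
        X = np.column_stack([col, col])
        model = fit_oplsda(X, y, n_orthogonal=0)
        vip = vip_scores(model).vip
        np.testing.assert_allclose(vip, [1.0, 1.0], atol=1e-10)

    def test_matches_brute_force_formula(self):
        """Random 12 x 6 instance: VIP equals the independently coded formula."""
        rng = np.random.default_rng(3)
        X, y = random_two_class(rng, n0=6, n1=6, p=6, effect=1.0)
        model = fit_oplsda(X, y, n_orthogonal=2)
        W = np.column_stack([model.w, model.W_o])
        expected = vip_brute(W, model.component_y_ss)
        np.testing.assert_allclose(vip_scores(model).vip, expected, atol=1e-8)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_vip_normalization_property(self, seed):
        """Sum of squared VIP equals the number of features on every fit."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 20))
        X, y = random_two_class(rng, n0=6, n1=7, p=p, effect=0.8)
        model = fit_oplsda(X, y, n_orthogonal=int(rng.integers(0, 3)))
        vip = vip_scores(model).vip
        assert (vip**2).sum() == pytest.approx(p, abs=1e-8)

    def test_total_and_predictive_only_variants_agree(self, small_planted_fm):
        fm, labels = small_planted_fm
        model = fit_oplsda(fm.values, labels, n_orthogonal=2)
        np.testing.assert_allclose(
            vip_scores(model, variant="total").vip,
            vip_scores(model, variant="predictive_only").vip,
            atol=1e-8,
        )


class TestRankVIP:
    def test_planted_bins_top_ranked_at_cutoff(self, small_planted_fm):
        fm, labels = small_planted_fm
        model = fit_oplsda(fm, labels)
        ranked = rank_vip(vip_scores(model), threshold=1.75)
        top_two_centers = sorted(round(c, 2) for _, c, _ in ranked[:2])
        assert top_two_centers == [3.61, 8.45]

    def test_threshold_zero_returns_all_descending(self, small_planted_fm):
        fm, labels = small_planted_fm
        vip = vip_scores(fit_oplsda(fm, labels))
        ranked = rank_vip(vip, threshold=0.0)
        assert len(ranked) == fm.n_features
        vals = [v for _, _, v in ranked]
        assert vals == sorted(vals, reverse=True)

    def test_threshold_above_max_empty(self, small_planted_fm):
        fm, labels = small_planted_fm
        vip = vip_scores(fit_oplsda(fm, labels))
        assert rank_vip(vip, threshold=float(vip.vip.max()) + 1) == []

    def test_ties_broken_by_ascending_bin_center(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 6 + [1] * 6)
        col = rng.normal(size=12) + y
        from chemoclass import FeatureMatrix

        fm = FeatureMatrix(
            values=np.column_stack([col, col]),
            bin_centers=np.array([5.0, 1.0]),
            sample_ids=[f"s{i}" for i in range(12)],
        )
        ranked = rank_vip(vip_scores(fit_oplsda(fm, y, n_orthogonal=0)), threshold=0.0)
        assert [c for _, c, _ in ranked] == [1.0, 5.0]
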