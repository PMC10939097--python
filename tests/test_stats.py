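"""Univariate screens (t, AUC, ICC) and multivariate models (PCA, PLS-DA, VIP)."""

import numpy as np
import pandas as pd
import pytest

from fibermsi.core import ValidationError
from fibermsi.stats import (PLSDAModel, auc_features, icc_band, icc_ck,
                            icc_features, pca, plsda, select_biomarkers,
                            ttest_features)


def brute_force_auc(pos, neg):
    """Pairwise enumeration: P(pos > neg) + 0.5 P(tie)."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def anova_icc_oracle(X):
    """ICC(C,k) from an independently built two-way ANOVA via statsmodels OLS."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n, k = X.shape
    long = pd.DataFrame({
        "y": X.ravel(),
        "target": np.repeat(np.arange(n), k).astype(str),
        "rater": np.tile(np.arange(k), n).astype(str),
    })
    tab = sm.stats.anova_lm(ols("y ~ C(target) + C(rater)", data=long).fit())
    ms_t = tab.loc["C(target)", "mean_sq"]
    ms_e = tab.loc["Residual", "mean_sq"]
    return (ms_t - ms_e) / ms_t


class TestTTest:
    def test_textbook_example(self):
        M = np.array([[1.0], [2], [3], [4], [5], [6]])
        out = ttest_features(M, ["a"] * 3 + ["b"] * 3)
        assert out["t"][0] == pytest.approx(-3.674, abs=1e-3)
        assert out["p"][0] == pytest.approx(0.0214, abs=2e-4)

    def test_identical_groups(self):
        M = np.tile([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]], (2, 1))
        out = ttest_features(M, ["a"] * 3 + ["b"] * 3)
        np.testing.assert_allclose(out["log2fc"], 0.0)

    def test_zero_variance_equal_means_gives_t0_p1(self):
        M = np.full((6, 1), 4.0)
        out = ttest_features(M, ["a"] * 3 + ["b"] * 3)
        assert out["t"][0] == 0.0 and out["p"][0] == 1.0

    def test_equal_means_nonzero_variance_fc_zero(self):
        M = np.array([[1.0], [3.0], [1.5], [2.5]])
        out = ttest_features(M, ["a", "a", "b", "b"])
        assert out["log2fc"][0] == pytest.approx(0.0)

    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(2024)
        M = rng.standard_normal((12, 2000))
        out = ttest_features(M, ["a"] * 6 + ["b"] * 6)
        assert (out["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)


class TestAUC:
    def test_complete_separation(self):
        M = np.array([[1.0], [2], [3], [4], [5], [6]])
        out = auc_features(M, ["a"] * 3 + ["b"] * 3, positive_group="b")
        assert out["auc"][0] == 1.0 and bool(out["discriminative"][0])

    def test_all_ties_gives_half(self):
        M = np.full((6, 1), 2.0)
        out = auc_features(M, ["a"] * 3 + ["b"] * 3)
        assert out["auc"][0] == 0.5 and not bool(out["discriminative"][0])

    def test_enumerated_example(self):
        M = np.array([[2.0], [4.0], [1.0], [3.0]])
        out = auc_features(M, ["b", "b", "a", "a"], positive_group="b")
        assert out["auc"][0] == 0.75

    def test_matches_brute_force_on_random_instances_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n1, n2 = rng.integers(3, 21, size=2)
            vals = rng.integers(0, 6, size=n1 + n2).astype(float)  # many ties
            groups = ["p"] * n1 + ["n"] * n2
            out = auc_features(vals[:, None], groups, positive_group="p")
            expect = brute_force_auc(vals[:n1], vals[n1:])
            assert abs(out["auc"][0] - expect) < 1e-12

    def test_symmetric_discriminative_flag(self):
        M = np.array([[6.0], [5], [4], [3], [2], [1]])
        out = auc_features(M, ["a"] * 3 + ["b"] * 3, positive_group="b")
        assert out["auc"][0] == 0.0 and bool(out["discriminative"][0])


class TestICC:
    def test_perfect_agreement_gives_one(self):
        X = np.array([[1.0, 1.0], [3.0, 3.0], [5.0, 5.0]])
        assert icc_ck(X) == 1.0

    def test_small_matrix_matches_anova_oracle(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert icc_ck(X) == pytest.approx(anova_icc_oracle(X), abs=1e-9)

    def test_random_matrices_match_anova_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n, k = rng.integers(3, 10), rng.integers(2, 6)
            X = rng.standard_normal((n, k)) + rng.standard_normal((n, 1))
            assert icc_ck(X) == pytest.approx(anova_icc_oracle(X), abs=1e-9)

    def test_matches_pingouin_icc3k(self):
        import pingouin as pg

        rng = np.random.default_rng(4)
        X = rng.standard_normal((8, 4)) + 2 * rng.standard_normal((8, 1))
        n, k = X.shape
        long = pd.DataFrame({"y": X.ravel(),
                             "t": np.repeat(np.arange(n), k),
                             "r": np.tile(np.arange(k), n)})
        ref = pg.intraclass_corr(long, targets="t", raters="r", ratings="y")
        ref_icc = ref.set_index("Type").loc["ICC(C,k)", "ICC"]
        assert icc_ck(X) == pytest.approx(ref_icc, abs=1e-9)

    def test_variance_component_closed_form(self):
        # sigma2_T = 1, sigma2_E = 1, k = 4: ICC(C,k) = 4/(4+1) = 0.8
        rng = np.random.default_rng(99)
        iccs = [icc_ck(rng.standard_normal((2000, 1)) +
                       rng.standard_normal((2000, 4)))
                for _ in range(3)]
        assert np.mean(iccs) == pytest.approx(0.8, abs=0.02)

    def test_degenerate_targets_warn_and_return_nan(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        with pytest.warns(UserWarning, match="ICC undefined"):
            assert np.isnan(icc_ck(X))

    def test_bands(self):
        assert icc_band(0.9) == "excellent"
        assert icc_band(0.75) == "excellent"
        assert icc_band(0.65) == "good"
        assert icc_band(0.5) == "fair"
        assert icc_band(0.1) == "poor"

    def test_icc_features_table(self):
        rng = np.random.default_rng(0)
        mats = rng.standard_normal((5, 6, 3)) + rng.standard_normal((5, 6, 1))
        out = icc_features(mats)
        assert len(out) == 5 and (out["icc"] <= 1).all()


class TestPCA:
    def test_collinear_data_has_unit_first_ratio(self):
        t = np.linspace(0, 1, 10)
        M = np.column_stack([t, 2 * t, -t])
        _, _, ratios = pca(M, 2)
        assert ratios[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_splits_variance(self):
        rng = np.random.default_rng(12)
        M = rng.standard_normal((4000, 2))
        _, _, ratios = pca(M, 2)
        np.testing.assert_allclose(ratios, [0.5, 0.5], atol=0.05)

    def test_duplicated_samples_have_identical_scores(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((5, 4))
        scores, _, _ = pca(np.vstack([M, M]), 2)
        np.testing.assert_allclose(scores[:5], scores[5:])

    def test_too_many_components_rejected(self):
        with pytest.raises(ValidationError):
            pca(np.eye(3), 3)


class TestPLSDA:
    def test_single_feature_vip_is_one(self):
        M = np.array([[1.0], [1.2], [0.9], [5.0], [5.2], [4.9]])
        model = plsda(M, ["a"] * 3 + ["b"] * 3, n_components=1)
        assert model.vip[0] == pytest.approx(1.0)

    def test_vip_squared_sums_to_feature_count(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            r = np.random.default_rng(seed)
            M = r.standard_normal((16, 30))
            model = plsda(M, ["a"] * 8 + ["b"] * 8, n_components=3)
            assert np.sum(model.vip ** 2) == pytest.approx(30, rel=1e-6)

    def test_planted_markers_take_top_vip_ranks(self):
        rng = np.random.default_rng(17)
        n = 10
        M = rng.standard_normal((2 * n, 100))
        y = np.array(["a"] * n + ["b"] * n)
        planted = [3, 20, 45, 71, 98]
        for j in planted:
            M[:, j] += np.where(y == "b", 3.0, 0.0)
        model = plsda(M, y, n_components=2)
        top5 = set(model.feature_names[np.argsort(-model.vip)[:5]])
        assert top5 == set(planted)

    def test_constant_features_dropped_with_warning(self):
        M = np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0], [4.0, 7.0]])
        with pytest.warns(UserWarning, match="constant"):
            model = plsda(M, ["a", "a", "b", "b"], n_components=1)
        assert list(model.dropped_features) == [1]


class TestBiomarkerGate:
    def _model(self, vip, loading):
        n = len(vip)
        return PLSDAModel(n_components=1, scores=np.zeros((2, 1)),
                          x_loadings=np.array(loading)[:, None],
                          weights=np.zeros((n, 1)),
                          y_variance_per_comp=np.ones(1),
                          vip=np.array(vip), feature_names=np.arange(n))

    def test_thresholds_are_inclusive(self):
        model = self._model([1.2, 0.9, 1.5, 1.0, 0.999, 1.0],
                            [0.06, 0.50, 0.04, 0.05, 0.05, 0.049])
        kept = set(select_biomarkers(model, vip_min=1.0, loading_min=0.05))
        # VIP>=1 & |loading|>=0.05: kept are (1.2, .06) and the exact (1.0, .05)
        assert kept == {0, 3}

    def test_negative_loading_counts_by_magnitude(self):
        model = self._model([2.0], [-0.3])
        assert list(select_biomarkers(model)) == [0]
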