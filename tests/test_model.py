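"""Modelling chain: transforms, OLS, Lasso ensemble, evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from smpc.model import (
    EfficacyModel,
    confusion,
    estimate_score,
    evaluate_mse,
    fit_combined,
    fit_single_metric,
    lasso_ensemble,
    mann_whitney,
    roc_analysis,
    transform_metrics,
)
from smpc.registry import ABT199_PANEL, METRIC_REGISTRY
from smpc.synthetic import default_ground_truth_model, gen_cohort


class TestTransformMetrics:
    def test_floor_rules(self):
        profiles = pd.DataFrame({
            "BCL2-BAX CPX": [50.0, 1024.0],
            "BCLxL-BAK CPX": [5e6, 4e7],
        })
        feat, flags = transform_metrics(profiles)
        assert feat.loc[0, "BCL2-BAX CPX"] == pytest.approx(np.log2(100))
        assert feat.loc[1, "BCL2-BAX CPX"] == pytest.approx(10.0)
        assert feat.loc[0, "BCLxL-BAK CPX"] == pytest.approx(np.log2(1e7))
        assert flags.loc[0, "BCL2-BAX CPX"] and not flags.loc[1, "BCL2-BAX CPX"]

    def test_monotone_and_idempotent_on_floored(self):
        profiles = pd.DataFrame({"BCL2-BAX CPX": [100.0, 150.0, 5000.0]})
        feat, _ = transform_metrics(profiles)
        assert (np.diff(feat["BCL2-BAX CPX"]) > 0).all()
        again, flags = transform_metrics(np.exp2(feat))
        pd.testing.assert_frame_equal(feat, again)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_metrics(pd.DataFrame({"BCL2-BAX CPX": [-1.0]}))

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            transform_metrics(pd.DataFrame({"bogus": [1.0]}))


class TestFitSingleMetric:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = fit_single_metric(x, 2 * x + 1)
        assert res.slopes[0] == pytest.approx(2.0)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.p_value < 1e-12

    def test_hand_computed_four_points(self):
        # closed-form OLS: Sxy = 3, Sxx = 5 -> slope 0.6
        res = fit_single_metric(np.array([1.0, 2, 3, 4]),
                                np.array([1.0, 2, 2, 3]))
        assert res.slopes[0] == pytest.approx(0.6)
        assert res.intercept == pytest.approx(0.5)

    def test_statsmodels_oracle_equivalence(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(scale=0.3, size=30)
        res = fit_single_metric(x, y)
        sm_fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.slopes[0] == pytest.approx(sm_fit.params[1], abs=1e-10)
        assert res.f_stat == pytest.approx(sm_fit.fvalue, rel=1e-10)
        assert res.p_value == pytest.approx(sm_fit.f_pvalue, abs=1e-12)

    def test_permuted_target_p_uniform(self, rng):
        pvals = []
        x = rng.normal(size=20)
        for _ in range(300):
            y = rng.normal(size=20)
            pvals.append(fit_single_metric(x, y).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.005

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_single_metric(np.ones(5), np.arange(5.0))


class TestFitCombined:
    def test_noiseless_recovery(self):
        truth = default_ground_truth_model()
        profiles, auc, _ = gen_cohort(
            30, noise_sd=0.0, seed=8,
            metric_logsds={m: 0.5 for m in METRIC_REGISTRY},
        )
        assert 0 < auc.min() and auc.max() < 1  # no clipping occurred
        feat, _ = transform_metrics(profiles)
        model, res = fit_combined(feat[list(ABT199_PANEL)], auc)
        np.testing.assert_allclose(model.coefficients, truth.coefficients,
                                   atol=1e-9)
        assert model.intercept == pytest.approx(truth.intercept, abs=1e-9)
        assert res.accepted

    def test_statsmodels_oracle_equivalence(self, rng):
        import statsmodels.api as sm

        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=ABT199_PANEL)
        y = X @ [0.1, 0.2, -0.1] + rng.normal(scale=0.1, size=40)
        model, res = fit_combined(X, y)
        sm_fit = sm.OLS(np.asarray(y), sm.add_constant(X.to_numpy())).fit()
        np.testing.assert_allclose(model.coefficients, sm_fit.params[1:],
                                   atol=1e-10)
        assert res.f_stat == pytest.approx(sm_fit.fvalue, rel=1e-10)

    def test_duplicated_metric_raises_naming_collinearity(self):
        X = pd.DataFrame({
            "BCL2-BAX CPX": [1.0, 2, 3, 4, 5, 6],
            "BCLxL-BAK CPX": [1.0, 2, 3, 4, 5, 6],
        })
        with pytest.raises(ValueError, match="collinear"):
            fit_combined(X, np.arange(6.0))


class TestEstimateScore:
    def test_constant_model(self):
        m = EfficacyModel(drug="ABT-199", metric_names=("BCL2-BAX CPX",),
                          coefficients=(0.0,), intercept=0.5)
        feat = pd.DataFrame({"BCL2-BAX CPX": [3.0, 8.0, 12.0]})
        assert (estimate_score(m, feat) == 0.5).all()

    def test_missing_metric_named(self):
        m = EfficacyModel(drug="ABT-199", metric_names=ABT199_PANEL,
                          coefficients=(0.1, 0.1, -0.1), intercept=0.0)
        with pytest.raises(ValueError, match="BCLxL-BAK CPX"):
            estimate_score(m, pd.DataFrame({
                "BCL2-BIM_BH3 PBA": [1.0], "BCL2-BAX CPX": [1.0]}))

    @given(alpha=st.floats(0.0, 1.0))
    def test_affine_in_features_before_clipping(self, alpha):
        m = EfficacyModel(drug="ABT-199", metric_names=("BCL2-BAX CPX",),
                          coefficients=(0.05,), intercept=0.1)
        f1 = pd.DataFrame({"BCL2-BAX CPX": [2.0]})
        f2 = pd.DataFrame({"BCL2-BAX CPX": [10.0]})
        mix = alpha * f1 + (1 - alpha) * f2
        expected = (alpha * estimate_score(m, f1).iloc[0]
                    + (1 - alpha) * estimate_score(m, f2).iloc[0])
        assert estimate_score(m, mix).iloc[0] == pytest.approx(expected)


class TestRocAnalysis:
    def test_perfect_separation(self):
        assert roc_analysis([0.9, 0.8, 0.2, 0.1],
                            [True, True, False, False]).auc == 1.0

    def test_all_ties_give_half(self):
        assert roc_analysis([0.5] * 6,
                            [True, False] * 3).auc == pytest.approx(0.5)

    def test_pair_enumeration_example(self):
        res = roc_analysis([0.9, 0.8, 0.4, 0.3],
                           [True, False, True, False])
        assert res.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.2], [True, True])


class TestEvaluateMse:
    def test_values(self):
        assert evaluate_mse([0.5, 0.5], [0.5, 0.5]) == 0.0
        assert evaluate_mse([0.6, 0.4], [0.5, 0.5]) == pytest.approx(0.01)

    def test_exclusions_logged(self):
        pred = pd.Series([0.5, 0.9], index=["a", "b"])
        obs = pd.Series([0.5, 0.1], index=["a", "b"])
        with pytest.warns(UserWarning, match="b"):
            assert evaluate_mse(pred, obs, exclusions=["b"]) == 0.0

    def test_combined_model_beats_single_metric(self):
        profiles, auc, _ = gen_cohort(32, noise_sd=0.05, seed=13)
        feat, _ = transform_metrics(profiles)
        combined, _ = fit_combined(feat[list(ABT199_PANEL)], auc)
        single, _ = fit_combined(feat[["BCL2-BAX CPX"]], auc)
        mse_c = evaluate_mse(estimate_score(combined, feat), auc)
        mse_s = evaluate_mse(estimate_score(single, feat), auc)
        assert mse_c < mse_s


class TestConfusion:
    def test_all_correct(self):
        res = confusion([True, False], [True, False])
        assert res.sensitivity_pct == 100.0 and res.specificity_pct == 100.0

    def test_prospective_cohort_shape(self):
        # 4 responders all predicted R; 6 non-responders, 5 predicted NR
        predicted = [True] * 4 + [False] * 5 + [True]
        observed = [True] * 4 + [False] * 6
        res = confusion(predicted, observed)
        assert res.sensitivity_pct == 100.0
        assert res.specificity_pct == pytest.approx(83.333, abs=0.01)
        np.testing.assert_array_equal(res.matrix, [[4, 0], [1, 5]])

    def test_degenerate_all_predicted_positive(self):
        res = confusion([True] * 6, [True, True, False, False, False, False])
        assert res.sensitivity_pct == 100.0 and res.specificity_pct == 0.0

    def test_absent_class_flagged_nan(self):
        res = confusion([True, True], [True, True])
        assert np.isnan(res.specificity_pct)


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p > 0.99

    def test_u_matches_roc_auc(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(3, 10, size=2)
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            u, _ = mann_whitney(a, b)
            auc = roc_analysis(np.concatenate([a, b]),
                               [True] * n1 + [False] * n2).auc
            assert u / (n1 * n2) == pytest.approx(auc, abs=1e-12)


class TestLassoEnsemble:
    def test_requires_seed_and_both_classes(self):
        profiles, auc, _ = gen_cohort(16, noise_sd=0.05, seed=4)
        feat, _ = transform_metrics(profiles)
        with pytest.raises(ValueError):
            lasso_ensemble(feat, auc, n_candidates=10)

    def test_strong_signal_recovers_true_support(self):
        truth = default_ground_truth_model()
        profiles, auc, _ = gen_cohort(32, noise_sd=0.05, seed=11)
        feat, _ = transform_metrics(profiles)
        ens = lasso_ensemble(feat, auc, n_candidates=400, seed=42)
        assert ens.n_retained > 10
        freq = ens.support_frequency()
        true_freq = freq[list(truth.metric_names)]
        null_freq = freq.drop(list(truth.metric_names))
        assert (true_freq >= 0.8).all()
        assert null_freq.mean() < true_freq.min()

    def test_pure_noise_target_rarely_retained(self):
        profiles, _, _ = gen_cohort(32, noise_sd=0.05, seed=5)
        feat, _ = transform_metrics(profiles)
        rng = np.random.default_rng(7)
        # noise target with both classes present but no metric signal
        target = rng.uniform(0.3, 0.9, size=32)
        ens = lasso_ensemble(feat, target, n_candidates=200, seed=3)
        # test split has >= 8 samples; chance of all-correct labels is
        # far below one half, so most candidates must fail retention
        assert ens.n_retained < 0.5 * ens.n_candidates

    def test_deterministic_under_seed(self):
        profiles, auc, _ = gen_cohort(32, noise_sd=0.05, seed=11)
        feat, _ = transform_metrics(profiles)
        a = lasso_ensemble(feat, auc, n_candidates=50, seed=9)
        b = lasso_ensemble(feat, auc, n_candidates=50, seed=9)
        pd.testing.assert_frame_equal(a.coefficient_matrix,
                                      b.coefficient_matrix)
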