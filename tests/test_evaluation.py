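"""Evaluation: Mann-Whitney AUC, GLM fitting, resampled distributions and
the permutation p-value."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traumapanel import (
    EvalConfig,
    evaluate_panel,
    fit_glm,
    improvement_pp,
    permutation_pvalue,
    resampled_auc,
    score_auc,
    timepoint_group_test,
    univariate_panel,
)


def brute_force_auc(scores, labels):
    """All-pairs counting oracle: (#{pos>neg} + 0.5 #{pos=neg}) / (np*nn)."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestScoreAuc:
    def test_perfect_separation(self):
        assert score_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert score_auc([0.3] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_three_of_four_pairs(self):
        assert score_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            score_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_equals_brute_force(self, data):
        n = data.draw(st.integers(2, 30))
        labels = data.draw(
            st.lists(st.sampled_from([0, 1]), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        # integer scores force ties to occur often
        scores = data.draw(st.lists(st.integers(-3, 3), min_size=n, max_size=n))
        assert score_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        scores = rng.standard_normal(n)
        labels = np.zeros(n, dtype=int)
        labels[: n // 3] = 1
        base = score_auc(scores, labels)
        assert score_auc(3 * scores + 2, labels) == pytest.approx(base, abs=1e-12)
        assert score_auc(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = rng.integers(-2, 3, n).astype(float)
            assert score_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestFitGlm:
    def test_outcome_identical_feature_orders_training_scores(self):
        y = np.array([0, 1, 0, 1, 1, 0, 0, 1], dtype=float)
        model = fit_glm(y[:, None], y)
        assert score_auc(model.decision(y[:, None]), y) == 1.0

    def test_intercept_only_constant_scores(self):
        y = np.array([0, 1, 1, 0, 1], dtype=float)
        model = fit_glm(np.empty((5, 0)), y)
        s = model.decision(np.empty((3, 0)))
        assert np.all(s == s[0])

    def test_matches_statsmodels_and_recovers_truth(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        n = 500
        X = rng.standard_normal((n, 2))
        eta = 1.0 * X[:, 0] - 1.0 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        model = fit_glm(X, y)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            np.r_[model.intercept, model.coef], ref.params, atol=1e-6
        )
        # parameter recovery within 3 standard errors of the truth
        for est, se, true in zip(ref.params[1:], ref.bse[1:], [1.0, -1.0]):
            assert abs(est - true) < 3 * se

    def test_separation_triggers_ridge_fallback(self):
        x = np.linspace(-1, 1, 20)
        y = (x > 0).astype(float)
        model = fit_glm(x[:, None], y)
        assert model.used_ridge
        assert np.isfinite(model.coef).all()
        assert score_auc(model.decision(x[:, None]), y) == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_glm(np.zeros((4, 1)), np.ones(4))


class TestPermutationPvalue:
    def test_all_permuted_below(self):
        real = np.full(100, 0.9)
        perm = np.linspace(0.3, 0.6, 1000)
        p = permutation_pvalue(real, perm)
        assert p.p_value == 0.0
        assert p.p_value_corrected == pytest.approx(1 / 1001)

    def test_identical_samples(self):
        rng = np.random.default_rng(4)
        s = rng.random(500)
        p = permutation_pvalue(s, s)
        assert p.p_value == pytest.approx((s > s.mean()).mean())

    def test_symmetric_null_near_half(self):
        rng = np.random.default_rng(5)
        real = np.full(200, 0.5)
        perm = 0.5 + 0.05 * rng.standard_normal(5000)
        assert permutation_pvalue(real, perm).p_value == pytest.approx(0.5, abs=0.03)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.array([]), np.array([0.5]))


class TestResampledAuc:
    def test_outcome_equal_feature_gives_perfect_auc(self, flat_cohort):
        cohort, _ = flat_cohort
        t = cohort.copy()
        t.data["oracle"] = t.outcome.astype(float)
        t.feature_meta.loc["oracle"] = ["t1", "immune"]
        cfg = EvalConfig(n_resamples=50, n_permutation_resamples=50, seed=1)
        aucs = resampled_auc(t, ["oracle"], cfg, permute=False)
        assert np.all(aucs == 1.0)

    def test_permuted_null_centres_at_half(self, flat_cohort):
        cohort, truth = flat_cohort
        cfg = EvalConfig(n_resamples=300, n_permutation_resamples=300, seed=2)
        perm = resampled_auc(cohort, truth.markers, cfg, permute=True)
        assert perm.mean() == pytest.approx(0.5, abs=0.05)
        assert np.all((perm >= 0) & (perm <= 1))

    def test_deterministic(self, flat_cohort):
        cohort, truth = flat_cohort
        cfg = EvalConfig(n_resamples=40, n_permutation_resamples=40, seed=9)
        a = resampled_auc(cohort, truth.markers, cfg)
        b = resampled_auc(cohort, truth.markers, cfg)
        np.testing.assert_array_equal(a, b)

    def test_unknown_feature_errors(self, flat_cohort):
        cohort, _ = flat_cohort
        with pytest.raises(ValueError, match="ghost"):
            resampled_auc(cohort, ["ghost"], EvalConfig(seed=0))

    def test_informative_panel_dominates_null(self, flat_cohort):
        cohort, truth = flat_cohort
        cfg = EvalConfig(n_resamples=150, n_permutation_resamples=150, seed=3)
        res = evaluate_panel(cohort, truth.markers, cfg)
        assert res.real_mean > res.permuted_mean + 0.15
        assert res.p_value < 0.01
        # stochastic dominance at the quartiles
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(res.real_aucs, q) > np.quantile(res.permuted_aucs, q)
        assert res.ci[0] <= res.real_mean <= res.ci[1]


class TestNestedPanelAuc:
    def test_nested_reselection_runs_and_is_seeded(self, flat_cohort):
        from traumapanel import SelectionConfig, nested_panel_auc

        cohort, truth = flat_cohort
        sel = SelectionConfig(n_iterations=3, cv_folds=4, alphas=(1.0,))
        cfg = EvalConfig(n_resamples=6, n_permutation_resamples=6, seed=11)
        aucs, panels = nested_panel_auc(cohort, sel, cfg)
        aucs2, panels2 = nested_panel_auc(cohort, sel, cfg)
        np.testing.assert_array_equal(aucs, aucs2)
        assert panels == panels2
        assert len(aucs) == 6 and np.all((aucs >= 0) & (aucs <= 1))
        # a strong planted signal keeps showing up inside training folds
        assert any(set(truth.markers) & set(p) for p in panels)


class TestUnivariatePanel:
    def test_single_feature_panel_coincides(self, flat_cohort):
        cohort, truth = flat_cohort
        cfg = EvalConfig(n_resamples=60, n_permutation_resamples=60, seed=7)
        uni, multi, dumbbell = univariate_panel(cohort, truth.markers[:1], cfg)
        assert uni[0].real_mean == pytest.approx(multi.real_mean)
        assert len(dumbbell) == 2  # the feature and the multivariate row

    def test_marker_beats_noise(self, flat_cohort):
        cohort, truth = flat_cohort
        noise = [f for f in cohort.data.columns if f not in truth.markers][0]
        cfg = EvalConfig(n_resamples=100, n_permutation_resamples=100, seed=8)
        uni, multi, _ = univariate_panel(cohort, [truth.markers[0], noise], cfg)
        assert uni[0].real_mean > uni[1].real_mean
        imp = improvement_pp(multi, uni[1])
        assert imp > 0  # the panel improves on the noise feature, in pp

    def test_empty_panel_errors(self, flat_cohort):
        cohort, _ = flat_cohort
        with pytest.raises(ValueError):
            univariate_panel(cohort, [], EvalConfig(seed=0))


class TestTimepointGroupTest:
    def test_identical_samples_p_one(self, rng):
        x = rng.standard_normal(25)
        out = timepoint_group_test({"t1": x, "t2": x.copy()})
        assert out["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_separated_groups(self, rng):
        out = timepoint_group_test(
            {"t1": rng.standard_normal(30), "t2": rng.standard_normal(30) + 3.0}
        )
        assert out["p_value"].iloc[0] < 1e-6

    def test_symmetric_in_group_order(self, rng):
        a, b = rng.standard_normal(15), rng.standard_normal(15) + 1
        p1 = timepoint_group_test({"x": a, "y": b})["p_value"].iloc[0]
        p2 = timepoint_group_test({"y": b, "x": a})["p_value"].iloc[0]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_group_marked_nan(self):
        out = timepoint_group_test({"t1": np.array([1.0]), "t2": np.zeros(5)})
        assert np.isnan(out["p_value"].iloc[0])

    def test_pairwise_over_three_groups(self, rng):
        out = timepoint_group_test(
            {"t1": rng.standard_normal(10), "t2": rng.standard_normal(10), "t3": rng.standard_normal(10)}
        )
        assert len(out) == 3
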