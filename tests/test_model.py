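"""Logistic fitting, AUC, model selection and LOOCV against independent
oracles (exhaustive pair counting, closed forms, scipy-minimize MLE,
statsmodels and scikit-learn cross-checks)."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from fragscore.datatypes import PREDEFINED_MODELS, ModelSpec
from fragscore.model import (
    ProgressionScoreModel,
    auc,
    evaluate_models,
    fit_logistic,
    loocv_auc,
    loocv_predictions,
    select_best,
)

SPEC_X = ModelSpec("x", ("FragDiff",))


def pair_counting_auc(scores, labels):
    """Brute force over all case-control pairs; ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def mle_oracle(x, y):
    """Independent logistic MLE: direct minimization of the negative
    log-likelihood (BFGS), no IRLS."""
    X = np.column_stack([np.ones(len(y)), x])

    def nll(beta):
        eta = X @ beta
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS")
    return res.x


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    @pytest.mark.parametrize(
        "labels,expected", [((0, 0, 1, 1), 1.0), ((0, 1, 0, 1), 0.75)]
    )
    def test_hand_counted_pairs(self, labels, expected):
        assert auc([1, 2, 3, 4], labels) == expected

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    @given(st.data())
    @settings(deadline=None, max_examples=200)
    def test_matches_pair_counting_oracle(self, data):
        n = data.draw(st.integers(min_value=2, max_value=12))
        scores = data.draw(
            st.lists(st.integers(min_value=0, max_value=5), min_size=n, max_size=n)
        )
        labels = data.draw(
            st.lists(st.integers(min_value=0, max_value=1), min_size=n, max_size=n)
        )
        if 0 < sum(labels) < n:
            assert auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        s = rng.normal(size=100)
        y = (rng.random(100) < expit(s)).astype(int)
        assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def _df(x):
    return pd.DataFrame({"FragDiff": np.asarray(x, dtype=float)})


class TestFitLogistic:
    def test_matches_2x2_log_odds_closed_form(self):
        # binary predictor: slope = log((a/b)/(c/d)) from the 2x2 table
        x = [1] * 30 + [0] * 70
        y = np.array([1] * 20 + [0] * 10 + [1] * 21 + [0] * 49, dtype=float)
        a, b = 20, 10  # cases/controls with x=1
        c, d = 21, 49  # cases/controls with x=0
        fit = fit_logistic(_df(x), y, SPEC_X)
        assert fit.coefficients["FragDiff"] == pytest.approx(
            math.log((a / b) / (c / d)), abs=1e-6
        )
        assert fit.coefficients["Intercept"] == pytest.approx(
            math.log(c / d), abs=1e-6
        )

    def test_matches_scipy_minimize_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = (rng.random(300) < expit(-0.5 + 1.2 * x)).astype(float)
        fit = fit_logistic(_df(x), y, SPEC_X)
        beta = mle_oracle(x, y)
        assert fit.coefficients["Intercept"] == pytest.approx(beta[0], abs=1e-5)
        assert fit.coefficients["FragDiff"] == pytest.approx(beta[1], abs=1e-5)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        x1 = rng.normal(size=250)
        x2 = rng.normal(size=250)
        y = (rng.random(250) < expit(0.3 + x1 - 0.8 * x2)).astype(float)
        feats = pd.DataFrame({"MMDiff": x1, "FragDiff": x2})
        fit = fit_logistic(feats, y, ModelSpec("m", ("MMDiff", "FragDiff")))
        ref = sm.Logit(y, sm.add_constant(feats[["MMDiff", "FragDiff"]])).fit(disp=0)
        assert fit.coefficients["Intercept"] == pytest.approx(ref.params["const"], abs=1e-6)
        assert fit.coefficients["MMDiff"] == pytest.approx(ref.params["MMDiff"], abs=1e-6)
        assert fit.coefficients["FragDiff"] == pytest.approx(ref.params["FragDiff"], abs=1e-6)
        assert fit.std_errors["FragDiff"] == pytest.approx(ref.bse["FragDiff"], rel=1e-4)
        assert fit.p_values["FragDiff"] == pytest.approx(ref.pvalues["FragDiff"], abs=1e-6)

    def test_null_predictor_not_significant(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=200)
        y = (rng.random(200) < 0.3).astype(float)  # independent of x
        fit = fit_logistic(_df(x), y, SPEC_X)
        assert fit.p_values["FragDiff"] > 0.05

    def test_parameter_recovery_single_fit(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=2000)
        y = (rng.random(2000) < expit(-1.0 + 2.0 * x)).astype(float)
        fit = fit_logistic(_df(x), y, SPEC_X)
        assert fit.coefficients["Intercept"] == pytest.approx(-1.0, abs=0.2)
        assert fit.coefficients["FragDiff"] == pytest.approx(2.0, abs=0.2)
        assert fit.converged

    def test_single_class_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_logistic(_df([1, 2, 3]), np.ones(3), SPEC_X)

    def test_separation_flagged_not_fatal(self):
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        fit = fit_logistic(_df(x), y, SPEC_X)
        assert fit.separation_flag
        assert fit.training_auc == 1.0

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            fit_logistic(
                _df([1.0, np.nan, 3.0, 4.0]), np.array([0, 1, 0, 1.0]), SPEC_X
            )


class TestEvaluateAndSelect:
    def test_six_rows_always_returned(self, default_cohort):
        *_, feats, labels = default_cohort
        table = evaluate_models(feats, labels)
        assert len(table) == 6
        assert [f.spec.name for f in table] == [m.name for m in PREDEFINED_MODELS]

    def test_bonferroni_multiplier_is_six(self, default_cohort):
        *_, feats, labels = default_cohort
        for f in evaluate_models(feats, labels):
            assert f.bonferroni_adjusted_p == pytest.approx(
                min(1.0, 6 * f.model_p_value)
            )

    def test_nested_training_auc_property(self, default_cohort):
        # adding MMDiff to FragDiff can only help the training fit
        *_, feats, labels = default_cohort
        table = {f.spec.name: f for f in evaluate_models(feats, labels)}
        assert (
            table["MMDiff + FragDiff"].training_auc
            >= table["FragDiff"].training_auc - 1e-9
        )

    def test_fragdiff_models_dominate_when_only_fragdiff_matters(self):
        rng = np.random.default_rng(2)
        n = 400
        fd = rng.normal(size=n)
        feats = pd.DataFrame(
            {
                "FragDiff": fd,
                "Frag1": rng.normal(size=n),
                "SM1": rng.normal(size=n),
                "MMDiff": rng.normal(size=n),
            }
        )
        y = (rng.random(n) < expit(-1.5 + 2.5 * fd)).astype(float)
        table = {f.spec.name: f for f in evaluate_models(feats, y)}
        assert table["FragDiff"].training_auc > 0.8
        for f in table.values():
            assert f.training_auc >= table["FragDiff"].training_auc - 0.02

    def test_row_error_does_not_abort_others(self):
        feats = pd.DataFrame(
            {"FragDiff": [1.0, 2.0, 3.0, 4.0], "MMDiff": [1.0, 2.0, 1.0, 2.0],
             "Frag1": [np.nan] * 4, "SM1": [1.0, 1.0, 2.0, 2.0]}
        )
        y = np.array([0, 1, 0, 1], dtype=float)
        table = evaluate_models(feats, y)
        errs = [f for f in table if f.error is not None]
        assert 0 < len(errs) < 6

    def test_parsimony_on_flag_vs_highest_auc(self, default_cohort):
        # construct the documented situation: a 3-predictor model edges out
        # the 2-predictor one on training AUC but its extra predictor is
        # not significant
        from dataclasses import replace
        *_, feats, labels = default_cohort
        table = evaluate_models(feats, labels)
        aucs = (0.80, 0.85, 0.91, 0.934, 0.936, 0.934)
        doctored = []
        for f, a, flag in zip(table, aucs, (False, False, False, False, True, True)):
            pv = dict(f.p_values)
            for p in f.spec.predictors:
                pv[p] = 0.001
            if flag:
                pv[f.spec.predictors[0]] = 0.5  # Frag1/SM1 not significant
            doctored.append(replace(f, training_auc=a, p_values=pv, error=None))
        assert select_best(doctored, selection="highest-auc").spec.name == (
            "Frag1 + MMDiff + FragDiff"
        )
        assert select_best(doctored, selection="parsimony-on-flag").spec.name == (
            "MMDiff + FragDiff"
        )

    def test_tie_break_prefers_fewer_predictors(self, default_cohort):
        from dataclasses import replace
        *_, feats, labels = default_cohort
        table = evaluate_models(feats, labels)
        tied = []
        for f in table:
            pv = {k: 0.001 for k in f.p_values}
            tied.append(replace(f, training_auc=0.9, p_values=pv))
        best = select_best(tied, selection="highest-auc")
        assert best.spec.name == "FragDiff"

    def test_single_model_returns_itself(self, default_cohort):
        *_, feats, labels = default_cohort
        table = evaluate_models(feats, labels, specs=PREDEFINED_MODELS[:1])
        assert select_best(table).spec.name == "FragDiff"

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            select_best([])


class TestLoocv:
    def test_matches_hand_rolled_six_fits(self):
        """n=6 fixture: each fold refit with the scipy-minimize oracle."""
        x = np.array([1.0, 2.0, 3.0, 2.5, 3.5, 5.0])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        feats = _df(x)
        preds_oracle = []
        for i in range(6):
            mask = np.arange(6) != i
            beta = mle_oracle(x[mask], y[mask])
            preds_oracle.append(expit(beta[0] + beta[1] * x[i]))
        expected = pair_counting_auc(preds_oracle, y)
        assert loocv_auc(feats, y, SPEC_X) == pytest.approx(expected, abs=1e-6)

    def test_null_predictors_give_chance_auc(self):
        rng = np.random.default_rng(3)
        n = 200
        feats = _df(rng.normal(size=n))
        y = (rng.random(n) < 0.3).astype(float)
        assert 0.4 <= loocv_auc(feats, y, SPEC_X) <= 0.6

    def test_patient_order_invariance(self, default_cohort):
        *_, feats, labels = default_cohort
        spec = PREDEFINED_MODELS[3]
        base = loocv_auc(feats, labels, spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(labels))
        shuffled = loocv_auc(
            feats.iloc[perm].reset_index(drop=True), labels[perm], spec
        )
        assert shuffled == pytest.approx(base, abs=1e-12)

    def test_single_class_fold_uses_prevalence_and_flags(self):
        # one lone case: its fold trains on controls only
        x = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 5.0])
        y = np.zeros(10)
        y[-1] = 1.0
        preds, flagged = loocv_predictions(_df(x), y, SPEC_X)
        assert flagged == [9]
        assert preds[9] == pytest.approx(0.0)

    def test_loocv_optimism_in_expectation(self):
        """Strong signal: mean LOOCV AUC does not exceed mean training AUC
        over repeated simulations (optimism is non-negative in aggregate)."""
        rng = np.random.default_rng(12)
        train_aucs, cv_aucs = [], []
        for _ in range(40):
            n = 60
            x = rng.normal(size=n)
            y = (rng.random(n) < expit(1.5 * x)).astype(float)
            if y.sum() in (0, n):
                continue
            feats = _df(x)
            fit = fit_logistic(feats, y, SPEC_X)
            train_aucs.append(fit.training_auc)
            cv_aucs.append(loocv_auc(feats, y, SPEC_X))
        assert np.mean(cv_aucs) <= np.mean(train_aucs)


class TestModelResultsApi:
    def test_fit_and_summary(self, default_cohort):
        *_, feats, labels = default_cohort
        res = ProgressionScoreModel(feats, labels).fit()
        text = res.summary()
        assert "Selected:" in text and "LOOCV AUC" in text
        assert res.selected.loocv_auc is not None
        assert 0.0 <= res.training_auc <= 1.0
        probs = res.predict()
        assert probs.shape == (len(labels),)
        ps = res.progression_scores()
        assert ps.min() >= 0.0 and ps.max() <= 100.0

    def test_from_dataframe(self, default_cohort):
        *_, feats, labels = default_cohort
        df = feats.copy()
        df["progressed"] = labels
        res = ProgressionScoreModel.from_dataframe(df).fit(compute_loocv=False)
        assert len(res.model_table()) == 6


def test_parameter_recovery_low_bias_over_replicates():
    """Mean coefficient bias < 5% over replicated simulated cohorts."""
    rng = np.random.default_rng(99)
    est = []
    for _ in range(60):
        x = rng.normal(size=2000)
        y = (rng.random(2000) < expit(-1.0 + 2.0 * x)).astype(float)
        fit = fit_logistic(_df(x), y, SPEC_X)
        est.append([fit.coefficients["Intercept"], fit.coefficients["FragDiff"]])
    mean = np.mean(est, axis=0)
    assert abs(mean[0] - (-1.0)) / 1.0 < 0.05
    assert abs(mean[1] - 2.0) / 2.0 < 0.05
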