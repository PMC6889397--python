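import numpy as np
import pandas as pd
import pytest
from lifelines.utils import concordance_index
from scipy import integrate, optimize, stats

import nbstrat as nb
from nbstrat.exceptions import DegenerateDataError, ParameterError
from nbstrat.survival import (
    SurvivalData,
    cox_partial_loglik,
    evaluations_to_frame,
    truncated_normal_mean,
)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = nb.km_estimate(SurvivalData([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert curve.at(0.5) == 1.0
        assert curve.at(1.0) == pytest.approx(2 / 3)

    def test_product_limit_with_censoring(self):
        # times (1,2,3), events (1,0,1): S(1)=2/3, S(3)=0
        curve = nb.km_estimate(SurvivalData([1, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])

    def test_no_events_flat_at_one(self):
        curve = nb.km_estimate(SurvivalData([1, 2, 3], [0, 0, 0]))
        assert curve.at(10.0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(DegenerateDataError):
            nb.km_estimate(SurvivalData([], []))


class TestLogrank:
    def test_identical_groups_null(self):
        surv = SurvivalData([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        stat, p, df = nb.logrank_test(surv, [0, 0, 0, 1, 1, 1])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_hand_computed_statistic(self):
        # A events at 1,2; B events at 3,4.  By hand:
        # t=1: risk {1,2,3,4}, E_A += 2/4, V += 2*2/16 = 1/4
        # t=2: risk {2,3,4},   E_A += 1/3, V += 1*2/9  = 2/9
        # t=3,4: no A at risk -> no contribution
        # O_A = 2, so chi2 = (2 - 5/6)^2 / (1/4 + 2/9) = 49/17
        surv = SurvivalData([1, 2, 3, 4], [1, 1, 1, 1])
        stat, p, df = nb.logrank_test(surv, ["A", "A", "B", "B"])
        assert stat == pytest.approx(49 / 17, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(49 / 17, 1))

    def test_three_groups_df(self):
        surv = SurvivalData([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])
        _, _, df = nb.logrank_test(surv, [0, 0, 1, 1, 2, 2])
        assert df == 2

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            nb.logrank_test(SurvivalData([1, 2], [1, 1]), [0, 0])


def separation_data():
    """Complete separation: all events in arm 1, earliest follow-up too."""
    x = np.r_[np.ones(10), np.zeros(10)]
    time = np.r_[np.arange(1.0, 11.0), np.arange(11.0, 21.0)]
    event = np.r_[np.ones(10, int), np.zeros(10, int)]
    return x, SurvivalData(time, event)


class TestCoxFirth:
    def test_constant_column_rejected(self):
        _, surv = separation_data()
        with pytest.raises(DegenerateDataError):
            nb.cox_firth_fit(np.ones(20), surv)

    def test_no_events_rejected(self):
        with pytest.raises(DegenerateDataError):
            nb.cox_firth_fit(np.r_[np.ones(3), np.zeros(3)], SurvivalData([1] * 6, [0] * 6))

    def test_finite_under_separation(self):
        x, surv = separation_data()
        fit = nb.cox_firth_fit(x, surv)
        assert abs(fit.beta[0]) < 10
        assert fit.converged
        assert fit.ci_low[0] < fit.hr[0] < fit.ci_high[0]

    def test_unpenalized_likelihood_is_monotone_under_separation(self):
        x, surv = separation_data()
        lls = [cox_partial_loglik(x, surv, [b]) for b in (5.0, 10.0, 20.0, 25.0)]
        assert np.all(np.diff(lls) > 0)  # no finite maximizer

    def test_matches_unpenalized_oracle_asymptotically(self):
        # large n, moderate censoring: the Firth penalty washes out
        rng = np.random.default_rng(5)
        n = 1000
        x = rng.normal(size=n)
        beta_true = 0.7
        event_t = rng.exponential(1.0 / (0.01 * np.exp(beta_true * x)))
        censor_t = rng.exponential(1.0 / 0.004, size=n)  # ~30% censoring
        surv = SurvivalData(np.minimum(event_t, censor_t), (event_t <= censor_t).astype(int))
        fit = nb.cox_firth_fit(x, surv)
        oracle = optimize.minimize_scalar(
            lambda b: -cox_partial_loglik(x, surv, [b]), bounds=(-5, 5), method="bounded"
        )
        assert abs(fit.beta[0] - oracle.x) < 0.1
        assert abs(fit.beta[0] - beta_true) < 0.2


class TestBic:
    def test_hand_value(self):
        assert nb.bic_of_fit(-100.0, 2, 100) == pytest.approx(209.2103, abs=1e-3)

    def test_zero_parameters(self):
        assert nb.bic_of_fit(-50.0, 0, 10) == 100.0

    def test_extra_parameter_costs_log_n(self):
        n = 37
        delta = nb.bic_of_fit(-10.0, 3, n) - nb.bic_of_fit(-10.0, 2, n)
        assert delta == pytest.approx(np.log(n))


class TestAftImputed:
    def test_no_censoring_reduces_to_ols(self, rng):
        X = rng.normal(size=(50, 2))
        logt = 3.0 + X @ np.array([0.5, -0.2]) + rng.normal(0, 0.3, 50)
        surv = SurvivalData(np.exp(logt), np.ones(50, int))
        fit = nb.aft_fit_imputed(X, surv)
        design = np.column_stack([np.ones(50), X])
        ols, *_ = np.linalg.lstsq(design, logt, rcond=None)
        np.testing.assert_allclose(np.r_[fit.intercept, fit.coef], ols, atol=1e-10)

    def test_truncated_mean_matches_quadrature(self):
        mu, sigma, lower = 1.3, 0.7, 2.0
        ours = truncated_normal_mean(mu, sigma, lower)
        num, _ = integrate.quad(
            lambda y: y * stats.norm.pdf(y, mu, sigma), lower, np.inf
        )
        den = stats.norm.sf((lower - mu) / sigma)
        assert float(ours) == pytest.approx(num / den, abs=1e-4)

    def test_imputed_times_respect_censoring_bounds(self, rng):
        X = rng.normal(size=(80, 1))
        logt = 4.0 + 0.8 * X[:, 0] + rng.normal(0, 0.5, 80)
        logc = 4.0 + rng.normal(0, 0.8, 80)
        t = np.exp(np.minimum(logt, logc))
        e = (logt <= logc).astype(int)
        surv = SurvivalData(t, e)
        fit = nb.aft_fit_imputed(X, surv)
        cens = e == 0
        assert np.all(fit.imputed_times[cens] >= t[cens] * (1 - 1e-12))
        assert fit.sigma > 0

    def test_too_few_events_rejected(self, rng):
        surv = SurvivalData([1.0, 2.0, 3.0], [1, 0, 0])
        with pytest.raises(DegenerateDataError):
            nb.aft_fit_imputed(rng.normal(size=(3, 1)), surv)


class TestCensoredRmse:
    def test_perfect_predictions_zero(self):
        surv = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1])
        assert nb.censored_rmse(np.array([1.0, 2.0, 3.0]), surv) == 0.0

    def test_censored_above_bound_free(self):
        surv = SurvivalData([5.0], [0])
        assert nb.censored_rmse(np.array([100.0]), surv) == 0.0

    def test_hand_case(self):
        # event (T=e^2, pred=e^1): (2-1)^2; censored (c=e^1, pred=e^0): (1-0)^2
        surv = SurvivalData([np.e**2, np.e], [1, 0])
        rmse = nb.censored_rmse(np.array([np.e, 1.0]), surv)
        assert rmse == pytest.approx(1.0, rel=1e-10)

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(Exception):
            nb.censored_rmse(np.array([0.0]), SurvivalData([1.0], [1]))


class TestHarrellC:
    def test_perfect_inverted_tied(self):
        surv = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1])
        assert nb.harrell_c(np.array([3.0, 2.0, 1.0]), surv) == 1.0
        assert nb.harrell_c(np.array([1.0, 2.0, 3.0]), surv) == 0.0
        assert nb.harrell_c(np.array([1.0, 1.0, 1.0]), surv) == 0.5

    def test_complement_property_without_ties(self, rng):
        t = rng.exponential(1.0, 50)
        e = rng.integers(0, 2, 50)
        e[0] = 1
        risk = rng.normal(size=50)
        surv = SurvivalData(t, e)
        assert nb.harrell_c(risk, surv) + nb.harrell_c(-risk, surv) == pytest.approx(1.0)

    def test_matches_lifelines(self, rng):
        t = rng.exponential(1.0, 60)
        e = rng.integers(0, 2, 60)
        e[:5] = 1
        risk = rng.normal(size=60)
        surv = SurvivalData(t, e)
        ours = nb.harrell_c(risk, surv)
        ref = concordance_index(t, -risk, e)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(DegenerateDataError):
            nb.harrell_c(np.array([1.0, 2.0]), SurvivalData([1.0, 2.0], [0, 0]))


class TestCvEvaluate:
    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 2))
        logt = 4.0 + X[:, 0] + rng.normal(0, 0.5, 60)
        logc = 4.0 + rng.normal(0, 1.0, 60)
        surv = SurvivalData(
            np.exp(np.minimum(logt, logc)), (logt <= logc).astype(int)
        )
        out1 = nb.cv_evaluate(X, surv, folds=5, repeats=2, seed=11)
        out2 = nb.cv_evaluate(X, surv, folds=5, repeats=2, seed=11)
        assert out1 == out2

    def test_too_few_samples_rejected(self, rng):
        surv = SurvivalData([1.0, 2.0], [1, 1])
        with pytest.raises(ParameterError):
            nb.cv_evaluate(rng.normal(size=(2, 1)), surv, folds=5)


def synthetic_clinical(n, rng, assignment):
    """Clinical table whose survival depends on the given assignment."""
    lam = np.where(assignment == 1, 5.0, 1.0) / 2000.0
    t = rng.exponential(1.0 / lam)
    c = rng.exponential(2000.0, n)
    time = np.maximum(np.minimum(t, c), 1e-3)
    event = (t <= c).astype(int)
    df = pd.DataFrame(
        {
            "os_event": event,
            "os_time": time,
            "efs_event": event,
            "efs_time": time,
            "high_risk": assignment,
            "mycn_amplified": pd.array(assignment, dtype="Int64"),
            "age": rng.uniform(100, 2000, n),
            "stage": rng.integers(1, 5, n),
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )
    return nb.ClinicalTable(df), SurvivalData(time, event)


class TestCompareStratifications:
    def test_candidate_equal_to_baseline_duplicates_row(self, rng):
        clin, surv = synthetic_clinical(120, rng, rng.integers(0, 2, 120))
        hr = clin.data["high_risk"].to_numpy(int)
        rows = nb.compare_stratifications(
            [("copy", hr)], clin, surv, folds=5, repeats=2, seed=0
        )
        by = {r.model_label: r for r in rows}
        assert by["copy"].hr == pytest.approx(by["High Risk / Low Risk"].hr)
        assert by["copy"].bic == pytest.approx(by["High Risk / Low Risk"].bic)
        assert by["copy"].c_index == pytest.approx(by["High Risk / Low Risk"].c_index)

    def test_k3_uses_reference_coding(self, rng):
        assignment = rng.integers(0, 3, 150)
        clin, surv = synthetic_clinical(150, rng, (assignment > 0).astype(int))
        rows = nb.compare_stratifications(
            [("k3", assignment)], clin, surv, folds=5, repeats=1, seed=0,
            include_risk_baseline=False,
        )
        assert rows[0].k == 3
        # two cluster indicators + age + stage
        X, k = nb.survival._stratification_design(assignment, clin)
        assert X.shape[1] == 4

    def test_constant_assignment_skipped_with_warning(self, rng):
        clin, surv = synthetic_clinical(60, rng, rng.integers(0, 2, 60))
        with pytest.warns(UserWarning, match="constant"):
            rows = nb.compare_stratifications(
                [("flat", np.zeros(60, int))], clin, surv,
                folds=5, repeats=1, include_risk_baseline=False,
            )
        assert rows == []

    def test_table_shape(self, rng):
        clin, surv = synthetic_clinical(100, rng, rng.integers(0, 2, 100))
        rows = nb.compare_stratifications([], clin, surv, folds=5, repeats=1)
        frame = evaluations_to_frame(rows)
        assert list(frame.columns) == [
            "Data", "k", "HR (confidence interval)", "Wald-test p-value",
            "BIC", "rmse", "c-index",
        ]
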