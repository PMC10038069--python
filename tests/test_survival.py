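"""Survival modeling: hand-worked product-limit and concordance oracles,
Cox parameter recovery, the nomogram affine identity, and the estimator
identities of the IPCW AUC and decision-curve references."""

import numpy as np
import pandas as pd
import pytest

from immunobud import survival
from immunobud.survival import (
    CoxFit,
    build_nomogram,
    calibration_curve,
    concordance_index,
    cox_fit,
    decision_curve,
    integrated_profile_score,
    km_estimate,
    logrank_test,
    time_dependent_roc,
)


def rec(times, events):
    return pd.DataFrame({"time": times, "event": events})


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        km = km_estimate(rec([3, 5, 8], [0, 0, 0]))
        assert (km.survival == 1.0).all()
        assert np.isnan(km.median)

    def test_two_subjects_one_event(self):
        km = km_estimate(rec([1.0, 2.0], [1, 0]))
        assert km.at(1.5) == pytest.approx(0.5)

    def test_hand_worked_product_limit(self):
        # times 1,2,3 events; censor at 2.5; death at 4:
        # S(1)=4/5*... enumerated by hand below
        km = km_estimate(rec([1, 2, 2.5, 3, 4], [1, 1, 0, 1, 1]))
        assert km.at(1) == pytest.approx(4 / 5)
        assert km.at(2) == pytest.approx(4 / 5 * 3 / 4)
        assert km.at(3) == pytest.approx(4 / 5 * 3 / 4 * 1 / 2)
        assert km.at(4) == pytest.approx(0.0)
        assert km.median == pytest.approx(3.0)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            km_estimate(rec([0.0, 1.0], [1, 1]))


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        records = rec([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        stat, p = logrank_test(["a", "a", "a", "b", "b", "b"], records)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test(["a", "a"], rec([1, 2], [1, 1]))

    def test_agrees_with_cox_score_test_oracle(self):
        # for one binary covariate the Cox score test at beta=0 IS the
        # log-rank statistic; enumerate it directly over event times
        rng = np.random.default_rng(0)
        n = 120
        x = rng.integers(0, 2, n)
        t = rng.exponential(10, n) * np.exp(-0.7 * x)
        records = rec(t, np.ones(n, dtype=int))
        u = v = 0.0
        order = np.argsort(t)
        for k, i in enumerate(order):
            at_risk = order[k:]
            xbar = x[at_risk].mean()
            m = len(at_risk)
            u += x[i] - xbar
            v += np.var(x[at_risk]) * m / max(m - 1, 1) * (m - 1) / m if m > 1 else 0.0
        chi2_oracle = u**2 / v
        stat, _ = logrank_test(np.where(x == 1, "hi", "lo"), records)
        assert stat == pytest.approx(chi2_oracle, rel=1e-6)


class TestCoxFit:
    def test_constant_covariate_rejected(self):
        X = pd.DataFrame({"a": np.ones(30), "b": np.arange(30.0)})
        records = rec(np.arange(1.0, 31.0), np.ones(30, dtype=int))
        with pytest.raises(ValueError, match="constant"):
            cox_fit(X, records, ["a", "b"])

    def test_collinear_pair_named(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=40)})
        X["b"] = 2 * X["a"]
        records = rec(rng.exponential(5, 40) + 0.1, np.ones(40, dtype=int))
        with pytest.raises(ValueError, match="'a' and 'b'"):
            cox_fit(X, records, ["a", "b"])

    def test_recovers_known_hazard_ratio(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0, n) / np.exp(np.log(2) * x)
        fit = cox_fit(pd.DataFrame({"x": x}), rec(t, np.ones(n, dtype=int)), ["x"])
        beta, se = fit.coefficients["x"], fit.standard_errors["x"]
        assert abs(beta - np.log(2)) < 3 * se
        assert fit.summary.loc["x", "HR_low"] < 2.0 < fit.summary.loc["x", "HR_high"]


def _two_factor_fit(n=300, seed=4):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "cd8_cd133_index": rng.lognormal(np.log(3.3), 0.5, n),
            "cd8_tb_index": rng.lognormal(np.log(3.7), 0.5, n),
        }
    )
    lp = -0.3 * X["cd8_cd133_index"] - 0.25 * X["cd8_tb_index"]
    t = rng.exponential(1.0, n) / np.exp(lp - lp.mean())
    records = rec(t * 12, np.ones(n, dtype=int))
    return cox_fit(X, records, list(X.columns)), X, records


class TestNomogram:
    def test_single_binary_factor_spans_0_to_100(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 200).astype(float)
        t = rng.exponential(1.0, 200) / np.exp(0.8 * x)
        fit = cox_fit(pd.DataFrame({"x": x}), rec(t, np.ones(200, dtype=int)), ["x"])
        nomo = build_nomogram(fit, {"x": (0.0, 1.0)})
        assert nomo.factor_points("x", 0.0) == pytest.approx(0.0)
        assert nomo.factor_points("x", 1.0) == pytest.approx(100.0)

    def test_protective_factor_gains_points_as_value_falls(self):
        fit, X, _ = _two_factor_fit()
        ranges = {f: (X[f].min(), X[f].max()) for f in fit.factors}
        nomo = build_nomogram(fit, ranges)
        f = "cd8_tb_index"
        assert nomo.factor_points(f, X[f].max()) == pytest.approx(0.0)
        assert nomo.factor_points(f, X[f].min()) > 0

    def test_round_trip_points_to_lp_is_exact(self):
        fit, X, _ = _two_factor_fit()
        ranges = {f: (X[f].min(), X[f].max()) for f in fit.factors}
        nomo = build_nomogram(fit, ranges)
        lp = fit.linear_predictor(X)
        pts = nomo.total_points(X)
        np.testing.assert_allclose(nomo.lp_from_points(pts), lp, atol=1e-9)
        np.testing.assert_allclose(nomo.points_from_lp(lp), pts, atol=1e-9)

    def test_points_survival_matches_direct_cox_prediction(self):
        fit, X, records = _two_factor_fit()
        ranges = {f: (X[f].min(), X[f].max()) for f in fit.factors}
        nomo = build_nomogram(fit, ranges)
        horizon = float(np.median(records["time"]))
        direct = fit.predict_survival(X.iloc[:100], horizon)
        via_points = nomo.survival_from_points(nomo.total_points(X.iloc[:100]), horizon)
        np.testing.assert_allclose(via_points, direct, atol=1e-6)

    def test_zero_range_factor_rejected(self):
        fit, X, _ = _two_factor_fit()
        with pytest.raises(ValueError, match="zero range"):
            build_nomogram(fit, {f: (1.0, 1.0) for f in fit.factors})


class TestIntegratedScore:
    def test_rank_correlation_with_linear_predictor_is_one(self):
        from scipy.stats import spearmanr

        fit, X, _ = _two_factor_fit()
        ranges = {f: (X[f].min(), X[f].max()) for f in fit.factors}
        nomo = build_nomogram(fit, ranges)
        score = integrated_profile_score(nomo, X)
        rho = spearmanr(score, fit.linear_predictor(X)).statistic
        assert rho == pytest.approx(1.0)

    def test_reference_values_score_zero_and_extremes_sum(self):
        fit, X, _ = _two_factor_fit()
        ranges = {f: (X[f].min(), X[f].max()) for f in fit.factors}
        nomo = build_nomogram(fit, ranges)
        refs = pd.DataFrame({f: [nomo.references[f]] for f in fit.factors})
        assert integrated_profile_score(nomo, refs)[0] == pytest.approx(0.0)
        extremes = pd.DataFrame(
            {
                f: [ranges[f][0] if nomo.references[f] == ranges[f][1] else ranges[f][1]]
                for f in fit.factors
            }
        )
        maxima = sum(
            abs(nomo.factor_points(f, extremes[f].iloc[0])) for f in fit.factors
        )
        assert integrated_profile_score(nomo, extremes)[0] == pytest.approx(maxima)

    def test_wrong_factor_set_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        fit = cox_fit(
            pd.DataFrame({"tnm_stage": x}),
            rec(rng.exponential(5, 100) + 0.1, np.ones(100, dtype=int)),
            ["tnm_stage"],
        )
        nomo = build_nomogram(fit, {"tnm_stage": (-3.0, 3.0)})
        with pytest.raises(ValueError, match="restricted"):
            integrated_profile_score(nomo, pd.DataFrame({"tnm_stage": [0.0]}))


class TestConcordance:
    def test_perfect_ranking_without_censoring(self):
        t = np.array([5.0, 3.0, 9.0, 1.0])
        c, _ = concordance_index(-t, t, np.ones(4, dtype=int))
        assert c == 1.0

    def test_three_patient_hand_enumeration(self):
        # usable pairs: (5,10), (5,15), (10,15) - all concordant
        c, _ = concordance_index([3, 2, 1], [5, 10, 15], [1, 1, 0])
        assert c == 1.0

    def test_matches_lifelines_on_censored_data(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(6)
        n = 300
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        s = rng.normal(size=n)
        ours, _ = concordance_index(s, t, e)
        theirs = ll_cindex(t, -s, e)  # lifelines expects predicted survival order
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, 100)
        e = rng.integers(0, 2, 100)
        s = rng.normal(size=100)
        c1, _ = concordance_index(s, t, e)
        c2, _ = concordance_index(np.exp(s), t, e)
        assert c1 == c2

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1, 2], [5, 5], [0, 0])


class TestTimeDependentROC:
    def test_perfect_score_gives_auc_one(self):
        t = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        records = rec(t, [1, 1, 1, 0, 0, 0])
        auc, _ = time_dependent_roc(-t, records, horizon=5.0)
        assert auc == 1.0

    def test_reduces_to_binary_auc_without_censoring(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        n = 400
        t = rng.exponential(10, n)
        s = -t + rng.normal(0, 5, n)
        records = rec(t, np.ones(n, dtype=int))
        horizon = 8.0
        auc, _ = time_dependent_roc(s, records, horizon)
        binary = roc_auc_score((t <= horizon).astype(int), s)
        assert auc == pytest.approx(binary, abs=1e-12)

    def test_uninformative_score_near_half(self):
        rng = np.random.default_rng(9)
        n = 1000
        t = rng.exponential(10, n)
        c = rng.uniform(0, 30, n)
        records = rec(np.minimum(t, c), (t <= c).astype(int))
        auc, _ = time_dependent_roc(rng.normal(size=n), records, horizon=8.0)
        assert abs(auc - 0.5) < 0.05

    def test_all_events_before_horizon_rejected(self):
        with pytest.raises(ValueError, match="survivors"):
            time_dependent_roc([1, 2], rec([1.0, 2.0], [1, 1]), horizon=5.0)


class TestCalibrationAndDecision:
    def test_constant_prediction_collapses_to_single_group(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(10, 100)
        records = rec(t, np.ones(100, dtype=int))
        cal = calibration_curve(lambda X: np.full(len(X), 0.5), pd.DataFrame(index=range(100)), records, horizon=5.0)
        assert len(cal) == 1
        assert cal.observed.iloc[0] == pytest.approx(np.mean(t > 5.0), abs=0.001)

    def test_horizon_beyond_followup_rejected(self):
        records = rec([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="horizon"):
            calibration_curve(lambda X: np.array([0.5, 0.5]), pd.DataFrame(index=range(2)), records, 10.0)

    def test_treat_all_limit_approaches_event_rate(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(10, 500)
        records = rec(t, np.ones(500, dtype=int))
        horizon = 8.0
        dc = decision_curve(np.full(500, 0.99), records, horizon, [0.01])
        event_rate = np.mean(t <= horizon)
        assert dc.treat_all.iloc[0] == pytest.approx(event_rate, abs=0.02)
        assert dc.net_benefit.iloc[0] == pytest.approx(dc.treat_all.iloc[0], abs=1e-9)

    def test_degenerate_thresholds_excluded_with_warning(self):
        records = rec([1.0, 2.0, 3.0], [1, 1, 0])
        with pytest.warns(UserWarning, match="excluded"):
            dc = decision_curve([0.5, 0.5, 0.5], records, 1.5, [0.0, 0.5, 1.0])
        assert list(dc.threshold) == [0.5]

    def test_true_model_dominates_noisy_model(self):
        rng = np.random.default_rng(12)
        n = 1500
        lp = rng.normal(0, 1.2, n)
        t = rng.exponential(1.0, n) / np.exp(lp) * 10
        records = rec(t, np.ones(n, dtype=int))
        horizon = 7.0
        # risks on the probability scale from the true generating model
        risk_true = 1 - np.exp(-np.exp(lp) * horizon / 10)
        noisy_lp = lp + rng.normal(0, 2.0, n)
        risk_noisy = 1 - np.exp(-np.exp(noisy_lp) * horizon / 10)
        thr = np.linspace(0.3, 0.7, 5)
        nb_true = decision_curve(risk_true, records, horizon, thr).net_benefit
        nb_noisy = decision_curve(risk_noisy, records, horizon, thr).net_benefit
        assert (nb_true.to_numpy() >= nb_noisy.to_numpy() - 0.01).all()
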