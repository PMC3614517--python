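import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from flexcif import CauseDGP, SimConfig, simulate, stack
from flexcif.fpm import FlexibleParametricSurvival, ModelSpec
from flexcif.splines import KnotVector

from conftest import manual_weibull_model


def _surv_frame(t, status, cause="event", **cov):
    d = pd.DataFrame({"time": t, "status": status, "cause": cause})
    for k, v in cov.items():
        d[k] = v
    return d


def weibull_mle_loglik(t, d):
    """Independent direct Weibull ML fit (oracle for the df=1 equivalence).

    Maximizes sum d*(ln lam + ln gam + (gam-1) ln t) - lam t^gam over
    (ln lam, ln gam) with Nelder-Mead; no spline machinery involved.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=bool)
    lt = np.log(t)

    def nll(p):
        lam, gam = np.exp(p)
        return -(np.sum(d * (p[0] + p[1] + (gam - 1) * lt)) - np.sum(lam * t**gam))

    res = minimize(nll, x0=[np.log(d.sum() / t.sum()), 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    return -res.fun


class TestLogLikelihoodClosedForms:
    """Single-subject exponential contributions have pencil-and-paper forms."""

    @pytest.mark.parametrize(
        "status, lam, t, expected",
        [
            (0, 0.7, 3.0, -0.7 * 3.0),                 # censored: -lam*t
            (1, 0.7, 3.0, np.log(0.7) - 0.7 * 3.0),    # event: ln lam - lam*t
            (1, 2.5, 0.4, np.log(2.5) - 2.5 * 0.4),
        ],
    )
    def test_exponential_single_subject(self, status, lam, t, expected):
        est = manual_weibull_model({"event": (lam, 1.0)})
        data = _surv_frame([t], [status])
        assert est.log_likelihood(data) == pytest.approx(expected, abs=1e-12)

    def test_stacked_two_cause_likelihood_is_additive(self):
        cfg = SimConfig(
            n=300,
            causes={"a": CauseDGP(rate=0.4), "b": CauseDGP(rate=0.2)},
            censoring=("uniform", 6.0),
            covariates=None,
            seed=7,
        )
        stacked = stack(simulate(cfg), ["a", "b"])
        joint = FlexibleParametricSurvival(df=1).fit(stacked)
        ll_sep = 0.0
        for k in ["a", "b"]:
            sub = stacked[stacked["cause"] == k]
            ll_sep += FlexibleParametricSurvival(df=1).fit(sub).log_likelihood_
        assert joint.log_likelihood_ == pytest.approx(ll_sep, abs=1e-8)

    def test_nonpositive_time_rejected(self):
        est = manual_weibull_model({"event": (1.0, 1.0)})
        with pytest.raises(ValueError, match="positive"):
            est.log_likelihood(_surv_frame([0.0], [1]))


class TestFit:
    def test_exponential_score_identity(self):
        # at the optimum the intercept score gives lam-hat = D / sum t^gam-hat
        cfg = SimConfig(n=3000, causes={"e": CauseDGP(rate=0.5)},
                        censoring=("uniform", 4.0), covariates=None, seed=11)
        data = stack(simulate(cfg), ["e"])
        est = FlexibleParametricSurvival(df=1).fit(data)
        lam_hat, gam_hat = np.exp(est.params_[0]), est.params_[1]
        t = data["time"].to_numpy()
        closed_form = data["status"].sum() / np.sum(t**gam_hat)
        assert lam_hat == pytest.approx(closed_form, rel=1e-4)
        # and the Weibull shape is consistent with the exponential truth
        se_gam = np.sqrt(est.vcov_[1, 1])
        assert abs(gam_hat - 1.0) < 3 * se_gam

    def test_df1_matches_direct_weibull_mle(self):
        cfg = SimConfig(n=2000, causes={"e": CauseDGP(family="weibull", rate=0.3, shape=1.4)},
                        censoring=("uniform", 5.0), covariates=None, seed=5)
        data = stack(simulate(cfg), ["e"])
        est = FlexibleParametricSurvival(df=1).fit(data)
        oracle = weibull_mle_loglik(data["time"], data["status"] == 1)
        assert est.log_likelihood_ == pytest.approx(oracle, abs=1e-6)

    def test_binary_covariate_recovery(self):
        cfg = SimConfig(
            n=10000,
            causes={
                "a": CauseDGP(family="weibull", rate=0.1, shape=1.2, log_hr={"x": np.log(2)}),
                "b": CauseDGP(rate=0.05),
            },
            censoring=("uniform", 12.0),
            covariates="binary",
            seed=42,
        )
        data = stack(simulate(cfg), ["a", "b"])
        est = FlexibleParametricSurvival(df=1, covariates=["x"]).fit(data)
        i = est.param_names_.index("a:x")
        se = np.sqrt(est.vcov_[i, i])
        assert abs(est.params_[i] - np.log(2)) < 3 * se

    def test_joint_stacked_fit_reproduces_separate_fits(self, two_cause_weibull_data):
        _, _, stacked = two_cause_weibull_data
        joint = FlexibleParametricSurvival(df=3).fit(stacked)
        for k in ["cancer", "other"]:
            sep = FlexibleParametricSurvival(df=3).fit(stacked[stacked["cause"] == k])
            sl = joint._slices_[k]
            np.testing.assert_allclose(joint.params_[sl], sep.params_, atol=1e-6)

    def test_covariate_rescaling_invariance(self):
        cfg = SimConfig(n=1500, causes={"a": CauseDGP(rate=0.3, log_hr={"x": 0.5})},
                        censoring=("uniform", 6.0), covariates="binary", seed=3)
        data = stack(simulate(cfg), ["a"])
        est1 = FlexibleParametricSurvival(df=2, covariates=["x"]).fit(data)
        rescaled = data.assign(x=2.0 * data["x"] + 1.0)
        est2 = FlexibleParametricSurvival(df=2, covariates=["x"]).fit(rescaled)
        assert est1.log_likelihood_ == pytest.approx(est2.log_likelihood_, abs=1e-6)
        i = est1.param_names_.index("a:x")
        assert est1.params_[i] == pytest.approx(2.0 * est2.params_[i], rel=1e-5)

    def test_aic_bic_formulas(self, two_cause_fit):
        est = two_cause_fit
        p = est.params_.size
        assert est.aic_ == pytest.approx(-2 * est.log_likelihood_ + 2 * p)
        assert est.bic_ == pytest.approx(-2 * est.log_likelihood_ + np.log(est.n_events_) * p)
        assert np.max(np.abs(est.vcov_ - est.vcov_.T)) < 1e-10

    def test_missing_events_for_cause_raises(self, table2_wide):
        stacked = stack(
            table2_wide,
            ["Breast Cancer", "Other Cancer", "Heart Disease", "Other Causes"],
        )
        with pytest.raises(ValueError, match="no events"):
            FlexibleParametricSurvival(df=1).fit(stacked)

    def test_missing_covariate_column_raises(self):
        data = _surv_frame([1.0, 2.0, 3.0], [1, 1, 0])
        with pytest.raises(ValueError, match="missing"):
            FlexibleParametricSurvival(df=1, covariates=["zzz"]).fit(data)

    def test_horizon_administratively_censors(self):
        cfg = SimConfig(n=500, causes={"a": CauseDGP(rate=0.2)},
                        covariates=None, seed=9)
        data = stack(simulate(cfg), ["a"])
        est = FlexibleParametricSurvival(df=1, horizon=5.0).fit(data)
        assert np.exp(est.spec_.baseline_knots["a"].knots[-1]) <= 5.0 + 1e-12


class TestPredict:
    def test_weibull_survival_and_hazard_closed_forms(self):
        lam, gam = 0.4, 1.7
        est = manual_weibull_model({"event": (lam, gam)})
        t = np.linspace(0.05, 8.0, 60)
        np.testing.assert_allclose(
            est.predict_survival("event", {}, t), np.exp(-lam * t**gam), rtol=1e-12)
        np.testing.assert_allclose(
            est.predict_hazard("event", {}, t), lam * gam * t ** (gam - 1), rtol=1e-12)

    def test_exponential_hazard_constant(self):
        est = manual_weibull_model({"event": (0.3, 1.0)})
        h = est.predict_hazard("event", {}, np.array([0.1, 1.0, 5.0, 20.0]))
        np.testing.assert_allclose(h, 0.3, rtol=1e-12)

    def test_eta_zero_gives_exp_minus_one(self):
        est = manual_weibull_model({"event": (1.0, 1.0)})  # eta = ln t, so t=1 -> eta=0
        assert est.predict_survival("event", {}, [1.0])[0] == pytest.approx(np.exp(-1))

    def test_survival_limits_and_monotonicity(self, two_cause_fit):
        t = np.geomspace(1e-8, 10.0, 200)
        S = two_cause_fit.predict_survival("cancer", {}, t)
        assert np.all(np.diff(S) <= 1e-12)
        assert S[0] == pytest.approx(1.0, abs=1e-6)
        assert np.all((S > 0) & (S <= 1))

    def test_hazard_matches_neg_dlogS_dt(self, two_cause_fit):
        t = np.linspace(0.5, 9.0, 40)
        h = two_cause_fit.predict_hazard("cancer", {}, t)
        eps = 1e-5
        S_hi = two_cause_fit.predict_survival("cancer", {}, t + eps)
        S_lo = two_cause_fit.predict_survival("cancer", {}, t - eps)
        num = -(np.log(S_hi) - np.log(S_lo)) / (2 * eps)
        np.testing.assert_allclose(h, num, rtol=1e-4)

    def test_ph_covariate_shift_is_uniform_in_time(self):
        kv = [np.log(0.1), np.log(20.0)]
        est = manual_weibull_model({"a": (0.2, 1.3)})
        est.spec_ = ModelSpec(
            cause_labels=["a"],
            baseline_knots={"a": KnotVector(kv)},
            covariates={"a": ["x"]},
        )
        beta = 0.8
        est.params_ = np.array([np.log(0.2), 1.3, beta])
        est.param_names_, est._slices_, _ = est._param_layout(est.spec_)
        t = np.linspace(0.5, 10, 30)
        eta0, _ = est.linear_predictor("a", {"x": 1.0}, t)
        eta1, _ = est.linear_predictor("a", {"x": 3.5}, t)
        np.testing.assert_allclose(eta1 - eta0, beta * 2.5, rtol=1e-12)

    def test_tvc_with_zero_delta_reduces_to_ph(self):
        kv = KnotVector([np.log(0.1), np.log(20.0)])
        ph = manual_weibull_model({"a": (0.2, 1.3)})
        ph.spec_ = ModelSpec(["a"], {"a": kv}, covariates={"a": ["x"]})
        ph.params_ = np.array([np.log(0.2), 1.3, 0.8])
        ph.param_names_, ph._slices_, _ = ph._param_layout(ph.spec_)

        tvc = manual_weibull_model({"a": (0.2, 1.3)})
        tvc.spec_ = ModelSpec(
            ["a"], {"a": kv}, covariates={"a": ["x"]},
            tvc_terms={"a": [("x", KnotVector([np.log(0.1), np.log(2.0), np.log(20.0)]))]},
        )
        tvc.params_ = np.array([np.log(0.2), 1.3, 0.8, 0.0, 0.0])
        tvc.param_names_, tvc._slices_, _ = tvc._param_layout(tvc.spec_)

        t = np.linspace(0.2, 15, 50)
        cov = {"x": 1.7}
        np.testing.assert_allclose(
            ph.linear_predictor("a", cov, t)[0], tvc.linear_predictor("a", cov, t)[0],
            rtol=0, atol=1e-14)
        np.testing.assert_allclose(
            ph.predict_hazard("a", cov, t), tvc.predict_hazard("a", cov, t),
            rtol=1e-13)

    def test_unknown_cause_and_missing_covariate_errors(self, two_cause_fit):
        with pytest.raises(KeyError, match="unknown cause"):
            two_cause_fit.predict_survival("nope", {}, [1.0])
        with pytest.raises(ValueError, match="times must be positive"):
            two_cause_fit.predict_survival("cancer", {}, [-1.0])

    def test_km_tracking_covariate_free(self, two_cause_weibull_data, two_cause_fit):
        from lifelines import KaplanMeierFitter

        _, _, stacked = two_cause_weibull_data
        sub = stacked[stacked["cause"] == "cancer"]
        km = KaplanMeierFitter().fit(sub["time"], sub["status"])
        t = np.linspace(0.2, 9.5, 150)
        S_km = km.survival_function_at_times(t).to_numpy()
        S_fpm = two_cause_fit.predict_survival("cancer", {}, t)
        assert np.max(np.abs(S_fpm - S_km)) < 0.02


class TestHazardRatios:
    def test_table_shape_and_exp_transform(self):
        kv = KnotVector([np.log(0.1), np.log(20.0)])
        est = manual_weibull_model({"a": (0.2, 1.0)})
        est.spec_ = ModelSpec(["a"], {"a": kv}, covariates={"a": ["x", "z"]})
        est.params_ = np.array([np.log(0.2), 1.0, 0.0, np.log(2.0)])
        est.param_names_, est._slices_, _ = est._param_layout(est.spec_)
        est.vcov_ = np.zeros((4, 4))
        hr = est.hazard_ratios()
        assert list(hr["covariate"]) == ["x", "z"]
        assert hr.loc[hr.covariate == "x", "hr"].iloc[0] == pytest.approx(1.0)
        row = hr.loc[hr.covariate == "z"].iloc[0]
        assert row["hr"] == pytest.approx(2.0)
        assert row["ci_low"] == pytest.approx(2.0)  # SE = 0: degenerate CI
        assert row["ci_high"] == pytest.approx(2.0)


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, two_cause_fit, tmp_path):
        path = tmp_path / "model.json"
        two_cause_fit.to_json(path)
        loaded = FlexibleParametricSurvival.from_json(path)
        t = np.linspace(0.5, 9.0, 20)
        for k in ["cancer", "other"]:
            np.testing.assert_allclose(
                loaded.predict_survival(k, {}, t),
                two_cause_fit.predict_survival(k, {}, t), rtol=1e-12)
        assert loaded.aic_ == two_cause_fit.aic_
        np.testing.assert_allclose(loaded.vcov_, two_cause_fit.vcov_)
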