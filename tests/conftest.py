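import numpy as np
import pandas as pd
import pytest

from flexcif import CauseDGP, SimConfig, simulate, stack
from flexcif.fpm import FlexibleParametricSurvival, ModelSpec
from flexcif.splines import KnotVector


def manual_weibull_model(params_by_cause, bounds=(0.01, 100.0)):
    """Hand-built fitted model with exact Weibull parameters per cause.

    ``params_by_cause`` maps cause -> (lam, gamma) so that
    H_k(t) = lam * t**gamma.  Used to test predictions and the CIF
    machinery against closed forms without any fitting noise.
    """
    causes = list(params_by_cause)
    kv = KnotVector(np.log(np.asarray(bounds, dtype=float)))
    est = FlexibleParametricSurvival(df=1)
    est.spec_ = ModelSpec(
        cause_labels=causes,
        baseline_knots={k: kv for k in causes},
        covariates={k: [] for k in causes},
        tvc_terms={k: [] for k in causes},
    )
    params = []
    for k in causes:
        lam, gam = params_by_cause[k]
        params += [np.log(lam), gam]
    est.params_ = np.asarray(params, dtype=float)
    est.param_names_, est._slices_, est.n_params_ = *est._param_layout(est.spec_)[:2], len(params)
    est.vcov_ = np.zeros((len(params), len(params)))
    est.log_likelihood_ = 0.0
    est.n_obs_ = est.n_events_ = 0
    est.aic_ = est.bic_ = np.nan
    est.converged_ = True
    est.hazard_violations_ = {}
    return est


@pytest.fixture(scope="session")
def two_cause_weibull_data():
    """n=5000 two-cause Weibull draw with uniform censoring, no covariates."""
    cfg = SimConfig(
        n=5000,
        causes={
            "cancer": CauseDGP(family="weibull", rate=0.08, shape=1.3),
            "other": CauseDGP(family="weibull", rate=0.05, shape=0.9),
        },
        censoring=("uniform", 15.0),
        tau=10.0,
        covariates=None,
        seed=20260930,
    )
    wide = simulate(cfg)
    return cfg, wide, stack(wide, ["cancer", "other"])


@pytest.fixture(scope="session")
def two_cause_fit(two_cause_weibull_data):
    _, _, stacked = two_cause_weibull_data
    return FlexibleParametricSurvival(df=4).fit(stacked)


@pytest.fixture
def table2_wide():
    """The two-patient illustrative input: one censored, one heart-disease death."""
    return pd.DataFrame(
        {
            "id": [1, 2],
            "age": [50, 70],
            "time": [10.0, 6.5],
            "cause_of_death": [None, "Heart Disease"],
        }
    )


FOUR_CAUSES = ["Breast Cancer", "Other Cancer", "Heart Disease", "Other Causes"]
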