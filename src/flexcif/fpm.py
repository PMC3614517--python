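"""Flexible parametric survival model on the log cumulative hazard scale.

The model (Royston–Parmar family, log cumulative hazard scale only)
writes, for each cause ``k``,

.. math::

    \\ln H_k(t \\mid x) = s(\\ln t \\mid \\gamma_k, n_{k0}) + x \\beta_k
        + \\sum_j s(\\ln t \\mid \\delta_{kj}, n_{kj}) \\, x_j

where ``s`` is a restricted cubic spline in log time
(:mod:`flexcif.splines`).  With two knots the spline is linear in
``ln t`` and the model is exactly Weibull
(:math:`\\ln H = \\ln\\lambda + \\gamma\\ln t`); additional knots relax
the shape of the baseline.  Covariate effects :math:`\\beta` are log
cause-specific hazard ratios under proportional hazards; the optional
covariate-by-spline interactions give time-dependent effects.

Survival and hazard follow by transformation:
``S = exp(-exp(eta))`` and ``h = (1/t) (d eta / d ln t) exp(eta)``.
Fitting is full maximum likelihood for right-censored data,

.. math::

    \\ell = \\sum_i d_i \\ln h(t_i \\mid x_i) - H(t_i \\mid x_i),

by Newton iteration with analytic gradient and Hessian; the reported
variance matrix is the inverse negative Hessian at the optimum.

Data may be a single cause, or "stacked" long format with one row per
subject per cause (see :func:`flexcif.competing.stack`), in which case
one model is fitted for all K causes simultaneously with per-cause
baselines and (by default) cause-specific covariate effects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

# sklearn gives get_params/set_params and pipeline compatibility
from sklearn.base import BaseEstimator

from .splines import KnotVector, basis, place_knots

__all__ = ["ModelSpec", "FlexibleParametricSurvival", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Raised when Newton iteration fails to converge."""


@dataclass
class ModelSpec:
    """Resolved per-cause model structure: knots, covariates, tvc terms.

    ``tvc_terms[cause]`` is a list of ``(covariate_name, KnotVector)``;
    the interaction uses the spline basis *without* its intercept (the
    covariate's proportional-hazards coefficient plays that role), so
    every tvc covariate must also appear in ``covariates[cause]``.
    """

    cause_labels: list[str]
    baseline_knots: dict[str, KnotVector]
    covariates: dict[str, list[str]] = field(default_factory=dict)
    tvc_terms: dict[str, list[tuple[str, KnotVector]]] = field(default_factory=dict)
    shared_covariates: list[str] = field(default_factory=list)
    knot_scale: str = "log"

    def __post_init__(self):
        if len(set(self.cause_labels)) != len(self.cause_labels):
            raise ValueError("cause labels must be unique")
        for k in self.cause_labels:
            self.covariates.setdefault(k, [])
            self.tvc_terms.setdefault(k, [])
        for k in self.cause_labels:
            for name, _ in self.tvc_terms.get(k, []):
                if name not in self.covariates.get(k, []) and name not in self.shared_covariates:
                    raise ValueError(
                        f"tvc covariate {name!r} for cause {k!r} must also have a "
                        "proportional-hazards term"
                    )

    def to_dict(self) -> dict:
        return {
            "cause_labels": list(self.cause_labels),
            "baseline_knots": {k: v.to_list() for k, v in self.baseline_knots.items()},
            "covariates": {k: list(v) for k, v in self.covariates.items()},
            "tvc_terms": {
                k: [[name, kv.to_list()] for name, kv in v]
                for k, v in self.tvc_terms.items()
            },
            "shared_covariates": list(self.shared_covariates),
            "knot_scale": self.knot_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            cause_labels=list(d["cause_labels"]),
            baseline_knots={k: KnotVector.from_list(v) for k, v in d["baseline_knots"].items()},
            covariates={k: list(v) for k, v in d.get("covariates", {}).items()},
            tvc_terms={
                k: [(name, KnotVector.from_list(kv)) for name, kv in v]
                for k, v in d.get("tvc_terms", {}).items()
            },
            shared_covariates=list(d.get("shared_covariates", [])),
            knot_scale=d.get("knot_scale", "log"),
        )


def _as_per_cause(value, causes, default):
    """Broadcast a scalar / list / dict argument to a per-cause dict."""
    if value is None:
        return {k: default for k in causes}
    if isinstance(value, dict) and set(value) & set(causes):
        return {k: value.get(k, default) for k in causes}
    return {k: value for k in causes}


class FlexibleParametricSurvival(BaseEstimator):
    """Maximum-likelihood flexible parametric survival model, one or K causes.

    Parameters
    ----------
    df : int or dict, default 4
        Baseline spline degrees of freedom per cause (``df + 1`` knots at
        event-time centiles).  ``df=1`` is the Weibull special case.
        Ignored for causes with explicit ``knots``.
    knots : dict of cause -> array-like, optional
        Explicit baseline knots on the log-time scale.
    covariates : list of str or dict of cause -> list, optional
        Numeric covariate columns entering with cause-specific
        proportional-hazards coefficients.
    tvc : dict, optional
        Time-dependent effects: ``{covariate: df}`` (applied to every
        cause) or ``{cause: {covariate: df}}``.  Knots placed at
        event-time centiles of the cause.
    shared_covariates : list of str, optional
        Covariates with a single coefficient shared across all causes.
    duration_col, event_col, cause_col : str
        Column names in the input frame.  If ``cause_col`` is absent the
        data are treated as a single cause named ``"event"``.
    horizon : float, optional
        Administrative censoring: follow-up truncated at this time before
        fitting.
    knot_scale : {"log", "natural"}
        Scale on which knot centiles are computed (recorded in the spec).
    tol, grad_tol : float
        Convergence: relative log-likelihood change and max absolute
        score at the optimum.
    max_iter : int
        Newton iteration cap.

    Attributes
    ----------
    params_ : ndarray
        Stacked coefficient vector (per-cause gamma, beta, delta blocks,
        then shared betas).
    param_names_ : list of str
    vcov_ : ndarray
        Inverse negative Hessian at the optimum.
    log_likelihood_, aic_, bic_ : float
        ``bic_`` uses the number of events as n.
    n_obs_, n_events_ : int
    spec_ : ModelSpec
    converged_ : bool
    hazard_violations_ : dict
        Per-cause time ranges where the fitted d eta/d ln t <= 0 at
        event times, if any (reported, not clipped).
    """

    def __init__(
        self,
        df=4,
        knots=None,
        covariates=None,
        tvc=None,
        shared_covariates=None,
        duration_col="time",
        event_col="status",
        cause_col="cause",
        horizon=None,
        knot_scale="log",
        tol=1e-8,
        grad_tol=1e-5,
        max_iter=100,
    ):
        self.df = df
        self.knots = knots
        self.covariates = covariates
        self.tvc = tvc
        self.shared_covariates = shared_covariates
        self.duration_col = duration_col
        self.event_col = event_col
        self.cause_col = cause_col
        self.horizon = horizon
        self.knot_scale = knot_scale
        self.tol = tol
        self.grad_tol = grad_tol
        self.max_iter = max_iter

    # ------------------------------------------------------------------ setup

    def _validate_data(self, data: pd.DataFrame) -> pd.DataFrame:
        for col in (self.duration_col, self.event_col):
            if col not in data.columns:
                raise ValueError(f"column {col!r} not in data")
        d = data.copy()
        t = d[self.duration_col].to_numpy(dtype=float)
        if np.any(t <= 0):
            raise ValueError("all durations must be positive")
        status = d[self.event_col].to_numpy()
        if not np.isin(status, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if self.horizon is not None:
            over = t > self.horizon
            d.loc[over, self.duration_col] = float(self.horizon)
            d.loc[over, self.event_col] = 0
        if self.cause_col not in d.columns:
            d[self.cause_col] = "event"
        return d

    def _resolve_spec(self, data: pd.DataFrame) -> ModelSpec:
        causes = list(pd.unique(data[self.cause_col]))
        causes = [str(c) for c in causes]
        dfs = _as_per_cause(self.df, causes, 4)
        cov = self.covariates
        if cov is not None and not (isinstance(cov, dict) and set(cov) & set(causes)):
            cov = {k: list(cov) for k in causes}
        cov = cov or {}
        covariates = {k: list(cov.get(k, [])) for k in causes}
        shared = list(self.shared_covariates or [])

        knots_arg = self.knots or {}
        baseline_knots = {}
        tvc_terms: dict[str, list[tuple[str, KnotVector]]] = {k: [] for k in causes}
        tvc = self.tvc or {}
        # {cause: {cov: df}} vs {cov: df}
        per_cause_tvc = isinstance(tvc, dict) and set(map(str, tvc)) <= set(causes) and all(
            isinstance(v, dict) for v in tvc.values()
        )
        for k in causes:
            mask = (data[self.cause_col].astype(str) == k) & (data[self.event_col] == 1)
            ev = data.loc[mask, self.duration_col].to_numpy(dtype=float)
            if ev.size == 0:
                raise ValueError(f"no events for cause {k!r}; cannot place knots or fit")
            if k in knots_arg:
                baseline_knots[k] = KnotVector.from_list(knots_arg[k])
            else:
                baseline_knots[k] = place_knots(ev, int(dfs[k]), scale=self.knot_scale)
            k_tvc = tvc.get(k, {}) if per_cause_tvc else tvc
            for name, tdf in k_tvc.items():
                if name not in covariates[k] and name not in shared:
                    covariates[k].append(name)
                tknots = place_knots(ev, int(tdf), scale=self.knot_scale)
                tvc_terms[k].append((name, tknots))
        return ModelSpec(
            cause_labels=causes,
            baseline_knots=baseline_knots,
            covariates=covariates,
            tvc_terms=tvc_terms,
            shared_covariates=shared,
            knot_scale=self.knot_scale,
        )

    def _param_layout(self, spec: ModelSpec):
        """Column names and per-cause slices of the stacked parameter vector."""
        names, slices, pos = [], {}, 0
        for k in spec.cause_labels:
            start = pos
            nb = spec.baseline_knots[k].n_basis
            names.append(f"{k}:gamma0")
            names += [f"{k}:gamma{j}" for j in range(1, nb + 1)]
            pos += nb + 1
            for c in spec.covariates[k]:
                names.append(f"{k}:{c}")
                pos += 1
            for c, kv in spec.tvc_terms[k]:
                names += [f"{k}:{c}:delta{j}" for j in range(1, kv.n_basis + 1)]
                pos += kv.n_basis
            slices[k] = slice(start, pos)
        for c in spec.shared_covariates:
            names.append(f"shared:{c}")
            pos += 1
        return names, slices, pos

    def _design(self, spec: ModelSpec, cause_arr, log_t, covframe):
        """Dense design matrices for eta and d eta/d ln t over stacked rows."""
        names, slices, p = self._param_layout(spec)
        n = log_t.size
        X = np.zeros((n, p))
        Xd = np.zeros((n, p))
        for k in spec.cause_labels:
            rows = np.flatnonzero(cause_arr == k)
            if rows.size == 0:
                continue
            sl = slices[k]
            col = sl.start
            b = basis(log_t[rows], spec.baseline_knots[k])
            X[rows, col] = 1.0
            nb = b.values.shape[1]
            X[rows, col + 1 : col + 1 + nb] = b.values
            Xd[rows, col + 1 : col + 1 + nb] = b.derivs
            col += 1 + nb
            for c in spec.covariates[k]:
                X[rows, col] = covframe[c].to_numpy(dtype=float)[rows]
                col += 1
            for c, kv in spec.tvc_terms[k]:
                tb = basis(log_t[rows], kv)
                xval = covframe[c].to_numpy(dtype=float)[rows][:, None]
                X[rows, col : col + kv.n_basis] = tb.values * xval
                Xd[rows, col : col + kv.n_basis] = tb.derivs * xval
                col += kv.n_basis
        col = p - len(spec.shared_covariates)
        for c in spec.shared_covariates:
            X[:, col] = covframe[c].to_numpy(dtype=float)
            col += 1
        return X, Xd

    # ------------------------------------------------------------- likelihood

    @staticmethod
    def _loglik_parts(theta, X, Xd, d, log_t):
        eta = X @ theta
        deta = Xd @ theta
        if np.any(deta[d] <= 0):
            return -np.inf, eta, deta
        H = np.exp(eta)
        ll = np.sum(np.log(deta[d]) - log_t[d] + eta[d]) - np.sum(H)
        return ll, eta, deta

    def log_likelihood(self, data: pd.DataFrame, params=None) -> float:
        """Right-censored log-likelihood of ``data`` at ``params``.

        Contributions of stacked rows are additive across causes, so the
        joint stacked likelihood with disjoint parameters equals the sum
        of per-cause likelihoods.
        """
        self._check_fitted()
        theta = self.params_ if params is None else np.asarray(params, dtype=float)
        d = self._validate_data(data)
        cause_arr = d[self.cause_col].astype(str).to_numpy()
        log_t = np.log(d[self.duration_col].to_numpy(dtype=float))
        X, Xd = self._design(self.spec_, cause_arr, log_t, d)
        ev = d[self.event_col].to_numpy() == 1
        ll, _, _ = self._loglik_parts(theta, X, Xd, ev, log_t)
        return float(ll)

    def _initial_params(self, spec, data, slices, p):
        """gamma from regressing ln(-ln KM) on the basis; beta, delta = 0."""
        from lifelines import KaplanMeierFitter

        theta = np.zeros(p)
        for k in spec.cause_labels:
            sub = data[data[self.cause_col].astype(str) == k]
            t = sub[self.duration_col].to_numpy(dtype=float)
            ev = sub[self.event_col].to_numpy() == 1
            km = KaplanMeierFitter().fit(t, ev)
            te = np.unique(t[ev])
            S = km.survival_function_at_times(te).to_numpy()
            S = np.clip(S, 1e-6, 1 - 1e-6)
            y = np.log(-np.log(S))
            b = basis(np.log(te), spec.baseline_knots[k])
            D = np.column_stack([np.ones(te.size), b.values])
            coef, *_ = np.linalg.lstsq(D, y, rcond=None)
            if coef[1] <= 0:  # guarantee a valid starting hazard
                coef = np.zeros_like(coef)
                coef[0] = np.log(max(ev.sum(), 1) / t.sum())
                coef[1] = 1.0
            sl = slices[k]
            theta[sl.start : sl.start + 1 + b.values.shape[1]] = coef
        return theta

    # ------------------------------------------------------------------- fit

    def fit(self, data: pd.DataFrame, y=None):
        """Fit by Newton–Raphson with analytic gradient and Hessian.

        ``data`` is a long-format frame (one row per subject, or one row
        per subject per cause when stacked) with duration, 0/1 status,
        optional cause label and numeric covariate columns.
        """
        d = self._validate_data(data)
        spec = self._resolve_spec(d)
        names, slices, p = self._param_layout(spec)
        missing = [
            c
            for k in spec.cause_labels
            for c in spec.covariates[k]
            if c not in d.columns
        ] + [c for c in spec.shared_covariates if c not in d.columns]
        if missing:
            raise ValueError(f"covariate columns missing from data: {sorted(set(missing))}")

        cause_arr = d[self.cause_col].astype(str).to_numpy()
        t = d[self.duration_col].to_numpy(dtype=float)
        log_t = np.log(t)
        ev = d[self.event_col].to_numpy() == 1
        X, Xd = self._design(spec, cause_arr, log_t, d)

        theta = self._initial_params(spec, d, slices, p)
        ll, eta, deta = self._loglik_parts(theta, X, Xd, ev, log_t)
        if not np.isfinite(ll):
            raise ConvergenceError("invalid starting values (non-positive hazard)")

        converged = False
        for _ in range(self.max_iter):
            H = np.exp(eta)
            w_ev = np.zeros_like(eta)
            w_ev[ev] = 1.0 / deta[ev]
            grad = Xd.T @ w_ev + X.T @ (ev.astype(float) - H)
            hess = -(Xd.T @ (Xd * (w_ev**2)[:, None]) + X.T @ (X * H[:, None]))
            try:
                step = linalg.solve(-hess, grad, assume_a="sym")
            except linalg.LinAlgError:
                step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
            # step halving until the likelihood improves and hazard stays valid
            alpha, new_ll = 1.0, -np.inf
            for _ in range(40):
                cand = theta + alpha * step
                new_ll, new_eta, new_deta = self._loglik_parts(cand, X, Xd, ev, log_t)
                if new_ll > ll - 1e-12:
                    break
                alpha *= 0.5
            if not np.isfinite(new_ll):
                raise ConvergenceError("step halving failed; model may be unidentified")
            theta, eta, deta = cand, new_eta, new_deta
            rel = abs(new_ll - ll) / (abs(ll) + 1e-12)
            ll = new_ll
            if rel < self.tol and np.max(np.abs(grad)) < self.grad_tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"Newton iteration did not meet tolerances after {self.max_iter} "
                f"iterations (last max |score| = {np.max(np.abs(grad)):.2e})",
                RuntimeWarning,
            )

        H = np.exp(eta)
        w_ev = np.zeros_like(eta)
        w_ev[ev] = 1.0 / deta[ev]
        hess = -(Xd.T @ (Xd * (w_ev**2)[:, None]) + X.T @ (X * H[:, None]))
        try:
            vcov = linalg.inv(-hess)
        except linalg.LinAlgError as e:
            raise ConvergenceError(f"singular Hessian at the optimum: {e}") from e
        vcov = 0.5 * (vcov + vcov.T)

        self.spec_ = spec
        self.params_ = theta
        self.param_names_ = names
        self._slices_ = slices
        self.vcov_ = vcov
        self.log_likelihood_ = float(ll)
        self.converged_ = converged
        self.n_obs_ = int(len(d))
        self.n_events_ = int(ev.sum())
        self.aic_ = float(-2 * ll + 2 * p)
        self.bic_ = float(-2 * ll + np.log(max(self.n_events_, 1)) * p)
        self.n_params_ = p

        # flag (never clip) hazard violations at event times
        self.hazard_violations_ = {}
        bad = ev & (deta <= 0)
        if np.any(bad):
            for k in spec.cause_labels:
                kt = t[bad & (cause_arr == k)]
                if kt.size:
                    self.hazard_violations_[k] = (float(kt.min()), float(kt.max()))
            warnings.warn(
                f"fitted d eta/d ln t <= 0 at some event times: {self.hazard_violations_}",
                RuntimeWarning,
            )
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted; call fit() first")

    # -------------------------------------------------------------- predict

    def _profile_design(self, cause, covariates, log_t):
        """Design rows for one covariate profile of one cause over a time grid."""
        self._check_fitted()
        spec = self.spec_
        cause = str(cause)
        if cause not in spec.cause_labels:
            raise KeyError(f"unknown cause {cause!r}; model causes: {spec.cause_labels}")
        covariates = covariates or {}
        needed = list(spec.covariates[cause]) + list(spec.shared_covariates)
        missing = [c for c in needed if c not in covariates]
        if missing:
            raise ValueError(f"missing covariate values for cause {cause!r}: {missing}")
        frame = pd.DataFrame({c: np.full(log_t.size, float(covariates[c])) for c in needed})
        if not needed:
            frame = pd.DataFrame(index=range(log_t.size))
        cause_arr = np.full(log_t.size, cause, dtype=object)
        return self._design(spec, cause_arr, log_t, frame)

    def linear_predictor(self, cause, covariates, times):
        """``eta = ln H_k(t|x)`` and its derivative d eta/d ln t.

        Returns ``(eta, deta)`` arrays over ``times``.
        """
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(t <= 0):
            raise ValueError("times must be positive")
        X, Xd = self._profile_design(cause, covariates, np.log(t))
        return X @ self.params_, Xd @ self.params_

    def predict_cumulative_hazard(self, cause, covariates, times):
        """Cause-specific cumulative hazard ``H_k(t|x) = exp(eta)``."""
        eta, _ = self.linear_predictor(cause, covariates, times)
        return np.exp(eta)

    def predict_survival(self, cause, covariates, times):
        """Cause-specific survival ``S_k(t|x) = exp(-exp(eta))``.

        Interpretable as a net probability of avoiding cause ``k`` only
        under independence of the competing event times; use the
        cumulative incidence function for real-world probabilities in
        the presence of competing causes.
        """
        eta, _ = self.linear_predictor(cause, covariates, times)
        return np.exp(-np.exp(eta))

    def predict_hazard(self, cause, covariates, times):
        """Cause-specific hazard ``h_k(t|x) = (1/t)(d eta/d ln t) exp(eta)``.

        Negative values (possible because the spline does not constrain
        d eta/d ln t > 0) are returned as-is with a warning, never
        clipped.
        """
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(t <= 0):
            raise ValueError("times must be positive")
        eta, deta = self.linear_predictor(cause, covariates, t)
        h = deta / t * np.exp(eta)
        if np.any(h < 0):
            bad = t[h < 0]
            warnings.warn(
                f"negative fitted hazard for cause {cause!r} on "
                f"t in [{bad.min():.4g}, {bad.max():.4g}]",
                RuntimeWarning,
            )
        return h

    def hazard_ratios(self, alpha=0.05) -> pd.DataFrame:
        """Cause-specific hazard ratios exp(beta) with Wald CIs.

        Proportional-hazards coefficients only; time-dependent terms are
        excluded (their effect is time-varying by construction).
        """
        from scipy.stats import norm

        self._check_fitted()
        z = norm.ppf(1 - alpha / 2)
        se = np.sqrt(np.diag(self.vcov_))
        rows = []
        for i, name in enumerate(self.param_names_):
            parts = name.split(":")
            if len(parts) != 2 or parts[1].startswith("gamma"):
                continue
            cause, cov = parts
            b, s = self.params_[i], se[i]
            rows.append(
                {
                    "cause": cause,
                    "covariate": cov,
                    "coef": b,
                    "se": s,
                    "hr": np.exp(b),
                    "ci_low": np.exp(b - z * s),
                    "ci_high": np.exp(b + z * s),
                }
            )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------- io

    def to_json(self, path=None):
        """Serialize the fitted model (spec, params, vcov, fit stats)."""
        self._check_fitted()
        obj = {
            "spec": self.spec_.to_dict(),
            "params": self.params_.tolist(),
            "param_names": self.param_names_,
            "vcov": self.vcov_.tolist(),
            "log_likelihood": self.log_likelihood_,
            "aic": self.aic_,
            "bic": self.bic_,
            "n_obs": self.n_obs_,
            "n_events": self.n_events_,
            "converged": self.converged_,
            "estimator_params": {
                "duration_col": self.duration_col,
                "event_col": self.event_col,
                "cause_col": self.cause_col,
            },
        }
        if path is None:
            return json.dumps(obj, indent=1)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
        return None

    @classmethod
    def from_json(cls, source) -> "FlexibleParametricSurvival":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        est = cls(**obj.get("estimator_params", {}))
        est.spec_ = ModelSpec.from_dict(obj["spec"])
        est.params_ = np.asarray(obj["params"], dtype=float)
        est.param_names_ = list(obj["param_names"])
        est.vcov_ = np.asarray(obj["vcov"], dtype=float)
        est.log_likelihood_ = obj["log_likelihood"]
        est.aic_ = obj["aic"]
        est.bic_ = obj["bic"]
        est.n_obs_ = obj["n_obs"]
        est.n_events_ = obj["n_events"]
        est.converged_ = obj["converged"]
        est.n_params_ = est.params_.size
        _, est._slices_, _ = est._param_layout(est.spec_)
        est.hazard_violations_ = {}
        return est
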