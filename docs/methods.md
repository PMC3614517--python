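# Methods

## Model

`flexcif` fits flexible parametric survival models on the log cumulative
hazard scale to right-censored competing-risks data and transforms the
fitted cause-specific hazards into cumulative incidence functions (CIFs).

For each cause *k* of K mutually exclusive causes the model is

    ln H_k(t | x) = s(ln t | γ_k, n_k0) + x β_k + Σ_j s(ln t | δ_kj, n_kj) x_j

where `s` is a restricted cubic spline in log time: piecewise cubic,
continuous through the second derivative at every knot, and constrained
linear beyond the boundary knots. With N knots the spline contributes an
intercept plus N−1 derived variables; the first derived variable is
exactly `ln t`, so a 2-knot model is Weibull
(`ln H = ln λ + γ ln t`) and an additional unit slope constraint would
give the exponential. Covariate effects β are log cause-specific hazard
ratios under proportional hazards (PH); the optional covariate × spline
interactions (`tvc`) give time-dependent effects. The tvc spline enters
*without* its intercept: the covariate's PH coefficient plays that role,
which is why every tvc covariate must also carry a PH term.

Survival and hazard follow by transformation: `S_k = exp(−exp(η))` and
`h_k = (1/t)(dη/d ln t) exp(η)`, with the derivative of the spline taken
analytically. Nothing constrains `dη/d ln t > 0`, so a fitted hazard can
dip negative in data-sparse regions; the package warns and reports the
offending time range rather than clipping.

### Competing risks

K cause-specific models are fitted jointly on *stacked* data (each
subject contributes one row per cause; the death indicator is 1 only on
the row matching the subject's cause of death). With fully
cause-specific parameters the joint likelihood factorizes, so the
stacked fit reproduces K separate per-cause fits; sharing a coefficient
across causes (`shared_covariates`) is supported but left to the user's
judgement.

The CIF is

    C_k(t | x) = ∫₀ᵗ h_k(u|x) exp(−Σ_j H_j(u|x)) du ,

the real-world ("crude") probability of death from cause k by t in the
presence of the other causes. The complement of the cause-specific
survival `exp(−H_k)` is interpretable as a net probability only under
independence of the competing event times and always exceeds the CIF;
the package exposes both, documented as such.

Two relative measures are derived from the fit: `C_k/ΣC_j`, the
probability the death was from cause k given a death *by* t, and
`h_k/Σh_j`, the same given a death *at* t.

## Estimation

Full maximum likelihood for right-censored data,
`ℓ = Σ_i d_i ln h(t_i|x_i) − H(t_i|x_i)`, by Newton–Raphson with
analytic gradient and Hessian and step-halving; a step is rejected while
it leaves `dη/d ln t ≤ 0` at any event time or decreases ℓ. Starting
values: γ from an OLS regression of `ln(−ln Ŝ_KM)` on the spline basis
at the cause's event times (Kaplan–Meier computed per cause with
competing events censored), β = δ = 0; if the implied log-time slope is
non-positive the start falls back to the exponential fit
`λ = events / time at risk`. Convergence requires relative ℓ-change
< 1e−8 *and* max |score| < 1e−5 (both configurable); the variance matrix
is the inverse negative Hessian at the optimum. AIC = −2ℓ + 2p;
BIC = −2ℓ + p·ln(n) with n = number of events (a deliberate choice — the
effective information in censored data scales with events, not rows).

### Knots

Boundary knots at the log of the first and last *uncensored* event times
of the cause (distinct values under ties); df−1 internal knots at
equally spaced centiles of the event times, so df = 4 gives the
25th/50th/75th centiles. Centiles use numpy's linear-interpolation
empirical quantile and are computed on the log scale by default (for
symmetry with the basis); `knot_scale="natural"` computes them on the
raw times first. Duplicate knots from tied centiles are an error rather
than silently merged. Follow-up can be administratively truncated at a
configurable horizon before knot placement and fitting.

### CIF integration and uncertainty

The CIF integral is evaluated on a uniform grid of m intervals of length
l = τ/m. The integrand `f_k = h_k · exp(−Σ H_j)` is evaluated at interval
*midpoints* by default (an `endpoint` option gives the literal
rectangle rule) and cumulated through the l-scaled lower-triangular ones
matrix L, i.e. `C_k = l · cumsum(f_k)`. Because that cumulation
approximates the integral up to each interval's right endpoint,
estimates are reported at t = l, 2l, …, τ — the grid never touches 0, so
`ln t` is always defined. Default m = 1000; on smooth test models
doubling m moves C_k(τ) by well under 1e−3. All-cause survival is
evaluated directly as `exp(−Σ H_j)` at the report times, so
`Σ_k C_k + S` deviates from 1 only by the quadrature error.

Delta-method variance: G is the m × p matrix of central
finite-difference derivatives of the integrand with respect to the
parameters (step `1e−5·(1+|θ|)`), and `Var(C_k) = L G V̂ G′ L′` with V̂
the parameter variance matrix. Pointwise Wald intervals are formed on
the natural scale and truncated to [0, 1] by default; a `cloglog`
transform gives boundary-respecting intervals. The alternative is a
bias-corrected percentile bootstrap: subjects (all K stacked rows
together) resampled with replacement, the model refitted — including
knot re-placement — per replicate, percentile points shifted by the
bias-correction z₀ = Φ⁻¹(fraction of replicates below the point
estimate), no acceleration term. Non-converged replicates are dropped,
counted, and an error raised beyond a 10% allowance.

## Synthetic data generator

`synthesize` draws competing-risks datasets from known cause-specific
hazards: per subject, one latent time per cause by inverse transform
from the cause's all-covariate cumulative hazard; observed time and
cause are the minimum and argmin, censoring by an independent uniform or
exponential time and/or an administrative horizon. For the observable
cause-specific hazards this is equivalent to drawing the all-cause time
and assigning the cause multinomially with probabilities `h_k/Σh_j`, so
no dependence structure among latent times is assumed or identifiable.
Hazard families: exponential, Weibull (`H = λ t^γ`), and Weibull with a
log-time-linear time-varying log hazard ratio, chosen because its
cumulative hazard stays invertible in closed form (the tvc slope simply
shifts the effective shape: `H = λγ e^{xβ₀} t^{γ+xb}/(γ+xb)`).

The default covariate generator mirrors a population cancer-registry
design: a 4-level age-group factor (frequencies 0.50/0.21/0.19/0.10) and
a 3-level stage factor (0.61/0.33/0.06), emitted as dummy columns, which
exercises the cause-interaction machinery. A single Bernoulli(½)
covariate (`"binary"`) is used for parameter-recovery studies.

What the generator deliberately does *not* emulate: dependent censoring,
delayed entry, covariate measurement error, non-PH effects beyond the
log-time-linear form, and cause misclassification. Passing tests
therefore show correctness of the estimator under a correctly specified
independent-censoring world, not robustness to those violations.

Independent oracles used in testing: the true CIF by high-resolution
midpoint quadrature (m = 1e5 by default) from the known hazards; the
nonparametric Aalen–Johansen estimator (via lifelines) for model-free
CIF agreement; and a direct 2-parameter Weibull ML fit (Nelder–Mead on
the closed-form likelihood) for the 2-knot equivalence — each
deliberately avoids the spline code path it validates.

## Numerical and design choices

- Problem sizes in the test and acceptance runs: single fits at
  n = 2000–10000, 200 replicates for coverage, B = 200 bootstrap
  replicates, m = 100–1000 integration intervals — sizes at which every
  check is stable yet the whole suite completes in about a minute.
- Ties in event times need no special handling (parametric likelihood).
- Exact zeros are never passed to `ln t`: durations must be positive,
  integration grids start at l or l/2.
- Prediction beyond the boundary knots is allowed (the spline is linear
  there by construction) but flagged with a warning, since extrapolation
  is driven entirely by the boundary slope.
- The bootstrap reuses the estimator's constructor parameters, so a
  replicate re-places knots at its own event-time centiles — the CI thus
  reflects knot-selection variability as well as sampling noise.
- Left truncation (delayed entry), probit/log-odds model scales, cure
  and frailty models, Fine–Gray subdistribution regression, and
  simultaneous confidence bands are out of scope.

## Known limitations

- The fitted hazard is not constrained positive; sparse tails can
  produce negative hazard estimates (warned, never clipped).
- Delta-method CIs are symmetric on the natural scale and can be poor
  very near C = 0; use `ci_transform="cloglog"` or the bootstrap there.
- With heavy censoring and small event counts per cause, high df spline
  fits can be weakly identified; the Newton iteration reports
  non-convergence and the singular-Hessian case raises.
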