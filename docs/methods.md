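# Methods

## Model

For right-censored survival data `(t_i, c_i)` with quantitative exposure
`x_i` (and optional adjustment covariates `z_i`), the hazard is modeled as

    lambda(t | x) = lambda_0(t) * exp(s(x) + gamma' z),

with the exposure-response curve represented as a basis expansion
`s(x) = sum_{j=1..J} b_j f_j(x)`. No intercept basis function is used: the
constant is absorbed by the unspecified baseline hazard, so `s` is
identified only up to an additive constant and every reported quantity is a
contrast `s(x) - s(x_ref)`.

Two basis families are implemented.

**Truncated power basis** of degree `p` with knots `k_1 < ... < k_K`:
`{x, x^2, ..., x^p, (x-k_1)_+^p, ..., (x-k_K)_+^p}`, giving `J = p + K`
functions whose span is the space of piecewise degree-`p` polynomials with
`p-1` continuous derivatives. Knots default to the quartiles of the *case*
exposures — knot placement should track where the events are, since the
events carry the information. The quantile rule interpolates order
statistics at positions `(n+1)p` (numpy method `"weibull"`), so that, e.g.,
seven distinct case exposures put the quartile knots exactly at the
2nd/4th/6th order statistics; the rule is pluggable.

**B-spline basis** built by the de Boor recursion with boundary knots at
the observed exposure range (multiplicity `degree+1`) and, by default,
equally spaced interior knots. The full basis satisfies the partition of
unity, so one direction equals the constant; the first basis function is
dropped, leaving `J = m + degree - 1` functions for `m` spans (15 spans of
cubics → 17 functions). Contrasts are invariant to which column is dropped
(tested). B-splines span the same space as the truncated power basis with
the same knots but are dramatically better conditioned (also tested).

## Fitting and penalization

Unpenalized fits maximize the Cox log partial likelihood by Newton-Raphson
with step-halving; ties are handled by the Efron correction by default
(Breslow selectable). Penalized fits maximize

    l(b) - theta * b' Omega b,

where `Omega_jl = ∫ f_j''(x) f_l''(x) dx` over the exposure range is the
curvature penalty, computed exactly by per-interval Gauss-Legendre
quadrature (the integrand is piecewise polynomial). For degree < 2 the
second derivative vanishes almost everywhere and the standard discrete
analogue — squared second-order differences of adjacent coefficients — is
used instead, with a logged notice. Affine functions lie in the penalty
null space, so as `theta → ∞` the fit approaches a linear log hazard
ratio.

The effective degrees of freedom are `df = tr[(H + 2 theta Omega)^{-1} H]`
with `H` the observed partial-likelihood information: `df = J` at
`theta = 0` (returned exactly, since the numerical trace of a
near-singular `inv(H) H` can miss J by ~1e-6) and `df → 1` as
`theta → ∞`; `df(theta)` is continuous and strictly decreasing. With
adjustment covariates the penalty has a zero block and each covariate
contributes one further df; the per-column decomposition
`diag[(H+2 theta Omega)^{-1} H]` attributes df to the spline term alone,
which is what `df=`-targeted fitting controls.

Smoothing is chosen either by a target spline df (bisection on
`log theta`, tolerance 1e-3), or by minimizing

    AIC  = -2 l(b-hat) + 2 df,
    AICc = AIC + 2 df (df + 1) / (m - df - 1),

with `m` the number of *events* — the events, not the cohort size, carry
the information in a Cox model. The criterion is scanned on a coarse
19-point `log10 theta` grid spanning the decades around the natural scale
`tr(H_0)/tr(Omega)` (warm-starting each fit from its smoother neighbour)
and refined by bounded golden-section search between the grid optimum's
neighbours; `theta` values where `m <= df + 1` score `+inf`.

Two covariance estimators are stored for penalized fits: the model-based
`(H + 2 theta Omega)^{-1}` (default, matching the reference software's
intervals) and the sandwich `(H+2tO)^{-1} H (H+2tO)^{-1}`. They coincide
at `theta = 0`.

### Numerical choices

- Design columns are centered and scaled internally; the penalty is
  transformed consistently and estimates/covariances are back-transformed,
  so results are invariant to the standardization. Centering does not move
  Cox coefficients; it only stabilizes the exponentials.
- Convergence: gradient infinity-norm below 1e-9, at most 50 Newton
  iterations. At extreme `theta` the objective's rounding noise scales
  with the penalty magnitude, so acceptance and stopping are additionally
  scale-aware: the solver stops when the quadratic-model improvement falls
  below the objective's rounding noise (≈1e-9 of its magnitude), which at
  `theta ~ 1e8 x` the information scale leaves the solution within ~1e-5
  of the exact optimum — far inside any reported precision.
- Monotone partial likelihoods (coefficients diverging to infinity) are
  detected in unpenalized fits by a still-large final Newton step at a flat
  gradient, or a runaway standardized coefficient, and raise a
  `DivergenceError` naming the column. Penalized fits never raise it: the
  quadratic penalty bounds the optimum, and weakly identified B-spline
  tail columns (no observations in their support) are precisely what the
  penalty is for. Consequently, a positive `theta` also accepts designs
  that are rank-deficient; `theta = 0` demands full rank.
- Evaluation of a basis outside its exposure range linearly extrapolates
  from the boundary with a warning: splines have boundary effects and
  polynomial extension is untrustworthy there.

## Effects and inference

All reported effects are Wald contrasts: for `c = f(x) - f(x_ref)`,
`lnHR-hat = c'b-hat`, `se = sqrt(c'Vc)`, `HR = exp(lnHR-hat)`, with
confidence limits computed on the log scale and exponentiated
(z = 1.959964 for 95%). The "mean-centered" curve that general-purpose
software reports by default is provided for illustration only; for a
multi-column basis it differs from every exposure-referenced curve by a
constant and has no subject-matter meaning.

The p-value function `p(HR_0) = 2[1 - Phi(|lnHR-hat - ln HR_0| / se)]`
traces the whole family of confidence intervals and is exactly dual to
them (tested at levels 0.8/0.9/0.95/0.99).

Nonlinearity is tested against `H0: s(x) = b x`. For truncated-power fits,
a Wald chi-square that all coefficients beyond the linear term vanish
(df = J - 1). For penalized fits, the fitted basis columns are projected
(unweighted least squares, intercept included) onto `[1, x]` over the
observed exposures; the Wald chi-square of the remainder coefficients
(generalized inverse of their covariance) is referred to chi-square with
`df_spline - 1` degrees of freedom. An exactly linear fitted curve yields
statistic 0 by construction; fits with `df_spline <= 1.001` return p = 1
with a notice rather than a spurious rejection.

## The simulator

The generator emulates an occupational cohort with risk that rises and
then attenuates:

- **Truth**: `s(x) = a x - b x^2` with `s(0) = 0`, maximum at `x* = 15`,
  and HR 2.0 at x = 4, which pins `b = ln2/104`, `a = 30b` (maximum
  HR ≈ 4.48). A linear truth and arbitrary callables are also available
  for null and custom experiments; null simulations here use slope 0.08
  (HR ≈ 2.2 at x = 10, a realistic moderate effect).
- **Exposure**: zero-inflated gamma; `P(x = 0) = 0.13`, and
  gamma(shape 2.5605, scale 2.1343) for the exposed, quantile-calibrated
  so the cohort shares in (0,5], (5,10], (10,15], (15,∞) are ≈ 46/32/8/1
  percent. This is an emulation of the target distribution's category
  shares, not a claim about any particular cohort's generator.
- **Event times**: inverse cumulative-hazard inversion
  `T = H_0^{-1}(-ln U * exp(-s(x)))` with Weibull baseline
  `H_0(t) = (t/34.725)^{4.590}`, administrative censoring at t = 20. The
  Weibull scale was solved offline (large-sample root finding, and
  `calibrate_baseline` reproduces the computation) jointly with the
  censoring horizon so that ≈16% of subjects are cases, the median
  observed case time is ≈17 and the non-case median is 20 (exact by
  construction under purely administrative censoring), with left-skewed
  times. Under these defaults the case-exposure quartiles land near
  (3.0, 5.5, 8.3). Whether censoring should be administrative, random or
  both is underdetermined by those summaries; the administrative scheme is
  the simplest consistent choice.
- `sparse_case_config(n, cases)` rescales the baseline for the sparse-case
  regimes (e.g. 41 cases in n = 500, 40 in n = 5000).

All randomness flows through one seeded `numpy` generator.

What the simulator does *not* emulate: covariate confounding, measurement
error in the exposure, non-administrative loss to follow-up, time-varying
exposure, or heterogeneity across workplaces. Passing tests on these
cohorts therefore demonstrates correctness of the estimation machinery
under a clean Cox data-generating process, not robustness to those
real-data complications.

## Study sizes used in the checks

The frequentist operating characteristics are assessed at reduced scale to
keep the default test run fast: 200 replicates of n = 1000 (~160 events
each). Pointwise 95% CI coverage of the true `s(x)` at x ∈ {2, 4, 7, 9}
is computed for the penalized fit at fixed df = 2 — the covariance is
conditional on the smoothing parameter, so coverage is a property of the
interval at a given smoothing level — and the type-I error of the
truncated-power nonlinearity test is computed under the linear truth at
nominal 5%. Null-distribution and selection checks use 500 replicates at
n = 400 and 20 replicates at n = 800 respectively.

## Known limitations

- With AICc-*selected* smoothing the model-based pointwise intervals
  undercover (measured ≈0.85 at n = 1000 versus ≈0.95-0.97 at fixed
  df 2-4): data-driven selection introduces smoothing bias and extra
  variability that the conditional Wald covariance ignores. This is a
  known property of penalized-spline Wald intervals, not a defect of the
  implementation; fix the df (or report both) when interval calibration
  matters.
- Left truncation, time-varying exposures, stratified baselines, frailty
  and competing risks are out of scope; the data container keeps
  follow-up time as a single column (an entry-time slot would be the
  natural extension).
- Simultaneous confidence bands are not provided — all intervals are
  pointwise.
- Spline estimates are unreliable beyond the observed exposure range and
  where cases are sparse; extrapolation is deliberately linear and
  warned about.
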