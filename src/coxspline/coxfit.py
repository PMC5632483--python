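"""Unpenalized and penalized Cox proportional hazards fitting.

Estimators follow scikit-learn conventions: hyperparameters in
``__init__``, a ``fit(X, y)`` method where ``y`` carries ``(time, event)``,
and fitted attributes with a trailing underscore. ``X`` is an explicit
design matrix (e.g. spline basis columns); the higher-level
exposure-response estimators in :mod:`coxspline.model` build it for you.

Penalized fits maximize ``l(b) - theta * b' Omega b`` where ``l`` is the
log partial likelihood and ``Omega`` a curvature penalty; the effective
degrees of freedom ``df = trace((H + 2 theta Omega)^-1 H)`` move from J
(no penalty) down to the dimension of the penalty null space (1, a linear
log hazard ratio) as theta grows.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from . import _pl
from ._pl import ConvergenceError, DivergenceError, PLOverflowError  # noqa: F401
from .basis import PenaltyMatrix, SplineBasis, curvature_penalty
from .data import SurvivalData

logger = logging.getLogger(__name__)


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


class InvalidTargetError(ValueError):
    """Requested effective df outside the attainable (1, J) range."""


def unpack_survival(y):
    """Extract (time, event) from the accepted y formats.

    Accepts a ``SurvivalData``, a (time, event) tuple/list, a 2-column
    array, a structured array with ``time``/``event`` fields, or a
    DataFrame with those columns.
    """
    if isinstance(y, SurvivalData):
        return y.time, y.event
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return np.asarray(y[0], dtype=float), np.asarray(y[1], dtype=int)
    if hasattr(y, "columns"):
        return y["time"].to_numpy(dtype=float), y["event"].to_numpy(dtype=int)
    arr = np.asarray(y)
    if arr.dtype.names and {"time", "event"} <= set(arr.dtype.names):
        return arr["time"].astype(float), arr["event"].astype(int)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0].astype(float), arr[:, 1].astype(int)
    raise ValueError("y must provide follow-up time and event indicator")


def _standardize(X, allow_singular: bool = False):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        if not allow_singular:
            j = int(np.flatnonzero(sd == 0)[0])
            raise CollinearityError(f"design column {j} is constant")
        sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd
    if not allow_singular and np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    return Xs, mu, sd


class CoxPH(BaseEstimator):
    """Cox proportional hazards regression on an explicit design matrix.

    Parameters
    ----------
    ties : "efron" (default) or "breslow" tie handling in the partial
        likelihood.
    tol : convergence tolerance on the gradient infinity norm.
    max_iter : Newton-Raphson iteration budget (with step-halving).

    Attributes (after fit)
    ----------------------
    coef_ : (J,) coefficient vector b-hat.
    covariance_ : (J, J) inverse-information covariance of b-hat.
    loglik_ : maximized log partial likelihood.
    n_events_ : number of observed events.
    converged_ : always True on normal return.
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-9, max_iter: int = 50):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    def _validate(self, X, time, event, allow_singular: bool = False):
        Xs, mu, sd = _standardize(X, allow_singular=allow_singular)
        if not allow_singular and event.sum() < Xs.shape[1]:
            raise ValueError(
                f"{int(event.sum())} events cannot identify {Xs.shape[1]} coefficients"
            )
        return Xs, mu, sd

    def fit(self, X, y, column_names=None):
        time, event = unpack_survival(y)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != time.shape[0]:
            X = X.T
        Xs, mu, sd = self._validate(X, time, event)
        sc = _pl.prepare(time, event, Xs)
        b_std, l, g, H, conv, it = _pl.newton(
            sc,
            penalty=None,
            ties=self.ties,
            tol=self.tol,
            max_iter=self.max_iter,
            column_names=column_names,
        )
        D = np.diag(1.0 / sd)
        V_std = np.linalg.inv(H)
        self.coef_ = b_std / sd
        self.covariance_ = D @ V_std @ D
        self.loglik_ = float(l)
        self.n_events_ = int(event.sum())
        self.converged_ = bool(conv)
        self.n_iter_ = it
        self.df_ = float(Xs.shape[1])
        self._sc = sc
        self._mu, self._sd = mu, sd
        self._b_std = b_std
        self._info_std = H
        return self

    @property
    def n_params_(self) -> int:
        return self.coef_.shape[0]

    def predict(self, X) -> np.ndarray:
        """Linear predictor X @ coef_ (log relative hazard)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef_

    def baseline_cumulative_hazard(self):
        """Breslow step-function estimate of the cumulative baseline hazard.

        Returns ``(times, cumhaz)`` on the original design scale, i.e. the
        baseline corresponds to all design columns equal to zero.
        """
        times, ch = _pl.breslow_cumhaz(self._sc, self._b_std)
        # centered design baseline refers to columns at their means
        return times, ch * np.exp(-float(self._mu @ self.coef_))

    def cumulative_hazard(self, X, at_times):
        """Model cumulative hazard for rows of X at the given times."""
        times, ch0 = self.baseline_cumulative_hazard()
        lp = self.predict(X)
        return _pl.eval_step(times, ch0, at_times) * np.exp(lp)


class PenalizedCoxPH(CoxPH):
    """Cox regression with a quadratic coefficient penalty theta * b'Omega b.

    Parameters
    ----------
    theta : smoothing parameter >= 0.
    penalty : PenaltyMatrix or (J, J) array Omega.
    covariance : "model" for (H + 2 theta Omega)^-1 (default) or
        "sandwich" for (H+2tO)^-1 H (H+2tO)^-1. Both are stored.

    Extra attributes: ``theta_``, ``df_`` (effective degrees of freedom,
    trace((H + 2 theta Omega)^-1 H)), ``covariance_model_``,
    ``covariance_sandwich_``.
    """

    def __init__(
        self,
        theta: float = 0.0,
        penalty=None,
        covariance: str = "model",
        ties: str = "efron",
        tol: float = 1e-9,
        max_iter: int = 50,
    ):
        super().__init__(ties=ties, tol=tol, max_iter=max_iter)
        self.theta = theta
        self.penalty = penalty
        self.covariance = covariance

    def fit(self, X, y, column_names=None, b0=None):
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        time, event = unpack_survival(y)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != time.shape[0]:
            X = X.T
        # a positive penalty regularizes directions the data do not identify
        # (e.g. B-spline columns with no observations in their support)
        Xs, mu, sd = self._validate(X, time, event, allow_singular=self.theta > 0)
        omega = self.penalty.omega if isinstance(self.penalty, PenaltyMatrix) else self.penalty
        if omega is None:
            omega = np.zeros((Xs.shape[1], Xs.shape[1]))
        omega = np.asarray(omega, dtype=float)
        D = np.diag(1.0 / sd)
        omega_std = D @ omega @ D  # penalty on standardized coefficients
        sc = _pl.prepare(time, event, Xs)
        b_std, l, g, H, conv, it = _pl.newton(
            sc,
            penalty=self.theta * omega_std,
            b0=None if b0 is None else np.asarray(b0) * sd,
            ties=self.ties,
            tol=self.tol,
            max_iter=self.max_iter,
            column_names=column_names,
        )
        A = H + 2.0 * self.theta * omega_std
        A_inv = np.linalg.inv(A)
        V_model = A_inv
        V_sand = A_inv @ H @ A_inv
        self.coef_ = b_std / sd
        self.covariance_model_ = D @ V_model @ D
        self.covariance_sandwich_ = D @ V_sand @ D
        self.covariance_ = (
            self.covariance_sandwich_
            if self.covariance == "sandwich"
            else self.covariance_model_
        )
        self.loglik_ = float(l)
        # at theta = 0 the trace is J by definition; avoid the ill-conditioned
        # numerical trace there
        if self.theta == 0:
            self.df_components_ = np.ones(Xs.shape[1])
        else:
            self.df_components_ = np.diag(A_inv @ H).copy()
        self.df_ = float(self.df_components_.sum())
        self.theta_ = float(self.theta)
        self.penalized_loglik_ = float(l - self.theta * b_std @ omega_std @ b_std)
        self.n_events_ = int(event.sum())
        self.converged_ = bool(conv)
        self.n_iter_ = it
        self._sc = sc
        self._mu, self._sd = mu, sd
        self._b_std = b_std
        self._info_std = H
        self._omega = omega
        return self


# ---------------------------------------------------------------------------
# functional wrappers and smoothing-parameter selection


def log_partial_likelihood(data, design, b, ties: str = "efron"):
    """Log partial likelihood with gradient and (negative-definite) Hessian.

    Returns ``(l, grad, hessian)`` where ``hessian`` is the second
    derivative matrix of l (so ``-hessian`` is the information).
    """
    time, event = unpack_survival(data)
    sc = _pl.prepare(time, event, design)
    l, g, info = _pl.loglik_derivs(sc, b, ties=ties)
    return l, g, -info


def fit_cox(data, design, ties: str = "efron", column_names=None) -> CoxPH:
    """Maximum partial likelihood fit of a Cox model on a design matrix."""
    return CoxPH(ties=ties).fit(design, data, column_names=column_names)


def breslow_baseline(data, design=None, coef=None):
    """Breslow cumulative baseline hazard for a (possibly null) model.

    With ``design``/``coef`` omitted a null model (b = 0) is used.
    Returns ``(times, cumhaz, evaluate)`` where ``evaluate(t)`` gives the
    right-continuous step function value.
    """
    time, event = unpack_survival(data)
    if design is None:
        design = np.zeros((time.shape[0], 1))
        coef = np.zeros(1)
    sc = _pl.prepare(time, event, design)
    times, ch = _pl.breslow_cumhaz(sc, np.asarray(coef, dtype=float))
    return times, ch, lambda at: _pl.eval_step(times, ch, at)


def _spline_design(data: SurvivalData, basis: SplineBasis):
    """Basis columns for the exposure plus any adjustment covariates."""
    B = basis.design_matrix(data.exposure)
    names = [f"f{j + 1}" for j in range(B.shape[1])]
    if data.covariates is not None:
        B = np.hstack([B, data.covariates])
        names += list(data.covariate_names)
    return B, names


def _padded_penalty(basis: SplineBasis, n_cols: int, support) -> np.ndarray:
    pen = curvature_penalty(basis, support=support)
    J = basis.n_functions
    omega = np.zeros((n_cols, n_cols))
    omega[:J, :J] = pen.omega
    return omega


def fit_penalized(
    data: SurvivalData,
    basis: SplineBasis,
    theta: float,
    ties: str = "efron",
    covariance: str = "model",
    b0=None,
) -> PenalizedCoxPH:
    """Penalized spline Cox fit at a given smoothing parameter theta.

    The curvature penalty acts on the spline coefficients only; any
    adjustment covariates are left unpenalized.
    """
    X, names = _spline_design(data, basis)
    support = basis.support or (data.exposure.min(), data.exposure.max())
    omega = _padded_penalty(basis, X.shape[1], support)
    est = PenalizedCoxPH(theta=theta, penalty=omega, covariance=covariance, ties=ties)
    est.fit(X, data, column_names=names, b0=b0)
    est.basis_ = basis
    # effective df attributable to the spline term alone (sum of the
    # per-column df over the penalized basis columns); equals df_ when
    # there are no adjustment covariates
    est.df_spline_ = float(est.df_components_[: basis.n_functions].sum())
    return est


def effective_df(fit: PenalizedCoxPH) -> float:
    """Effective number of parameters trace((H + 2 theta Omega)^-1 H)."""
    return float(fit.df_)


def theta_scale(data: SurvivalData, basis: SplineBasis, ties: str = "efron") -> float:
    """Natural scale for theta: trace(H at b=0) / trace(Omega).

    Multiplying this by a large factor (e.g. 1e8) drives the effective df
    to the penalty null-space dimension.
    """
    X, _ = _spline_design(data, basis)
    support = basis.support or (data.exposure.min(), data.exposure.max())
    omega = _padded_penalty(basis, X.shape[1], support)
    _, _, hess = log_partial_likelihood(data, X, np.zeros(X.shape[1]), ties=ties)
    return float(np.trace(-hess) / np.trace(omega))


def solve_theta_for_df(
    data: SurvivalData,
    basis: SplineBasis,
    target_df: float,
    ties: str = "efron",
    tol: float = 1e-3,
    covariance: str = "model",
):
    """Find theta so the spline term has the requested effective df.

    Bisection on log theta; returns ``(theta, fit)``. The target refers to
    the effective df of the spline term (adjustment covariates contribute
    one df each on top); it must lie strictly between 1 and J.
    """
    J_spline = basis.n_functions
    if not 1.0 < target_df < J_spline:
        raise InvalidTargetError(
            f"target df must lie strictly between 1 and {J_spline}"
        )
    scale = theta_scale(data, basis, ties=ties)
    lo, hi = np.log(scale * 1e-6), np.log(scale * 1e8)
    state = {"b0": None}

    def df_at(log_t):
        try:
            f = fit_penalized(
                data, basis, float(np.exp(log_t)), ties=ties,
                covariance=covariance, b0=state["b0"],
            )
        except (ConvergenceError, DivergenceError):
            # tiny theta on a weakly identified design: treat as unpenalized
            return float(J_spline), None
        state["b0"] = f.coef_
        return f.df_spline_, f

    # df is decreasing in theta
    if df_at(hi)[0] > target_df:
        raise InvalidTargetError("target df not attainable within the theta range")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        df_mid, f = df_at(mid)
        if f is not None and abs(df_mid - target_df) < tol:
            return float(np.exp(mid)), f
        if hi - lo < 1e-14:
            break
        if df_mid > target_df:
            lo = mid
        else:
            hi = mid
    raise ConvergenceError("bisection on theta failed to reach the df tolerance")


def aic(fit) -> float:
    """Akaike information criterion -2 l + 2 df (effective df if penalized)."""
    return -2.0 * fit.loglik_ + 2.0 * fit.df_

def aicc(fit) -> float:
    """Corrected AIC with the event count m as the effective sample size.

    AICc = AIC + 2 df (df + 1) / (m - df - 1); +inf when m <= df + 1.
    """
    m, df = fit.n_events_, fit.df_
    if m <= df + 1:
        return float("inf")
    return aic(fit) + 2.0 * df * (df + 1.0) / (m - df - 1.0)


def select_theta(
    data: SurvivalData,
    basis: SplineBasis,
    criterion: str = "aicc",
    ties: str = "efron",
    covariance: str = "model",
) -> PenalizedCoxPH:
    """Choose theta by minimizing AIC or AICc over log theta.

    A coarse log10-theta grid spanning several decades around the natural
    theta scale is scanned (warm-starting each fit from its smoother
    neighbour), then a golden-section search refines between the
    neighbours of the grid optimum. Returns the winning fit with
    ``theta_``, ``df_`` and the criterion value in ``criterion_value_``.
    """
    if criterion not in ("aic", "aicc"):
        raise ValueError("criterion must be 'aic' or 'aicc'")
    score_fn = aicc if criterion == "aicc" else aic
    scale = theta_scale(data, basis, ties=ties)
    state = {"b0": None}
    cache: dict[float, PenalizedCoxPH] = {}

    def score(log10_t):
        log10_t = float(log10_t)
        if log10_t in cache:
            return score_fn(cache[log10_t])
        try:
            f = fit_penalized(
                data, basis, 10.0**log10_t, ties=ties,
                covariance=covariance, b0=state["b0"],
            )
        except (ConvergenceError, DivergenceError):
            return float("inf")
        state["b0"] = f.coef_
        cache[log10_t] = f
        return score_fn(f)

    center = np.log10(scale)
    grid = np.linspace(center + 5.0, center - 4.0, 19)  # smooth -> rough
    scores = np.array([score(g) for g in grid])
    if not np.isfinite(scores).any():
        raise ConvergenceError("no theta in the search range produced a fit")
    i = int(np.nanargmin(scores))
    lo = grid[min(i + 1, grid.size - 1)]
    hi = grid[max(i - 1, 0)]
    if lo < hi:
        optimize.minimize_scalar(
            score, bounds=(lo, hi), method="bounded", options={"xatol": 0.01}
        )
    best_key = min(cache, key=lambda k: score_fn(cache[k]))
    fit = cache[best_key]
    fit.criterion_ = criterion
    fit.criterion_value_ = float(score_fn(fit))
    logger.info(
        "selected theta=%.4g (df=%.3f, %s=%.3f)",
        fit.theta_, fit.df_, criterion, fit.criterion_value_,
    )
    return fit
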