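"""High-level exposure-response estimator in scikit-learn style.

``SplineCoxPH`` bundles basis construction, (penalized) Cox fitting, and
smoothing selection behind a single ``fit``; the lower-level pieces live
in :mod:`coxspline.basis` and :mod:`coxspline.coxfit`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import coxfit, effects
from .basis import (
    knots_from_case_quartiles,
    make_bspline_basis,
    make_truncated_power_basis,
)
from .data import SurvivalData


class SplineCoxPH(BaseEstimator):
    """Cox proportional hazards model with a spline exposure-response curve.

    Parameters
    ----------
    basis : "truncated_power" or "bspline".
    degree : polynomial degree of the spline (1 = piecewise linear,
        3 = cubic; default 1 for the truncated power basis, set 3 with
        ``basis="bspline"`` for penalized smooth fits).
    knots : "case_quartiles" (knots at quantiles of the case exposures,
        the default for the truncated power basis) or an explicit sequence.
        For B-splines an explicit sequence gives the interior knots;
        otherwise ``n_intervals`` equally spaced spans are used.
    n_knots : number of case-quantile knots (3 = quartiles).
    n_intervals : B-spline spans between the boundary knots (default 15,
        i.e. 17 basis functions of degree 3 after dropping the constant).
    theta, df, criterion : smoothing control, in order of precedence. A
        numeric ``theta`` fixes the penalty weight; ``df`` solves theta for
        a target effective degrees of freedom; ``criterion`` ("aic" or
        "aicc") selects theta by information-criterion search. All three
        ``None`` gives the unpenalized regression-spline fit.
    ties : "efron" (default) or "breslow".
    covariance : "model" ((H + 2 theta Omega)^-1, default) or "sandwich".

    Attributes
    ----------
    basis_ : the constructed ``SplineBasis``.
    coef_, covariance_ : coefficients and covariance for all design
        columns (basis columns first, covariates after).
    loglik_, df_, theta_, n_events_, aic_, aicc_ : fit summaries.
    """

    def __init__(
        self,
        basis: str = "truncated_power",
        degree: int = 1,
        knots="case_quartiles",
        n_knots: int = 3,
        n_intervals: int = 15,
        theta: float | None = None,
        df: float | None = None,
        criterion: str | None = None,
        ties: str = "efron",
        covariance: str = "model",
        quantile_method: str = "weibull",
    ):
        self.basis = basis
        self.degree = degree
        self.knots = knots
        self.n_knots = n_knots
        self.n_intervals = n_intervals
        self.theta = theta
        self.df = df
        self.criterion = criterion
        self.ties = ties
        self.covariance = covariance
        self.quantile_method = quantile_method

    # -- construction helpers -------------------------------------------------

    def _as_survival_data(self, X, y) -> SurvivalData:
        if isinstance(X, SurvivalData):
            return X
        X = np.asarray(X, dtype=float)
        time, event = coxfit.unpack_survival(y)
        if X.ndim == 1:
            return SurvivalData(time=time, event=event, exposure=X)
        return SurvivalData(
            time=time, event=event, exposure=X[:, 0], covariates=X[:, 1:] if X.shape[1] > 1 else None
        )

    def _build_basis(self, data: SurvivalData):
        lo, hi = float(data.exposure.min()), float(data.exposure.max())
        if self.basis == "truncated_power":
            if isinstance(self.knots, str):
                knots = knots_from_case_quartiles(
                    data, self.n_knots, quantile_method=self.quantile_method
                )
            else:
                knots = np.asarray(self.knots, dtype=float)
            return make_truncated_power_basis(self.degree, knots), (lo, hi)
        if self.basis == "bspline":
            interior = None if isinstance(self.knots, str) else np.asarray(self.knots, float)
            b = make_bspline_basis(
                self.degree, self.n_intervals, (lo, hi),
                drop_constant=True, interior_knots=interior,
            )
            return b, (lo, hi)
        raise ValueError(f"unknown basis kind {self.basis!r}")

    # -- fitting --------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit to exposures (and optional covariates) with survival outcome y.

        ``X`` may be a ``SurvivalData`` (y ignored), an exposure vector, or
        a matrix whose first column is the exposure and remaining columns
        are adjustment covariates; ``y`` then carries (time, event).
        """
        data = self._as_survival_data(X, y)
        basis, support = self._build_basis(data)
        basis.support = basis.support or support
        penalized = (
            self.theta is not None or self.df is not None or self.criterion is not None
        )
        if not penalized:
            design, names = coxfit._spline_design(data, basis)
            res = coxfit.fit_cox(data, design, ties=self.ties, column_names=names)
        elif self.theta is not None:
            res = coxfit.fit_penalized(
                data, basis, float(self.theta), ties=self.ties, covariance=self.covariance
            )
        elif self.df is not None:
            _, res = coxfit.solve_theta_for_df(
                data, basis, float(self.df), ties=self.ties, covariance=self.covariance
            )
        else:
            res = coxfit.select_theta(
                data, basis, criterion=self.criterion, ties=self.ties,
                covariance=self.covariance,
            )
        self.basis_ = basis
        self.result_ = res
        self.data_ = data
        self.coef_ = res.coef_
        self.covariance_ = res.covariance_
        self.loglik_ = res.loglik_
        self.df_ = res.df_
        self.theta_ = getattr(res, "theta_", 0.0)
        self.n_events_ = res.n_events_
        self.converged_ = res.converged_
        self.aic_ = coxfit.aic(res)
        self.aicc_ = coxfit.aicc(res)
        self._mu = res._mu
        return self

    # -- interpretation -------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """ln hazard ratio at the given exposures, referenced at x = 0."""
        x = np.asarray(X, dtype=float)
        x = x[:, 0] if x.ndim == 2 else x
        J = self.basis_.n_functions
        C = self.basis_.design_matrix(x) - self.basis_.evaluate(0.0)[None, :]
        return C @ self.coef_[:J]

    def lnhr(self, x, x_ref: float = 0.0):
        """Point estimate and standard error of ln HR(x vs x_ref)."""
        return effects.lnhr_contrast(self, x, x_ref=x_ref)

    def hazard_ratio(self, x, x_ref: float = 0.0) -> float:
        return float(np.exp(self.lnhr(x, x_ref)[0]))

    def curve(self, grid=None, x_ref: float = 0.0, level: float = 0.95):
        """Exposure-response curve with pointwise confidence limits."""
        if grid is None:
            lo, hi = self.basis_.support
            grid = np.linspace(lo, hi, 200)
        return effects.hr_curve(self, grid, x_ref=x_ref, level=level)

    def nonlinearity_test(self):
        """Test H0: s(x) = b x against the fitted basis expansion."""
        from . import inference

        if self.theta_ and self.theta_ > 0:
            return inference.pspline_nonlinearity_test(self, self.data_.exposure)
        return inference.wald_test_nonlinearity_tpb(self, self.basis_)

    def summary(self):
        """Fit summary as a data frame (coefficient table plus fit stats)."""
        import pandas as pd

        J = self.basis_.n_functions
        names = [f"f{j + 1}" for j in range(J)] + list(self.data_.covariate_names)
        se = np.sqrt(np.diag(self.covariance_))
        df = pd.DataFrame({"term": names, "coef": self.coef_, "se": se})
        df.attrs.update(
            loglik=self.loglik_, df=self.df_, theta=self.theta_,
            aic=self.aic_, aicc=self.aicc_, n_events=self.n_events_,
        )
        return df
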