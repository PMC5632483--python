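"""Nonlinearity tests and candidate-model comparison.

Both tests address H0: s(x) = b x (a linear log hazard ratio in the
exposure) against the fitted basis expansion s(x) = sum_j b_j f_j(x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import coxfit
from .basis import SplineBasis
from .data import SurvivalData


class NumericalSingularityError(np.linalg.LinAlgError):
    """Sub-covariance for the tested coefficients is numerically singular."""


@dataclass
class NonlinearityTest:
    """Chi-square test of a linear exposure-response against a spline fit."""

    statistic: float
    df: float
    p_value: float
    null_form: str = "s(x) = b*x"
    alt_form: str = "s(x) = sum_j b_j f_j(x)"
    note: str = ""

    def __str__(self):
        return (
            f"nonlinearity test: chi2 = {self.statistic:.3f} on "
            f"{self.df:.2f} df, p = {self.p_value:.4g}"
        )


def wald_test_nonlinearity_tpb(
    fit, basis: SplineBasis, null_degree: int = 1
) -> NonlinearityTest:
    """Wald chi-square that all spline coefficients beyond the polynomial
    terms of degree ``null_degree`` are zero.

    For a degree-1 truncated power basis with K knots this tests the K
    truncated-power coefficients jointly (df = J - 1).
    """
    J = basis.n_functions
    idx = np.arange(null_degree, J)
    b = np.asarray(fit.coef_)[idx]
    V = np.asarray(fit.covariance_)[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise NumericalSingularityError(
            "sub-covariance of the nonlinear coefficients is singular"
        ) from exc
    if not np.isfinite(stat):
        raise NumericalSingularityError(
            "sub-covariance of the nonlinear coefficients is singular"
        )
    df = float(idx.size)
    return NonlinearityTest(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        alt_form=f"truncated power basis, J={J}",
    )


def pspline_nonlinearity_test(fit, exposure) -> NonlinearityTest:
    """Chi-square test of the nonlinear component of a penalized fit.

    The fitted curve is decomposed into a linear component — the
    least-squares projection of the fitted basis values onto [1, x] over
    the observed exposures — and a nonlinear remainder. The Wald
    chi-square of the remainder is referred to a chi-square with
    (effective df - 1) degrees of freedom. An exactly linear fitted curve
    gives statistic 0 by construction.
    """
    basis = getattr(fit, "basis_", None)
    if basis is None:
        raise ValueError("fit must carry its spline basis (basis_)")
    x = np.asarray(exposure, dtype=float)
    J = basis.n_functions
    b = np.asarray(fit.coef_)[:J]
    V = np.asarray(fit.covariance_)[:J, :J]
    B = basis.design_matrix(x)
    A = np.column_stack([np.ones_like(x), x])
    # residual-maker of the regression of each basis column on [1, x]
    coefs, *_ = np.linalg.lstsq(A, B, rcond=None)
    R = B - A @ coefs
    Q, *_ = np.linalg.lstsq(B, R, rcond=None)  # b -> nonlinear remainder coefs
    b_nl = Q @ b
    C_nl = Q @ V @ Q.T
    eff_df = float(getattr(fit, "df_spline_", getattr(fit, "df_", J)))
    if eff_df <= 1.0 + 1e-3:
        return NonlinearityTest(
            statistic=0.0, df=0.0, p_value=1.0,
            note="effective df <= 1: penalized fit is already linear",
        )
    stat = float(b_nl @ np.linalg.pinv(C_nl, rcond=1e-10) @ b_nl)
    stat = max(stat, 0.0)
    df = eff_df - 1.0
    return NonlinearityTest(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        alt_form=f"penalized B-spline, effective df={eff_df:.2f}",
    )


# ---------------------------------------------------------------------------
# candidate-model comparison


def _linear_design(data: SurvivalData):
    return data.exposure[:, None], ["exposure"]


def _log_design(data: SurvivalData, offset: float):
    if offset <= 0 and data.exposure.min() <= 0:
        raise ValueError("logarithmic form needs a positive offset for zero exposures")
    return np.log(data.exposure + offset)[:, None], [f"log(exposure+{offset:g})"]


def compare_models(
    data: SurvivalData,
    specs,
    ties: str = "efron",
    log_offset: float = 1.0,
    return_fits: bool = False,
):
    """Fit candidate exposure-response forms and tabulate AIC.

    ``specs`` is a list of model specifications:

    * ``"linear"`` — single linear exposure term;
    * ``"logarithmic"`` — ln(exposure + offset) term;
    * ``{"kind": "linear_spline", "knot": k}`` — degree-1 truncated power
      basis with a single knot;
    * ``{"kind": "tpb", "degree": p, "knots": [...]}``;
    * ``{"kind": "pspline", "df": 2}`` / ``{"kind": "pspline",
      "criterion": "aicc"}`` / ``{"kind": "pspline", "theta": t}`` —
      penalized cubic B-spline (``degree``/``n_intervals`` overridable).

    Any covariates in ``data`` enter every model unpenalized. Returns a
    table of (model, loglik, df, aic, aicc); effective df is used for
    penalized fits.
    """
    from .model import SplineCoxPH

    rows, fits = [], []
    for spec in specs:
        if isinstance(spec, str):
            spec = {"kind": spec}
        kind = spec["kind"]
        if kind == "linear":
            design, names = _linear_design(data)
            fit = _fit_plain(data, design, names, ties)
            label = "linear"
        elif kind == "logarithmic":
            design, names = _log_design(data, spec.get("offset", log_offset))
            fit = _fit_plain(data, design, names, ties)
            label = names[0]
        elif kind in ("linear_spline", "tpb"):
            degree = spec.get("degree", 1)
            if "knots" in spec:
                knots = np.atleast_1d(spec["knots"])
            elif "knot" in spec:
                knots = np.atleast_1d(spec["knot"])
            else:
                knots = "case_quartiles"  # knots at case-exposure quartiles
            est = SplineCoxPH(
                basis="truncated_power", degree=degree, knots=knots, ties=ties
            ).fit(data)
            knot_desc = (
                "case quartiles" if isinstance(knots, str) else list(np.round(knots, 3))
            )
            fit, label = est, f"tpb degree {degree}, knots {knot_desc}"
        elif kind == "pspline":
            est = SplineCoxPH(
                basis="bspline",
                degree=spec.get("degree", 3),
                n_intervals=spec.get("n_intervals", 15),
                theta=spec.get("theta"),
                df=spec.get("df"),
                criterion=spec.get("criterion", "aicc" if "theta" not in spec and "df" not in spec else None),
                ties=ties,
            ).fit(data)
            fit, label = est, f"pspline ({ {k: v for k, v in spec.items() if k != 'kind'} })"
        else:
            raise ValueError(f"unknown model spec {spec!r}")
        rows.append(
            {
                "model": label,
                "loglik": fit.loglik_,
                "df": fit.df_,
                "aic": coxfit.aic(fit),
                "aicc": coxfit.aicc(fit),
            }
        )
        fits.append(fit)
    table = pd.DataFrame(rows)
    return (table, fits) if return_fits else table


def _fit_plain(data: SurvivalData, design, names, ties):
    if data.covariates is not None:
        design = np.hstack([design, data.covariates])
        names = list(names) + list(data.covariate_names)
    return coxfit.fit_cox(data, design, ties=ties, column_names=names)
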