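"""Model-free and residual-based diagnostics.

Kaplan-Meier curves by exposure group give a model-free first look at how
survival varies with exposure; martingale residuals from a covariate-only
Cox fit, plotted against exposure with loess smooths, suggest the
functional form the exposure term should take.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coxfit
from .data import SurvivalData

logger = logging.getLogger(__name__)

#: default exposure grouping: unexposed, (0,5], (5,10], (10,15], >15
DEFAULT_EXPOSURE_CUTS = (0.0, 5.0, 10.0, 15.0)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function for one group."""

    times: np.ndarray
    survival: np.ndarray
    label: str = ""
    n: int = 0
    n_events: int = 0

    def at(self, t):
        """Survival probability at time(s) t (right-continuous, S(0)=1)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]


def exposure_groups(data: SurvivalData, cuts=DEFAULT_EXPOSURE_CUTS) -> np.ndarray:
    """Categorical exposure labels from cut points (first cut = unexposed)."""
    cuts = list(cuts)
    labels = np.empty(data.n, dtype=object)
    labels[data.exposure <= cuts[0]] = "unexposed"
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        labels[(data.exposure > lo) & (data.exposure <= hi)] = f"({lo:g},{hi:g}]"
    labels[data.exposure > cuts[-1]] = f">{cuts[-1]:g}"
    return labels


def _km_one(time, event, label="", n_total=None):
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e == 1])
    surv = []
    s = 1.0
    n = t.size
    for u in uniq:
        at_risk = np.sum(t >= u)
        d = np.sum((t == u) & (e == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return SurvivalCurve(
        times=uniq,
        survival=np.asarray(surv),
        label=label,
        n=n,
        n_events=int(e.sum()),
    )


def kaplan_meier(data: SurvivalData, groups=None) -> list[SurvivalCurve]:
    """Product-limit survival estimates, optionally per group.

    ``groups`` is a categorical label per subject (see
    :func:`exposure_groups` for the default exposure grouping); censored
    subjects leave the risk set without a survival drop. Empty groups are
    skipped with a logged notice.
    """
    if groups is None:
        return [_km_one(data.time, data.event, label="all")]
    groups = np.asarray(groups)
    curves = []
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            logger.info("skipping empty group %r", g)
            continue
        curves.append(_km_one(data.time[mask], data.event[mask], label=str(g)))
    return curves


def martingale_residuals(
    data: SurvivalData, fit=None, design=None
) -> np.ndarray:
    """Martingale residuals r_i = c_i - Lambda0(t_i) exp(lp_i).

    ``fit``/``design`` describe a Cox model *excluding* the exposure (for
    functional-form diagnostics); omit both for null-model residuals
    (the Nelson-Aalen based c_i - Lambda-hat(t_i)).
    """
    if fit is None:
        _, _, lam = coxfit.breslow_baseline(data)
        return data.event - lam(data.time)
    if design is None:
        raise ValueError("pass the design matrix the fit was computed on")
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] != data.n:
        design = design.T
    lp = design @ fit.coef_
    _, _, lam = coxfit.breslow_baseline(data, design, fit.coef_)
    return data.event - lam(data.time) * np.exp(lp)


def deviance_residuals(martingale: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Deviance transform of martingale residuals.

    d_i = sign(r_i) sqrt(-2 [r_i + c_i ln(c_i - r_i)]); symmetrizes the
    skewed martingale residuals.
    """
    r = np.asarray(martingale, dtype=float)
    c = np.asarray(event, dtype=float)
    inner = np.where(c > 0, c * np.log(np.maximum(c - r, 1e-300)), 0.0)
    return np.sign(r) * np.sqrt(np.maximum(-2.0 * (r + inner), 0.0))


def loess_smooth(x, y, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Local polynomial (loess) smooth with tricube weights, fitted at x.

    ``span`` is the fraction of nearest neighbours entering each local
    fit; spans above 1 use all points with the bandwidth inflated by the
    span. Windows with fewer than degree+1 distinct points are widened.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    k = n if span >= 1 else max(int(np.ceil(span * n)), degree + 2)
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        if span >= 1:
            dmax = d.max() * span
        else:
            dmax = np.partition(d, k - 1)[k - 1]
        while True:
            if dmax <= 0:
                fitted[i] = y[d == 0].mean()
                break
            w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
            active = w > 0
            if np.unique(x[active]).size < degree + 1:
                logger.info("widening loess window at x=%.3g", x[i])
                dmax *= 1.5
                continue
            xa = x[active] - x[i]
            V = np.vander(xa, degree + 1, increasing=True)
            sw = np.sqrt(w[active])
            beta, *_ = np.linalg.lstsq(V * sw[:, None], y[active] * sw, rcond=None)
            fitted[i] = beta[0]
            break
    return fitted


def functional_form_table(
    data: SurvivalData,
    fit=None,
    design=None,
    spans=(0.4, 0.8, 1.2, 1.6, 2.0),
    degree: int = 2,
) -> pd.DataFrame:
    """Martingale residuals vs exposure with one loess smooth per span."""
    resid = martingale_residuals(data, fit=fit, design=design)
    out = pd.DataFrame({"exposure": data.exposure, "residual": resid})
    order = np.argsort(data.exposure, kind="stable")
    for sp in spans:
        sm = np.empty(data.n)
        sm[order] = loess_smooth(
            data.exposure[order], resid[order], span=sp, degree=degree
        )
        out[f"loess_{sp:g}"] = sm
    return out


def functional_form_plot(
    data: SurvivalData,
    fit=None,
    design=None,
    spans=(0.4, 0.8, 1.2, 1.6, 2.0),
    degree: int = 2,
    path=None,
):
    """Residual-vs-exposure scatter with loess curves and an exposure rug.

    Returns ``(figure, table)``; pass ``path`` to also save the figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    table = functional_form_table(data, fit=fit, design=design, spans=spans, degree=degree)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(table["exposure"], table["residual"], s=8, alpha=0.3, color="gray")
    order = np.argsort(table["exposure"].to_numpy())
    for sp in spans:
        ax.plot(
            table["exposure"].to_numpy()[order],
            table[f"loess_{sp:g}"].to_numpy()[order],
            label=f"span {sp:g}",
        )
    ax.plot(
        data.exposure, np.full(data.n, table["residual"].min() - 0.05), "|",
        color="black", markersize=4, alpha=0.4,
    )
    ax.set_xlabel("exposure")
    ax.set_ylabel("martingale residual")
    ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    return fig, table


def km_plot(curves: list[SurvivalCurve], path=None):
    """Step plot of Kaplan-Meier curves."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for c in curves:
        t = np.concatenate([[0.0], c.times])
        s = np.concatenate([[1.0], c.survival])
        ax.step(t, s, where="post", label=f"{c.label} (n={c.n})")
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    return fig
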