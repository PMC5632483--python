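"""Cox log partial likelihood internals.

Everything here works on a sorted copy of the data and an explicit design
matrix. Ties are handled by the Efron correction (default) or the Breslow
approximation. The Newton-Raphson driver supports an optional quadratic
coefficient penalty theta * b' Omega b for penalized spline fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class PLOverflowError(FloatingPointError):
    """Linear predictor overflowed; consider centering design columns."""


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge within the iteration budget."""


class DivergenceError(RuntimeError):
    """Monotone likelihood: a coefficient diverges to +/- infinity."""


@dataclass
class _SortedCox:
    """Design and outcomes sorted by ascending follow-up time."""

    t: np.ndarray
    e: np.ndarray
    X: np.ndarray
    order: np.ndarray
    uniq: np.ndarray  # unique death times, ascending
    first_risk: np.ndarray  # index of first subject at risk for each death time
    death_slices: list  # row indices (into sorted arrays) of deaths per time
    d_counts: np.ndarray


def prepare(time, event, X) -> _SortedCox:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.shape[0]:
        X = X.T
    order = np.argsort(time, kind="stable")
    t, e, Xs = time[order], event[order], X[order]
    dt = t[e == 1]
    uniq = np.unique(dt)
    first_risk = np.searchsorted(t, uniq, side="left")
    death_rows = np.flatnonzero(e == 1)
    slices = []
    counts = []
    for u in uniq:
        rows = death_rows[t[death_rows] == u]
        slices.append(rows)
        counts.append(rows.size)
    return _SortedCox(t, e, Xs, order, uniq, first_risk, slices, np.array(counts))


def loglik_derivs(sc: _SortedCox, b, ties: str = "efron", want_derivs: bool = True):
    """Log partial likelihood, gradient, and (PSD) information matrix.

    Returns ``(l, grad, info)`` with ``info = -Hessian of l``. With
    ``want_derivs=False`` the gradient/information are returned as None.
    """
    b = np.asarray(b, dtype=float)
    J = sc.X.shape[1]
    eta = sc.X @ b
    if not np.all(np.isfinite(eta)):
        raise PLOverflowError(
            "non-finite linear predictor; center/scale design columns"
        )
    shift = eta.mean()  # the partial likelihood is invariant to this shift
    with np.errstate(over="ignore"):
        w = np.exp(eta - shift)
    if not np.all(np.isfinite(w)):
        raise PLOverflowError(
            "exp(linear predictor) overflowed; center/scale design columns"
        )
    wX = w[:, None] * sc.X if want_derivs else None

    n_u = sc.uniq.size
    S0 = np.empty(n_u)
    S1 = np.empty((n_u, J)) if want_derivs else None
    S2 = np.empty((n_u, J, J)) if want_derivs else None
    ptr = sc.t.size
    s0, s1, s2 = 0.0, np.zeros(J), np.zeros((J, J))
    for i in range(n_u - 1, -1, -1):
        f = sc.first_risk[i]
        if f < ptr:
            s0 += w[f:ptr].sum()
            if want_derivs:
                s1 = s1 + wX[f:ptr].sum(axis=0)
                s2 = s2 + sc.X[f:ptr].T @ wX[f:ptr]
            ptr = f
        S0[i] = s0
        if want_derivs:
            S1[i], S2[i] = s1, s2

    l = 0.0
    g = np.zeros(J) if want_derivs else None
    H = np.zeros((J, J)) if want_derivs else None
    for i in range(n_u):
        rows = sc.death_slices[i]
        d = rows.size
        l += float((eta[rows] - shift).sum())
        if want_derivs:
            g += sc.X[rows].sum(axis=0)
        if ties == "breslow" or d == 1:
            den, num = S0[i], (S1[i] if want_derivs else None)
            l -= d * np.log(den)
            if want_derivs:
                mu = num / den
                g -= d * mu
                H += d * (S2[i] / den - np.outer(mu, mu))
        elif ties == "efron":
            s0d = w[rows].sum()
            s1d = wX[rows].sum(axis=0) if want_derivs else None
            s2d = sc.X[rows].T @ wX[rows] if want_derivs else None
            for r in range(d):
                frac = r / d
                den = S0[i] - frac * s0d
                l -= np.log(den)
                if want_derivs:
                    num = S1[i] - frac * s1d
                    mu = num / den
                    g -= mu
                    H += (S2[i] - frac * s2d) / den - np.outer(mu, mu)
        else:
            raise ValueError(f"unknown ties method {ties!r}")
    return l, g, H


def newton(
    sc: _SortedCox,
    penalty: np.ndarray | None = None,
    b0: np.ndarray | None = None,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
    coef_bound: float = 200.0,
    column_names=None,
):
    """Maximize l(b) - b' Q b by Newton-Raphson with step-halving.

    ``penalty`` is the full quadratic-form matrix Q (i.e. theta * Omega);
    the objective gradient is grad(l) - 2 Q b and the information is
    H + 2 Q. Assumes the caller standardized the design, so a coefficient
    wandering past ``coef_bound`` signals monotone likelihood.

    Returns ``(b, loglik, grad_l, info_l, converged, n_iter)`` where
    loglik/grad/info are of the *unpenalized* partial likelihood at b.
    """
    J = sc.X.shape[1]
    detect_divergence = penalty is None
    Q = np.zeros((J, J)) if penalty is None else np.asarray(penalty, dtype=float)
    b = np.zeros(J) if b0 is None else np.array(b0, dtype=float)

    def objective(l, b):
        return l - float(b @ Q @ b)

    def raise_divergence(vec):
        j = int(np.argmax(np.abs(vec)))
        name = column_names[j] if column_names else f"column {j}"
        raise DivergenceError(
            f"monotone likelihood: coefficient for {name} is diverging"
        )

    def check_divergence(b):
        # only meaningful without a penalty: the quadratic penalty bounds b
        if detect_divergence and np.max(np.abs(b)) > coef_bound:
            raise_divergence(b)

    l, g, H = loglik_derivs(sc, b, ties)
    obj = objective(l, b)
    converged = False
    it = 0
    last_move = None  # last accepted step, for monotone-likelihood detection
    for it in range(1, max_iter + 1):
        grad_pen = g - 2.0 * Q @ b
        info_pen = H + 2.0 * Q
        if np.max(np.abs(grad_pen)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info_pen, grad_pen)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info_pen, grad_pen, rcond=None)[0]
        # objective values carry rounding noise proportional to the size of
        # the likelihood and penalty terms; scale stopping/acceptance by it
        noise = 1e-9 * (1.0 + abs(l) + abs(float(b @ Q @ b)))
        # quadratic-model improvement below rounding: one last step, then stop
        last_step = 0.5 * abs(float(grad_pen @ step)) < noise or np.max(
            np.abs(step)
        ) < 1e-10 * (1.0 + np.max(np.abs(b)))
        # step halving on the penalized objective (likelihood value only;
        # derivatives are recomputed once a step is accepted)
        scale = 1.0
        accepted = False
        for _ in range(40):
            b_new = b + scale * step
            try:
                l_new, _, _ = loglik_derivs(sc, b_new, ties, want_derivs=False)
            except PLOverflowError:
                scale *= 0.5
                continue
            if objective(l_new, b_new) >= obj - noise:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            converged = last_step or converged
            break
        last_move = scale * step
        b = b_new
        l, g, H = loglik_derivs(sc, b, ties)
        obj = objective(l, b)
        check_divergence(b)
        if last_step:
            converged = True
            break
    grad_pen = g - 2.0 * Q @ b
    converged = converged or bool(np.max(np.abs(grad_pen)) < tol)
    if not converged:
        if detect_divergence and np.max(np.abs(b)) > 0.5 * coef_bound:
            raise_divergence(b)
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(|grad| = {np.max(np.abs(grad_pen)):.3e})"
        )
    # a monotone partial likelihood flattens while the coefficient keeps
    # travelling: "convergence" with a still-large final step means the
    # maximum lies at infinity along that coordinate
    if detect_divergence and last_move is not None and np.max(np.abs(last_move)) > 0.1:
        raise_divergence(last_move)
    return b, l, g, H, converged, it


def breslow_cumhaz(sc: _SortedCox, b):
    """Breslow estimator of the cumulative baseline hazard.

    Returns ``(times, cumhaz)``: unique death times and the step-function
    values of Lambda_0 at those times (0 before the first death time).
    The linear predictor is taken on the same scale as the design in
    ``sc``; use consistently with it.
    """
    eta = sc.X @ np.asarray(b, dtype=float)
    w = np.exp(eta)
    increments = np.empty(sc.uniq.size)
    ptr = sc.t.size
    s0 = 0.0
    for i in range(sc.uniq.size - 1, -1, -1):
        f = sc.first_risk[i]
        if f < ptr:
            s0 += w[f:ptr].sum()
            ptr = f
        increments[i] = sc.d_counts[i] / s0
    return sc.uniq.copy(), np.cumsum(increments)


def eval_step(times, values, at):
    """Evaluate a right-continuous step function (0 before first jump)."""
    at = np.asarray(at, dtype=float)
    idx = np.searchsorted(times, at, side="right")
    padded = np.concatenate([[0.0], values])
    return padded[idx]
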