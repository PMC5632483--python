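import numpy as np
import pytest

from coxspline import (
    SimulationConfig,
    SurvivalData,
    aic,
    aicc,
    breslow_baseline,
    fit_cox,
    fit_penalized,
    knots_from_case_quartiles,
    linear_true_curve,
    log_partial_likelihood,
    make_bspline_basis,
    make_truncated_power_basis,
    select_theta,
    simulate_cohort,
    solve_theta_for_df,
    theta_scale,
)
from coxspline.coxfit import CollinearityError, InvalidTargetError
from coxspline._pl import DivergenceError, PLOverflowError
from dataclasses import replace


class TestLogPartialLikelihood:
    def test_risk_set_enumeration_three_subjects(self, tiny_all_events):
        """Three events at 1 < 2 < 3, b = 0: risk sets of size 3, 2, 1 give
        l = -ln 6."""
        design = np.array([[1.0], [0.0], [0.0]])
        l, g, h = log_partial_likelihood(tiny_all_events, design, np.zeros(1))
        assert np.isclose(l, -np.log(6.0))

    def test_null_value_is_log_risk_set_sizes(self, rng):
        """At b = 0 with no ties, l = -sum over events of ln(risk-set size)."""
        n = 30
        t = rng.uniform(1, 10, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        data = SurvivalData(time=t, event=e, exposure=np.zeros(n))
        design = rng.normal(size=(n, 2))
        l, _, _ = log_partial_likelihood(data, design, np.zeros(2))
        expected = -sum(np.log(np.sum(t >= t[i])) for i in range(n) if e[i] == 1)
        assert np.isclose(l, expected)

    def test_gradient_matches_finite_differences(self, rng):
        n = 50
        data = SurvivalData(
            time=rng.uniform(1, 5, n),
            event=np.r_[1, rng.integers(0, 2, n - 1)],
            exposure=np.zeros(n),
        )
        design = rng.normal(size=(n, 3))
        b = np.array([0.3, -0.2, 0.1])
        l, g, h = log_partial_likelihood(data, design, b)
        eps = 1e-6
        for j in range(3):
            db = np.zeros(3)
            db[j] = eps
            lp, _, _ = log_partial_likelihood(data, design, b + db)
            lm, _, _ = log_partial_likelihood(data, design, b - db)
            assert np.isclose(g[j], (lp - lm) / (2 * eps), atol=1e-6)

    def test_hessian_negative_definite(self, rng):
        n = 40
        data = SurvivalData(
            time=rng.uniform(1, 5, n), event=np.ones(n, int), exposure=np.zeros(n)
        )
        design = rng.normal(size=(n, 2))
        _, _, h = log_partial_likelihood(data, design, np.zeros(2))
        assert np.all(np.linalg.eigvalsh(h) < 0)

    def test_overflow_raises_with_guidance(self, tiny_all_events):
        design = np.array([[1e4], [0.0], [-1e4]])
        with pytest.raises(PLOverflowError):
            log_partial_likelihood(tiny_all_events, design, np.array([1e3]))


class TestFitCox:
    def test_closed_form_single_covariate(self, tiny_all_events):
        """Events at 1 < 2 < 3 with z = (1, 0, 1): the score equation
        1 - 2u^2/(term) ... solves to b-hat = -ln(2)/2."""
        fit = fit_cox(tiny_all_events, np.array([[1.0], [0.0], [1.0]]))
        assert np.isclose(fit.coef_[0], -0.5 * np.log(2.0), atol=1e-8)
        assert fit.converged_

    def test_monotone_likelihood_raises_divergence(self):
        data = SurvivalData(time=[1.0, 2.0], event=[1, 1], exposure=[0.0, 0.0])
        with pytest.raises(DivergenceError):
            fit_cox(data, np.array([[1.0], [0.0]]))

    def test_rank_deficient_design_raises(self, cohort1000):
        x = cohort1000.exposure
        with pytest.raises(CollinearityError):
            fit_cox(cohort1000, np.column_stack([x, 2.0 * x]))

    def test_matches_reference_implementation(self, cohort1000):
        """Truncated-power-basis coefficients and covariance reproduce an
        independent Cox implementation (lifelines) to 1e-6."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        knots = knots_from_case_quartiles(cohort1000)
        basis = make_truncated_power_basis(1, knots)
        X = basis.design_matrix(cohort1000.exposure)
        fit = fit_cox(cohort1000, X)
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
        df["T"], df["E"] = cohort1000.time, cohort1000.event
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef_, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(
            fit.covariance_, cph.variance_matrix_.values, atol=1e-6
        )

    def test_local_maximum(self, cohort1000, rng):
        knots = knots_from_case_quartiles(cohort1000)
        basis = make_truncated_power_basis(1, knots)
        X = basis.design_matrix(cohort1000.exposure)
        fit = fit_cox(cohort1000, X)
        l_hat, _, _ = log_partial_likelihood(cohort1000, X, fit.coef_)
        for _ in range(10):
            delta = rng.normal(size=4)
            delta *= 1e-2 / np.linalg.norm(delta)
            l_pert, _, _ = log_partial_likelihood(cohort1000, X, fit.coef_ + delta)
            assert l_pert <= l_hat + 1e-12


@pytest.fixture(scope="module")
def cohort():
    # seed chosen so every B-spline basis function has data support,
    # making the unpenalized (theta = 0) limit well defined
    return simulate_cohort(SimulationConfig(n=1000, seed=11))


@pytest.fixture(scope="module")
def basis(cohort):
    return make_bspline_basis(3, 15, (cohort.exposure.min(), cohort.exposure.max()))


class TestPenalizedFit:
    def test_zero_theta_equals_unpenalized(self, cohort):
        # modest well-identified basis: the unpenalized MLE exists cleanly
        small = make_bspline_basis(
            3, 6, (cohort.exposure.min(), cohort.exposure.max())
        )
        f0 = fit_penalized(cohort, small, 0.0)
        fu = fit_cox(cohort, small.design_matrix(cohort.exposure))
        np.testing.assert_allclose(f0.coef_, fu.coef_, atol=1e-8)
        assert f0.df_ == small.n_functions
        np.testing.assert_allclose(
            f0.covariance_model_, f0.covariance_sandwich_, atol=1e-8
        )

    def test_df_limits(self, cohort, basis):
        """df = J at theta 0 and approaches 1 (a linear log HR) as theta
        grows without bound."""
        scale = theta_scale(cohort, basis)
        assert fit_penalized(cohort, basis, 0.0).df_ == pytest.approx(17, abs=1e-8)
        assert fit_penalized(cohort, basis, 1e8 * scale).df_ == pytest.approx(
            1.0, abs=0.05
        )

    def test_df_monotone_decreasing_in_theta(self, cohort, basis):
        scale = theta_scale(cohort, basis)
        thetas = scale * np.logspace(-4, 6, 20)
        dfs = [fit_penalized(cohort, basis, t).df_ for t in thetas]
        assert np.all(np.diff(dfs) < 0)
        assert all(1.0 <= d <= basis.n_functions + 1e-9 for d in dfs)

    def test_penalty_value_nonincreasing_in_theta(self, cohort, basis):
        from coxspline.basis import curvature_penalty

        pen = curvature_penalty(basis)
        scale = theta_scale(cohort, basis)
        vals = []
        for t in scale * np.logspace(-2, 4, 8):
            f = fit_penalized(cohort, basis, t)
            vals.append(pen.quadratic_form(f.coef_[: basis.n_functions]))
        assert np.all(np.diff(vals) <= 1e-10)

    def test_solve_theta_for_df(self, cohort, basis):
        theta, fit = solve_theta_for_df(cohort, basis, 2.0)
        assert abs(fit.df_ - 2.0) < 1e-3
        assert theta > 0

    @pytest.mark.parametrize("bad_target", [0.5, 1.0, 17.0, 25.0])
    def test_invalid_df_target(self, cohort, basis, bad_target):
        with pytest.raises(InvalidTargetError):
            solve_theta_for_df(cohort, basis, bad_target)


class TestSelectTheta:
    def test_quadratic_truth_detects_nonlinearity(self, cohort5000):
        """Under the strongly quadratic generating curve AICc keeps more
        than one effective parameter."""
        basis = make_bspline_basis(
            3, 15, (cohort5000.exposure.min(), cohort5000.exposure.max())
        )
        fit = select_theta(cohort5000, basis, criterion="aicc")
        assert fit.df_ > 1.5
        assert fit.criterion_ == "aicc"
        assert np.isfinite(fit.criterion_value_)

    def test_linear_truth_selects_near_linear(self):
        dfs = []
        for s in range(20):
            cfg = replace(
                SimulationConfig(n=800, seed=100 + s),
                curve=linear_true_curve(0.08),
            )
            d = simulate_cohort(cfg)
            basis = make_bspline_basis(3, 15, (d.exposure.min(), d.exposure.max()))
            dfs.append(select_theta(d, basis, criterion="aicc").df_)
        assert np.median(dfs) < 1.5

    def test_aicc_approaches_aic_with_many_events(self, cohort5000):
        basis = make_bspline_basis(
            3, 15, (cohort5000.exposure.min(), cohort5000.exposure.max())
        )
        fit = fit_penalized(cohort5000, basis, 100.0)
        # correction term 2 df (df+1) / (m - df - 1) with m ~ 800 events
        assert aicc(fit) - aic(fit) == pytest.approx(
            2 * fit.df_ * (fit.df_ + 1) / (fit.n_events_ - fit.df_ - 1)
        )
        assert aicc(fit) - aic(fit) < 0.2


class TestBreslowBaseline:
    def test_null_model_nelson_aalen(self, tiny_all_events):
        """b = 0 with events at 1, 2, 3: increments 1/3, 1/2, 1."""
        times, ch, fn = breslow_baseline(tiny_all_events)
        np.testing.assert_allclose(times, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(ch, [1 / 3, 5 / 6, 11 / 6])
        assert fn(0.5) == 0.0
        assert fn(2.5) == pytest.approx(5 / 6)

    def test_nondecreasing_and_zero_before_first_event(self, cohort1000):
        fit = fit_cox(cohort1000, cohort1000.exposure[:, None])
        times, ch, fn = breslow_baseline(
            cohort1000, cohort1000.exposure[:, None], fit.coef_
        )
        assert np.all(np.diff(ch) >= 0)
        assert fn(times.min() - 1e-9) == 0.0
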