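from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from coxspline import (
    SimulationConfig,
    SurvivalData,
    deviance_residuals,
    exposure_groups,
    fit_cox,
    kaplan_meier,
    linear_true_curve,
    loess_smooth,
    martingale_residuals,
    simulate_cohort,
    true_quadratic_curve,
)
from coxspline.diagnostics import functional_form_plot, functional_form_table, km_plot


class TestKaplanMeier:
    def test_no_censoring_product_limit(self):
        """Four events at 1..4: S-hat(2) = (3/4)(2/3) = 1/2."""
        d = SurvivalData(time=[1, 2, 3, 4], event=[1, 1, 1, 1], exposure=[0] * 4)
        curve = kaplan_meier(d)[0]
        assert curve.at(2.0) == pytest.approx(0.5)
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])

    def test_fully_censored_group_stays_at_one(self):
        d = SurvivalData(
            time=[1, 2, 3, 4], event=[1, 1, 0, 0], exposure=[0, 0, 5, 5]
        )
        groups = np.array(["a", "a", "b", "b"])
        curves = {c.label: c for c in kaplan_meier(d, groups)}
        assert curves["b"].at(10.0) == 1.0
        assert curves["b"].times.size == 0

    def test_reduces_to_empirical_survival_without_censoring(self, rng):
        t = rng.uniform(1, 10, 50)
        d = SurvivalData(time=t, event=np.ones(50, int), exposure=np.zeros(50))
        curve = kaplan_meier(d)[0]
        grid = np.linspace(0.5, 10.5, 21)
        np.testing.assert_allclose(
            curve.at(grid), [np.mean(t > g) for g in grid], atol=1e-12
        )

    def test_matches_reference_implementation(self, cohort1000):
        lifelines = pytest.importorskip("lifelines")
        kmf = lifelines.KaplanMeierFitter().fit(cohort1000.time, cohort1000.event)
        curve = kaplan_meier(cohort1000)[0]
        np.testing.assert_allclose(
            curve.at(curve.times), kmf.predict(curve.times).values, atol=1e-10
        )

    def test_default_exposure_grouping(self, cohort5000):
        groups = exposure_groups(cohort5000)
        labels = set(groups)
        assert labels == {"unexposed", "(0,5]", "(5,10]", "(10,15]", ">15"}
        assert len(kaplan_meier(cohort5000, groups)) == 5

    def test_unexposed_group_has_best_survival(self, cohort5000):
        """Risk rises with exposure, so the unexposed stratum keeps the
        highest Kaplan-Meier curve at mid follow-up."""
        curves = {c.label: c for c in kaplan_meier(cohort5000, exposure_groups(cohort5000))}
        s_unexposed = curves["unexposed"].at(15.0)
        for label in ["(0,5]", "(5,10]", "(10,15]"]:
            assert s_unexposed > curves[label].at(15.0)


class TestMartingaleResiduals:
    def test_null_model_nelson_aalen_enumeration(self, tiny_all_events):
        r = martingale_residuals(tiny_all_events)
        np.testing.assert_allclose(r, [2 / 3, 1 / 6, -5 / 6])

    def test_sum_zero_and_bounded_above(self, cohort1000):
        fit = fit_cox(cohort1000, cohort1000.exposure[:, None])
        r = martingale_residuals(cohort1000, fit, cohort1000.exposure[:, None])
        assert abs(r.sum()) < 1e-8
        assert np.all(r <= 1.0)

    def test_matches_reference_at_equal_coefficients(self, cohort1000):
        """With the coefficient fixed, the baseline-hazard and residual
        pipeline agrees with lifelines to near machine precision."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        from coxspline import breslow_baseline

        dd = pd.DataFrame(
            {"x": cohort1000.exposure, "T": cohort1000.time, "E": cohort1000.event}
        )
        cph = lifelines.CoxPHFitter().fit(dd, "T", "E")
        res_ll = cph.compute_residuals(dd, "martingale")["martingale"].sort_index()
        coef = cph.params_.values
        _, _, lam = breslow_baseline(cohort1000, cohort1000.exposure[:, None], coef)
        r = cohort1000.event - lam(cohort1000.time) * np.exp(
            cohort1000.exposure * coef[0]
        )
        np.testing.assert_allclose(r, res_ll.values, atol=1e-10)
        # and our own MLE agrees with theirs closely enough for diagnostics
        fit = fit_cox(cohort1000, cohort1000.exposure[:, None])
        assert abs(fit.coef_[0] - coef[0]) < 1e-4

    def test_deviance_transform(self, cohort1000):
        fit = fit_cox(cohort1000, cohort1000.exposure[:, None])
        r = martingale_residuals(cohort1000, fit, cohort1000.exposure[:, None])
        d = deviance_residuals(r, cohort1000.event)
        assert np.all(np.isfinite(d))
        assert np.all(np.sign(d[r != 0]) == np.sign(r[r != 0]))
        # the transform is monotone in r within each event status
        for status in (0, 1):
            m = cohort1000.event == status
            order = np.argsort(r[m])
            assert np.all(np.diff(d[m][order]) >= 0)


class TestLoess:
    def test_constant_reproduced_exactly(self, rng):
        x = np.sort(rng.uniform(0, 1, 60))
        for span in (0.3, 0.8, 1.5):
            np.testing.assert_allclose(
                loess_smooth(x, np.full(60, 3.2), span=span), 3.2
            )

    @pytest.mark.parametrize("degree", [1, 2])
    def test_linear_data_reproduced_exactly(self, rng, degree):
        x = np.sort(rng.uniform(0, 1, 80))
        y = 2.0 * x - 1.0
        np.testing.assert_allclose(
            loess_smooth(x, y, span=0.5, degree=degree), y, atol=1e-10
        )

    def test_smoothing_reduces_noise_rmse(self, rng):
        x = np.sort(rng.uniform(0, 1, 200))
        truth = 4.0 * (x - 0.5) ** 2
        y = truth + rng.normal(0, 0.2, 200)
        fitted = loess_smooth(x, y, span=0.6, degree=2)
        assert np.sqrt(np.mean((fitted - truth) ** 2)) < np.sqrt(
            np.mean((y - truth) ** 2)
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            loess_smooth([1.0, 2.0], [1.0, 2.0], span=-1)
        with pytest.raises(ValueError):
            loess_smooth([1.0, 2.0], [1.0, 2.0], span=0.5, degree=3)


@pytest.fixture(scope="module")
def quad_cohort():
    return simulate_cohort(SimulationConfig(n=3000, seed=5))


class TestFunctionalForm:
    def test_one_smooth_column_per_span(self, quad_cohort):
        spans = (0.4, 0.8, 1.2, 1.6, 2.0)
        table = functional_form_table(quad_cohort, spans=spans)
        assert [c for c in table.columns if c.startswith("loess_")] == [
            f"loess_{s:g}" for s in spans
        ]

    def test_quadratic_truth_shows_slope_attenuation(self, quad_cohort):
        """Under the concave generating curve the smoothed residual trend
        rises but its slope attenuates in the upper exposure half."""
        table = functional_form_table(quad_cohort, spans=(0.6,)).sort_values("exposure")
        x, y = table["exposure"].to_numpy(), table["loess_0.6"].to_numpy()
        assert stats.spearmanr(x, y).statistic > 0.85
        med = np.median(x)
        inner = x <= np.quantile(x, 0.98)
        s_lo = np.polyfit(x[x <= med], y[x <= med], 1)[0]
        s_hi = np.polyfit(x[(x > med) & inner], y[(x > med) & inner], 1)[0]
        assert s_hi < 0.9 * s_lo

    def test_linear_truth_monotone_without_attenuation(self):
        cfg = replace(SimulationConfig(n=3000, seed=6), curve=linear_true_curve(0.08))
        d = simulate_cohort(cfg)
        table = functional_form_table(d, spans=(0.6,)).sort_values("exposure")
        x, y = table["exposure"].to_numpy(), table["loess_0.6"].to_numpy()
        assert stats.spearmanr(x, y).statistic > 0.85
        med = np.median(x)
        inner = x <= np.quantile(x, 0.98)
        s_lo = np.polyfit(x[x <= med], y[x <= med], 1)[0]
        s_hi = np.polyfit(x[(x > med) & inner], y[(x > med) & inner], 1)[0]
        assert s_hi > 0.9 * s_lo

    def test_plot_emits_one_curve_per_span(self, tmp_path):
        d = simulate_cohort(SimulationConfig(n=300, seed=9))
        spans = (0.5, 1.0, 2.0)
        fig, table = functional_form_plot(
            d, spans=spans, path=tmp_path / "resid.png"
        )
        # one line per span plus the rug line
        assert len(fig.axes[0].lines) == len(spans) + 1
        assert (tmp_path / "resid.png").exists()

    def test_km_plot_smoke(self, tmp_path, cohort1000):
        curves = kaplan_meier(cohort1000, exposure_groups(cohort1000))
        fig = km_plot(curves, path=tmp_path / "km.png")
        assert (tmp_path / "km.png").exists()
        assert len(fig.axes[0].lines) == len(curves)
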