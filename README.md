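# coxspline

Nonlinear exposure-response curves for Cox proportional hazards models.

Occupational and environmental cohort studies often find that the hazard of
a health outcome rises with a quantitative exposure but attenuates — or even
falls — at the highest exposures. Forcing the log hazard ratio to be linear
in the exposure hides this. `coxspline` estimates the exposure-response
curve `s(x)` in

    lambda(t | x) = lambda_0(t) * exp(s(x))

flexibly, as a spline basis expansion `s(x) = sum_j b_j f_j(x)`, fitted by
(penalized) maximum partial likelihood, and turns the fitted curve into the
quantities an epidemiologist actually reports: hazard ratios
`HR(x) = exp(s-hat(x) - s-hat(x_ref))` at exposures of interest against a
chosen reference (by default the unexposed, `x_ref = 0`) with pointwise
Wald confidence intervals — not the mean-centered predictions some software
emits by default, which have no interpretation for basis expansions.

It is written for biostatisticians and epidemiologists analysing
right-censored cohort data with a quantitative exposure.

## What's inside

- **Bases** (`coxspline.basis`): truncated power bases
  `{x, ..., x^p, (x-k_1)_+^p, ...}` with knots at the case-exposure
  quartiles by default, and numerically stable B-spline bases (de Boor
  recursion) with the constant direction dropped (it is absorbed by the
  baseline hazard); curvature penalty matrices
  `Omega_jl = ∫ f_j''(x) f_l''(x) dx`.
- **Fitting** (`coxspline.coxfit`): Newton-Raphson maximum partial
  likelihood (Efron or Breslow ties), penalized fits maximizing
  `l(b) - theta * b' Omega b`, effective degrees of freedom
  `df = tr[(H + 2 theta Omega)^{-1} H]` running from J (no penalty) down
  to 1 (linear), smoothing selection by AIC/AICc or by a target df, and
  the Breslow baseline hazard.
- **Effects** (`coxspline.effects`): hazard-ratio curves, report tables,
  and p-value functions anchored at any reference exposure.
- **Inference** (`coxspline.inference`): Wald chi-square tests of
  `H0: s(x) = b x` against the spline alternative, for both unpenalized
  truncated-power fits and penalized fits (linear/nonlinear decomposition),
  plus AIC comparison across candidate forms (linear, logarithmic, linear
  spline, pspline).
- **Diagnostics** (`coxspline.diagnostics`): Kaplan-Meier curves by
  exposure group, martingale residuals with loess smooths for
  functional-form assessment, deviance residuals.
- **Simulator** (`coxspline.simulate`): cohorts with a known quadratic
  log-HR truth (maximum at x = 15, HR 2 at x = 4), zero-inflated gamma
  exposures, Weibull baseline and administrative censoring, calibrated so
  that ~13% of subjects are unexposed and ~16% become cases.
- A command-line interface: `coxspline simulate | fit | curve | test |
  diagnose | compare`.

## Worked example

```python
import numpy as np
from coxspline import (SimulationConfig, simulate_cohort, SplineCoxPH,
                       hr_table, format_hr_table, true_quadratic_curve)

data = simulate_cohort(SimulationConfig(n=5000, seed=42))
print(f"cohort: n={data.n}, events={data.n_events} "
      f"({100*data.n_events/data.n:.1f}%), "
      f"unexposed={100*np.mean(data.exposure==0):.1f}%")

spline = SplineCoxPH(basis="truncated_power", degree=1).fit(data)
print("knots (case-exposure quartiles):", np.round(spline.basis_.knots, 2))

pspline = SplineCoxPH(basis="bspline", degree=3, criterion="aicc").fit(data)
print(f"pspline: AICc-selected df = {pspline.df_:.2f}")

table = hr_table([pspline, spline], [2.0, 4.0, 7.0, 9.0],
                 model_names=["pspline (AICc)", "linear spline"])
print(format_hr_table(table))
print(pspline.nonlinearity_test())
```

prints

```
cohort: n=5000, events=850 (17.0%), unexposed=12.1%
knots (case-exposure quartiles): [3.56 5.72 8.32]
pspline: AICc-selected df = 4.92
model      linear spline  pspline (AICc)
exposure
2.0       1.3 (1.1, 1.5)  1.2 (1.0, 1.5)
4.0       1.7 (1.2, 2.2)  1.7 (1.3, 2.2)
7.0       2.8 (2.2, 3.5)  2.6 (2.1, 3.4)
9.0       3.2 (2.5, 4.2)  3.1 (2.4, 4.0)
nonlinearity test: chi2 = 21.399 on 3.92 df, p = 0.0002438
```

Read the table as: a subject at exposure 4 has an estimated hazard 1.7
times that of an unexposed subject (true generating HR: 2.0); at exposure
9 the estimate is ~3.1-3.2 (truth 3.5). The chi-square test firmly rejects
a linear log hazard ratio, as it should under the quadratic truth.

The same workflow from the shell:

```sh
coxspline simulate --n 5000 --seed 42 --out cohort.csv
coxspline fit --input cohort.csv --model tpb:1 --model pspline:aicc \
    --exposures 2,4,7,9 --out-dir results/
coxspline diagnose --input cohort.csv --out-dir results/
```

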