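# allosurv

Parametric survival modelling of **age-specific mortality trajectories
and the rate of aging** in first-allogeneic hematopoietic stem-cell
transplant (HSCT) cohorts — for biostatisticians and demographers who
need the *shape* of the hazard (not just hazard ratios) under left
truncation at transplant age, arbitrary administrative right-censoring,
and calendar-period effects.

## The model

Each patient contributes exit age *x*, transplant (recruitment) age *j*
and death indicator *θ*.  A binary stratum matrix **δ** — post-transplant
time-lapse interval (*t* ≤ 100 d, 100 d < *t* ≤ 365 d, *t* > 365 d) ×
donor source (related / unrelated) — keeps every patient in one
likelihood while giving each stratum its own baseline hazard.  With
proportional covariates *βZ*, the log-likelihood is

```
log L(ω; x, j) = Σᵢ Σₛ δᵢₛ [ θᵢ (log hₛ(xᵢ) + βZᵢ) + e^{βZᵢ} (log Sₛ(xᵢ) − log Sₛ(jᵢ)) ]
```

i.e. the left-truncated, right-censored parametric likelihood; an
all-ones δ collapses it to the conventional pooled form.  Baseline
families: Gompertz μ(x) = a·e^{bx}, Weibull μ(x) = λk·x^{k−1}, each
optionally with a Makeham background c and with gamma /
inverse-Gaussian / log-normal frailty (mean 1, variance σ²) marginalized
through its Laplace transform.  The **rate of aging** is
d(log μ(x))/dx — *b* for Gompertz, (k−1)/x for Weibull, so k < 1 is a
decelerating ("inverse-J") hazard and k = 1 negligible senescence.

Around that core the package provides multi-start MLE (simulated
annealing + quasi-Newton polish; delta-method SEs and asymmetric 95% CIs
from the internal-scale Hessian), AIC family ranking and LRT-based
forward covariate selection, frailty-degeneracy diagnostics (profile
boundary test), biennial event-history (EHA) episode splitting for
*t* > 365-day survivors over calendar 1995–2012, per-stratum trajectory
tables with hazard-crossing detection, and a synthetic cohort generator
that emulates the registry data structure this methodology targets
(which is not publicly deposited).

## Worked example

`examples/fit_mortality_trajectories.py` generates a 5,000-patient
cohort whose donor-specific Weibull shapes follow the early-interval
pattern (k = 1.0037 related — flat; k = 0.96 unrelated — decelerating)
plus an acute-GvHD effect (log-HR 0.5), fits the donor-stratified model
and prints:

```
converged: True   log-likelihood: -11514.2

   related: k = 1.274 (95% CI 1.009-1.608), rate of aging at 50 = +0.00547/yr
 unrelated: k = 1.057 (95% CI 0.882-1.266), rate of aging at 50 = +0.00113/yr

beta(acute GvHD) = 0.489 (hazard ratio 1.63)
hazard-line crossings on the 30-70y grid: (67.05542278891181,)
```

The shape estimates carry their delta-method CIs; the rate-of-aging
column is (k̂−1)/x; β is recovered near its generating value 0.5; and
`crossing_age` reports where the two fitted hazard lines intersect on
the semi-log trajectory plot.

The other examples, one capability each:

| script | shows |
|---|---|
| `examples/simulate_and_describe.py` | cohort generation, eligibility filtering, descriptive table |
| `examples/model_selection.py` | AIC family ranking + LRT forward selection |
| `examples/frailty_diagnostics.py` | unmeasurable frailty under heavy censoring vs σ² recovery |
| `examples/eha_calendar_adjustment.py` | biennial period-effect recovery and the no-EHA shape bias |

A thin CLI wraps the same stages
(`allosurv simulate|filter|fit|select|eha|trajectory|pipeline`, YAML
config, seeded, provenance-stamped outputs); `allosurv pipeline --config
cfg.yaml --seed 7` writes a run directory with cohort, exclusion report,
selection table, EHA fit, trajectory CSV/plot and a manifest.

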