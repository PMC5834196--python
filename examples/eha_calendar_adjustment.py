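"""Why long-term survivor analyses need calendar-period adjustment.

The cohort's hazard declines 10% per biennium (medical improvement).
The biennial event-history fit recovers that trend and the baseline
shape; the unadjusted fit — even with transplant year as a standalone
covariate — absorbs the within-follow-up decline into a distorted shape
estimate.
"""
from allosurv import (
    AnnealConfig,
    GeneratorConfig,
    ModelSpec,
    StartGrid,
    fit,
    fit_eha,
    generate_cohort,
)
from allosurv.eha import i3_entry_cohort

cohort, truth = generate_cohort(
    GeneratorConfig(n_patients=8000, seed=5, period_trend=-0.105)
)
k_true = truth["stratum_params"]["I3:related"]["k"]
base = ModelSpec(family="weibull", stratification="none")
grid = StartGrid(n_starts=2, seed=0)
fast = AnnealConfig(n_iter=0)

eha_fit, effects = fit_eha(cohort, base, grid, period_coding="linear", anneal=fast)
print(f"generator: k = {k_true}, period trend = -0.105 per biennium")
print(f"EHA fit:    k = {eha_fit.params_hat['k']:.3f} "
      f"(se {eha_fit.se['k']:.3f}), trend = {effects.coefficients['slope']:+.4f} "
      f"(se {eha_fit.se['beta_period_index']:.4f})")

plain = fit(i3_entry_cohort(cohort), base, grid, anneal=fast)
year_spec = ModelSpec(family="weibull", stratification="none",
                      covariate_names=("transplant_year",))
with_year = fit(i3_entry_cohort(cohort), year_spec, grid, anneal=fast)
print(f"no EHA:     k = {plain.params_hat['k']:.3f} (se {plain.se['k']:.3f})")
print(f"year covar: k = {with_year.params_hat['k']:.3f} "
      f"(se {with_year.se['k']:.3f}), "
      f"beta_year = {with_year.params_hat['beta_transplant_year']:+.4f}")
print(
    "\nThe episode-split (EHA) fit separates age from calendar time, so its"
    "\nshape estimate brackets the generating k; the unadjusted fits push k"
    "\ndownward because the calendar decline masquerades as hazard"
    "\ndeceleration — transplant year as a lone covariate does not fix it."
)
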