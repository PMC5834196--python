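"""Fit donor-stratified Weibull hazards and read off the rate of aging.

Generates a cohort whose donor-specific shapes follow the early-interval
pattern (flat for related grafts, decelerating for unrelated), fits the
stratified truncated likelihood, and prints per-stratum shape estimates
with 95% CIs, the rate of aging at age 50, and the age-specific hazard
trajectory table used for semi-log plots.
"""
from allosurv import (
    GeneratorConfig,
    ModelSpec,
    StartGrid,
    crossing_age,
    fit,
    generate_cohort,
    trajectory,
)

cfg = GeneratorConfig.donor_stratified(
    related={"lam": 0.10, "k": 1.0037},
    unrelated={"lam": 0.13, "k": 0.96},
    n_patients=5000,
    beta_true={"acute_gvhd": 0.5},
    seed=3,
)
cohort, truth = generate_cohort(cfg)

spec = ModelSpec(family="weibull", stratification="donor",
                 covariate_names=("acute_gvhd",))
result = fit(cohort, spec, StartGrid(n_starts=8, seed=0))
print(f"converged: {result.converged}   log-likelihood: {result.loglik:.1f}\n")

for stratum in ("related", "unrelated"):
    k = result.params_hat[f"k[{stratum}]"]
    lo, hi = result.ci95[f"k[{stratum}]"]
    tt = trajectory(result, stratum)
    roa50 = tt.table.loc[tt.table["age"] == 50.0, "rate_of_aging"].iloc[0]
    print(f"{stratum:>10}: k = {k:.3f} (95% CI {lo:.3f}-{hi:.3f}), "
          f"rate of aging at 50 = {roa50:+.5f}/yr")

print(f"\nbeta(acute GvHD) = {result.params_hat['beta_acute_gvhd']:.3f} "
      f"(hazard ratio {2.718281828**result.params_hat['beta_acute_gvhd']:.2f})")

cross = crossing_age(trajectory(result, "related"), trajectory(result, "unrelated"))
print(f"hazard-line crossings on the 30-70y grid: {cross if cross else 'none'}")
print(
    "\nk < 1 is a decelerating (inverse-J) hazard — the rate of aging is"
    "\nnegative; k ~ 1 is negligible senescence (flat hazard).  A crossing"
    "\nof two hazard lines would mark where the donor-source curves converge."
)
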