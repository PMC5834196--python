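"""Frailty under administrative censoring: unmeasurable vs recoverable.

Two contrasting cohorts, both fitted with a gamma-frailty Weibull:
(1) frailty-free truth cut off after ~2 years of follow-up — the frailty
variance is not identifiable and the fit is boundary-flagged; (2) real
heterogeneity (sigma2 = 1) with complete follow-up — the variance is
recovered with a tight profile-likelihood signature.
"""
from allosurv import (
    AnnealConfig,
    FrailtySpec,
    GeneratorConfig,
    ModelSpec,
    StartGrid,
    detect_frailty_degeneracy,
    fit,
    generate_cohort,
)

spec = ModelSpec(family="weibull", stratification="none",
                 frailty=FrailtySpec("gamma", 0.5))

# (1) no frailty in truth + heavy administrative censoring
cfg = GeneratorConfig.single_stratum(
    0.15, 1.0, n_patients=2000, seed=2,
    transplant_year_range=(2005, 2006), censor_year=2007,
)
cohort, _ = generate_cohort(cfg)
f1 = fit(cohort, spec, StartGrid(n_starts=4, seed=0), anneal=AnnealConfig(n_iter=0))
flag, report = detect_frailty_degeneracy(f1)
print("heavy censoring, sigma2 = 0 truth:")
print(f"  sigma2_hat = {f1.params_hat['sigma2']:.4g}, "
      f"boundary LRT = {report['boundary_lrt']:.2f} "
      f"(crit {report['boundary_lrt_crit']}), flagged = {flag}")

# (2) genuine gamma frailty, complete follow-up
cfg = GeneratorConfig.single_stratum(
    5e-4, 2.0, n_patients=10000, seed=2,
    frailty_true=FrailtySpec("gamma", 1.0),
    transplant_year_range=(1995, 1996), censor_year=2100,
)
cohort, _ = generate_cohort(cfg)
f2 = fit(cohort, spec, StartGrid(n_starts=5, seed=1), anneal=AnnealConfig(n_iter=15))
flag2, report2 = detect_frailty_degeneracy(f2)
lo, hi = f2.ci95["sigma2"]
print("\ncomplete follow-up, sigma2 = 1 truth:")
print(f"  sigma2_hat = {f2.params_hat['sigma2']:.3f} (95% CI {lo:.3f}-{hi:.3f}), "
      f"boundary LRT = {report2['boundary_lrt']:.1f}, flagged = {flag2}")
print(
    "\nA boundary LRT below ~2.7 means the likelihood cannot tell the fitted"
    "\nfrailty from none — the 'no measurable frailty' signature that"
    "\narbitrary right-censoring produces even when the model converges."
)
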