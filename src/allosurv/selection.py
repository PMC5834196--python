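"""Model selection: AIC over hazard families, likelihood-ratio tests and
forward covariate selection.

The family stage ranks converged candidate fits by AIC = 2p - 2 logL;
frailty parameters count toward p, and a frailty fit flagged as
boundary-degenerate is excluded from the ranking (its likelihood is not
trustworthy).  The covariate stage is a greedy forward selection: at
each round every remaining candidate is added to the current model, the
one with the smallest likelihood-ratio p-value joins if p < alpha, and
the loop stops when no candidate qualifies.  Multi-level categorical
covariates enter as blocks with df = levels - 1.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import chi2

from .estimation import AnnealConfig, FitResult, StartGrid, fit
from .likelihood import ModelSpec

DEFAULT_FAMILIES = ("gompertz", "gompertz_makeham", "weibull", "weibull_makeham")


@dataclasses.dataclass
class FamilyCandidate:
    spec: ModelSpec
    fit: FitResult | None
    aic: float
    excluded_reason: str | None = None


@dataclasses.dataclass
class LrtStep:
    covariate: str
    statistic: float
    df: int
    p_value: float
    accepted: bool
    reason: str | None = None


@dataclasses.dataclass
class SelectionReport:
    """Family ranking, forward-selection trail and the chosen model."""

    candidates: list[FamilyCandidate]
    chosen: ModelSpec
    chosen_fit: FitResult | None
    lrt_trail: list[LrtStep]
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "chosen": self.chosen.to_config(),
            "candidates": [
                {
                    "family": c.spec.family,
                    "frailty": c.spec.frailty.distribution,
                    "loglik": None if c.fit is None else c.fit.loglik,
                    "n_params": None if c.fit is None else c.fit.n_params,
                    "aic": None if not np.isfinite(c.aic) else c.aic,
                    "excluded_reason": c.excluded_reason,
                }
                for c in self.candidates
            ],
            "lrt_trail": [dataclasses.asdict(s) for s in self.lrt_trail],
        }

    def render_table(self) -> str:
        """Text table of the family stage (family, loglik, p, AIC, rank)."""
        rows = sorted(
            [c for c in self.candidates if np.isfinite(c.aic)], key=lambda c: c.aic
        )
        lines = [f"{'rank':>4}  {'family':<20} {'frailty':<16} {'loglik':>12} {'p':>4} {'AIC':>12}"]
        for r, c in enumerate(rows, 1):
            lines.append(
                f"{r:>4}  {c.spec.family:<20} {c.spec.frailty.distribution:<16} "
                f"{c.fit.loglik:>12.3f} {c.fit.n_params:>4d} {c.aic:>12.3f}"
            )
        for c in self.candidates:
            if not np.isfinite(c.aic):
                lines.append(
                    f"   -  {c.spec.family:<20} {c.spec.frailty.distribution:<16} "
                    f"excluded: {c.excluded_reason}"
                )
        return "\n".join(lines)


def aic(fit_result: FitResult) -> float:
    """Akaike information criterion 2p - 2 logL of a converged fit."""
    if not fit_result.converged:
        raise ValueError("AIC undefined for a non-converged fit")
    return 2.0 * fit_result.n_params - 2.0 * fit_result.loglik


def likelihood_ratio_test(nested: FitResult, full: FitResult):
    """LRT of a nested against a full fit on the same cohort.

    Returns ``(statistic, df, p)`` with the statistic 2(logL_full -
    logL_nested) clamped at zero for tiny negatives; a negative beyond
    -1e-6 signals an optimization failure and raises.
    """
    statistic = 2.0 * (full.loglik - nested.loglik)
    if statistic < -1e-6:
        raise ValueError(
            f"full model log-likelihood below nested ({statistic:.3g}); "
            "optimization failure"
        )
    statistic = max(statistic, 0.0)
    df = full.n_params - nested.n_params
    if df <= 0:
        raise ValueError("full model must have more free parameters than nested")
    p = float(chi2.sf(statistic, df))
    return statistic, df, p


def rank_families(
    cohort,
    *,
    base_spec: ModelSpec | None = None,
    families=DEFAULT_FAMILIES,
    frailty_options=("none",),
    start_grid: StartGrid | None = None,
    anneal: AnnealConfig | None = None,
) -> list[FamilyCandidate]:
    """Fit each family (x frailty option) and rank by AIC.

    Non-converged fits and boundary-flagged frailty fits are kept in the
    list with an exclusion reason and AIC = inf so they never rank.
    """
    from .hazards import FrailtySpec

    base = base_spec or ModelSpec()
    out: list[FamilyCandidate] = []
    for fam in families:
        for fr in frailty_options:
            spec = dataclasses.replace(
                base, family=fam, frailty=FrailtySpec(fr, 0.1 if fr != "none" else 0.0)
            )
            try:
                f = fit(cohort, spec, start_grid, anneal=anneal)
            except Exception as exc:  # pragma: no cover - defensive
                out.append(FamilyCandidate(spec, None, np.inf, f"fit error: {exc}"))
                continue
            if not f.converged:
                out.append(FamilyCandidate(spec, f, np.inf, "non-converged"))
            elif spec.frailty.active and f.frailty_boundary_flag:
                out.append(FamilyCandidate(spec, f, np.inf, "frailty boundary-degenerate"))
            else:
                out.append(FamilyCandidate(spec, f, aic(f)))
    out.sort(key=lambda c: (c.aic, c.spec.family))
    return out


def forward_select(
    cohort,
    base_spec: ModelSpec,
    candidate_covariates,
    alpha: float = 0.05,
    *,
    start_grid: StartGrid | None = None,
    anneal: AnnealConfig | None = None,
    family_candidates: list[FamilyCandidate] | None = None,
) -> SelectionReport:
    """Greedy forward selection of covariates by likelihood-ratio test.

    At each round the candidate with the smallest LRT p-value joins the
    model if p < alpha (ties: larger statistic, then lexicographic name);
    non-converging candidate fits are skipped with a logged reason.
    Deterministic given the start-grid seed.
    """
    remaining = sorted(set(candidate_covariates))
    current_spec = base_spec
    current_fit = fit(cohort, current_spec, start_grid, anneal=anneal)
    trail: list[LrtStep] = []
    while remaining and alpha > 0:
        round_results = []
        for cov in remaining:
            spec_c = dataclasses.replace(
                current_spec,
                covariate_names=tuple(current_spec.covariate_names) + (cov,),
            )
            try:
                fit_c = fit(cohort, spec_c, start_grid, anneal=anneal)
                if not fit_c.converged:
                    trail.append(LrtStep(cov, np.nan, 0, np.nan, False, "non-converged"))
                    continue
                stat, df, p = likelihood_ratio_test(current_fit, fit_c)
            except ValueError as exc:
                trail.append(LrtStep(cov, np.nan, 0, np.nan, False, str(exc)))
                continue
            round_results.append((p, -stat, cov, stat, df, fit_c, spec_c))
        if not round_results:
            break
        round_results.sort(key=lambda t: (t[0], t[1], t[2]))
        p, _, cov, stat, df, fit_c, spec_c = round_results[0]
        if p < alpha:
            trail.append(LrtStep(cov, stat, df, p, True))
            current_spec, current_fit = spec_c, fit_c
            remaining.remove(cov)
        else:
            trail.append(LrtStep(cov, stat, df, p, False))
            break
    return SelectionReport(
        candidates=family_candidates or [],
        chosen=current_spec,
        chosen_fit=current_fit,
        lrt_trail=trail,
        alpha=alpha,
    )
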