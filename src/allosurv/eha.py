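"""Biennial event-history analysis for long-term (t > 365-day) survivors.

Each long-term survivor's follow-up from one year post-transplant to exit
is split into episodes at biennial calendar boundaries (1995-96, 1997-98,
..., 2011-12; right-closed).  Each episode is a left-truncated,
right-censored observation in its own right — entry and exit ages, a
death indicator carried only by the terminal episode of a death — so the
episode table feeds the same likelihood machinery, with a calendar-period
covariate scaling the hazard by exp(gamma_period).  With all period
coefficients fixed at zero the episode-split likelihood telescopes back
to the unsplit fit on the one-year-survivor cohort: the fundamental
bookkeeping check of the truncation machinery.

Calendar position of age ``x`` for a patient transplanted at age ``j`` in
year ``Y`` is ``Y + 0.5 + (x - j)`` (mid-year transplant convention; exact
transplant dates are not part of the schema).
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .data_model import (
    COVARIATE_NAMES,
    DAYS_PER_YEAR,
    CohortTable,
    PatientRecord,
    record_from_row,
)
from .estimation import AnnealConfig, FitResult, StartGrid, fit
from .likelihood import ModelSpec

#: post-transplant duration (years) at which the long-term interval begins
I3_ENTRY_YEARS = 365.0 / DAYS_PER_YEAR

DEFAULT_CALENDAR_START = 1995
DEFAULT_CALENDAR_END = 2012


@dataclasses.dataclass
class Episode:
    """One biennial slice of a long-term survivor's follow-up."""

    patient_id: str
    period_label: str
    period_index: int
    entry_age: float
    exit_age: float
    event_theta_episode: int
    donor_source: str
    transplant_year: int
    covariates: dict


@dataclasses.dataclass
class PeriodEffects:
    """Per-bin log-hazard coefficients, reference bin fixed at 0."""

    labels: tuple[str, ...]
    coefficients: dict[str, float]
    reference: str | None  # None for the linear (single-slope) coding

    def __post_init__(self):
        if self.reference is not None and self.coefficients.get(self.reference, 0.0) != 0.0:
            raise ValueError("reference period coefficient must be 0")


def _bin_label(lo: float) -> str:
    return f"{int(lo)}-{str(int(lo) + 1)[2:]}"


def period_labels(calendar_start=DEFAULT_CALENDAR_START, calendar_end=DEFAULT_CALENDAR_END):
    return tuple(_bin_label(b) for b in np.arange(calendar_start, calendar_end + 1, 2))


def split_biennial(
    record: PatientRecord,
    calendar_start: int = DEFAULT_CALENDAR_START,
    calendar_end: int = DEFAULT_CALENDAR_END,
) -> list[Episode]:
    """Split one long-term survivor into biennial calendar episodes.

    Episodes partition ages [j + 365 days, x] at the biennial boundaries;
    bins are right-closed so an exit exactly on a boundary stays in the
    earlier bin.  Follow-up outside the calendar window is clipped with a
    warning (a death clipped away becomes censoring at the window edge).
    Total episode exposure equals the patient's long-term exposure and the
    episode death indicators sum to the patient's.
    """
    if record.post_transplant_days <= 365.0:
        raise ValueError(
            f"record {record.id} is not a t>365-day survivor; cannot split"
        )
    j, x = record.transplant_age_j, record.exit_age_x
    cal0 = record.transplant_year + 0.5
    entry_age = j + I3_ENTRY_YEARS
    cal_entry = cal0 + (entry_age - j)
    cal_exit = cal0 + (x - j)
    theta = record.event_theta
    win_lo, win_hi = float(calendar_start), float(calendar_end) + 1.0
    if cal_entry < win_lo:
        warnings.warn(
            f"record {record.id}: follow-up starts before {calendar_start}; clipped"
        )
        cal_entry = win_lo
    if cal_exit > win_hi + 1e-9:
        warnings.warn(
            f"record {record.id}: follow-up extends past {calendar_end}; clipped "
            "(event beyond the window becomes censoring)"
        )
        cal_exit = win_hi
        theta = 0
    elif cal_exit > win_hi:  # float round-trip noise at the boundary
        cal_exit = win_hi
    if cal_exit <= cal_entry:
        return []
    boundaries = np.arange(win_lo, win_hi + 1.0, 2.0)
    covs = dict(record.covariates)
    episodes: list[Episode] = []
    for m in range(len(boundaries) - 1):
        lo, hi = boundaries[m], boundaries[m + 1]
        seg_lo = max(lo, cal_entry)
        seg_hi = min(hi, cal_exit)
        if seg_hi <= seg_lo:
            continue
        episodes.append(
            Episode(
                patient_id=record.id,
                period_label=_bin_label(lo),
                period_index=m,
                entry_age=j + (seg_lo - cal0),
                exit_age=j + (seg_hi - cal0),
                event_theta_episode=0,
                donor_source=record.donor_source,
                transplant_year=record.transplant_year,
                covariates=covs,
            )
        )
    if episodes and theta == 1:
        episodes[-1].event_theta_episode = 1
    return episodes


def i3_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Rows of a cohort in the long-term (t > 365-day) interval."""
    df = cohort.df
    return df.loc[df["post_transplant_days"] > 365.0].reset_index(drop=True)


def i3_entry_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Long-term survivors with entry age moved to one year post-transplant.

    This is the unsplit comparator of the episode likelihood: splitting
    telescopes to a likelihood truncated at j + 365 days, i.e. conditioned
    on one-year survival, not at the transplant age itself.
    """
    df = i3_cohort(cohort).copy()
    df["transplant_age_j"] = df["transplant_age_j"] + I3_ENTRY_YEARS
    return df


def build_episode_table(
    cohort: CohortTable,
    calendar_start: int = DEFAULT_CALENDAR_START,
    calendar_end: int = DEFAULT_CALENDAR_END,
) -> pd.DataFrame:
    """Episode long-format table for the I3 sub-cohort of a cohort.

    Columns mirror the patient schema (episode entry age in
    ``transplant_age_j``, episode exit in ``exit_age_x``) plus ``period``
    and ``period_index``; exportable as CSV.
    """
    rows = []
    for _, r in i3_cohort(cohort).iterrows():
        rec = record_from_row(r)
        for e_i, ep in enumerate(split_biennial(rec, calendar_start, calendar_end)):
            row = {
                "id": f"{ep.patient_id}:e{e_i}",
                "patient_id": ep.patient_id,
                "transplant_age_j": ep.entry_age,
                "exit_age_x": ep.exit_age,
                "event_theta": ep.event_theta_episode,
                "donor_source": ep.donor_source,
                "transplant_year": ep.transplant_year,
                "post_transplant_days": (ep.exit_age - ep.entry_age) * DAYS_PER_YEAR,
                "period": ep.period_label,
                "period_index": ep.period_index,
            }
            for name in COVARIATE_NAMES:
                row[name] = ep.covariates.get(name)
            rows.append(row)
    return pd.DataFrame(rows)


def fit_eha(
    cohort: CohortTable,
    spec: ModelSpec,
    start_grid: StartGrid | None = None,
    *,
    period_coding: str = "factor",
    calendar_start: int = DEFAULT_CALENDAR_START,
    calendar_end: int = DEFAULT_CALENDAR_END,
    anneal: AnnealConfig | None = None,
    include_all_intervals: bool = False,
) -> tuple[FitResult, PeriodEffects | None]:
    """Fit the episode-split likelihood with calendar-period effects.

    ``period_coding``: "factor" estimates one coefficient per biennial bin
    (earliest non-empty bin as reference), "linear" a single per-bin
    slope on the bin index, "none" fixes all period effects at zero (the
    split-invariance check).  EHA applies to the t>365-day sub-cohort;
    ``include_all_intervals`` admits shorter survivors for exploration
    only.  Empty bins are absent from the design by construction.
    """
    if spec.stratification not in ("none", "donor"):
        raise ValueError("EHA episodes live in one interval; stratify by none/donor")
    if period_coding not in ("factor", "linear", "none"):
        raise ValueError(f"unknown period_coding {period_coding!r}")
    base = cohort
    if include_all_intervals:
        df = cohort.df.copy()
        df["post_transplant_days"] = np.maximum(df["post_transplant_days"], 366.0)
        base = CohortTable(df)
    episodes = build_episode_table(base, calendar_start, calendar_end)
    if not len(episodes):
        raise ValueError("no t>365-day episodes to fit")
    extra = {"factor": ("period",), "linear": ("period_index",), "none": ()}[period_coding]
    spec2 = dataclasses.replace(
        spec, covariate_names=tuple(spec.covariate_names) + extra
    )
    result = fit(episodes, spec2, start_grid, anneal=anneal)
    effects = None
    if period_coding == "factor":
        labels = tuple(sorted(episodes["period"].unique()))
        coefs = {labels[0]: 0.0}
        for lb in labels[1:]:
            coefs[lb] = float(result.params_hat.get(f"beta_period[{lb}]", np.nan))
        effects = PeriodEffects(labels, coefs, reference=labels[0])
    elif period_coding == "linear":
        effects = PeriodEffects(
            ("slope",),
            {"slope": float(result.params_hat["beta_period_index"])},
            reference=None,
        )
    return result, effects
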