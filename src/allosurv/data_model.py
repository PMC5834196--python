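"""Patient-level data structures, eligibility filtering and cohort I/O.

A cohort is a flat table of first-allogeneic transplant patients.  Each
record carries the three quantities any left-truncated survival likelihood
needs — age at exit ``x`` (death or censoring), age at recruitment
(transplant) ``j``, and the vital-status indicator ``theta`` — together
with the donor source, the post-transplant survival duration in days, the
transplant calendar year, and a fixed set of clinical/demographic
covariates (GvHD status, disease group, conditioning class, TBI band,
graft type, Karnofsky band, prior autologous transplant, sex, region).

Post-transplant follow-up duration determines the time-lapse interval of a
record: ``I1`` (t <= 100 days), ``I2`` (100 < t <= 365 days) and ``I3``
(t > 365 days), with both cut-offs right-closed.
"""
from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: days per year used to convert between day-scale durations and year-scale ages
DAYS_PER_YEAR = 365.25

#: right-closed post-transplant interval cut-offs, in days
INTERVAL_BOUNDS_DAYS = (100.0, 365.0)

DONOR_SOURCES = ("related", "unrelated")

#: covariate columns every cohort file must carry (categorical or 0/1 coded)
COVARIATE_NAMES = (
    "acute_gvhd",
    "chronic_gvhd",
    "disease",
    "conditioning",
    "tbi_band",
    "graft_type",
    "karnofsky_ge80",
    "prior_auto",
    "sex",
    "region",
)

CORE_COLUMNS = (
    "id",
    "transplant_age_j",
    "exit_age_x",
    "event_theta",
    "donor_source",
    "post_transplant_days",
    "transplant_year",
)

REQUIRED_COLUMNS = CORE_COLUMNS + COVARIATE_NAMES

SCHEMA_VERSION = "1"

_NUMERIC_COLUMNS = {
    "transplant_age_j": float,
    "exit_age_x": float,
    "event_theta": int,
    "post_transplant_days": float,
    "transplant_year": int,
}


class SchemaError(ValueError):
    """Raised when a cohort table violates the documented schema."""


class IntervalCategory(str, enum.Enum):
    """Post-transplant survival time-lapse interval."""

    I1 = "I1"  # t <= 100 days
    I2 = "I2"  # 100 days < t <= 365 days
    I3 = "I3"  # t > 365 days


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """One subject's survival profile."""

    id: str
    transplant_age_j: float
    exit_age_x: float
    event_theta: int
    donor_source: str
    post_transplant_days: float
    transplant_year: int
    covariates: Mapping[str, object] = dataclasses.field(default_factory=dict)

    def interval(self) -> IntervalCategory:
        return categorize_interval(self.post_transplant_days)

    def to_row(self) -> dict:
        row = {
            "id": self.id,
            "transplant_age_j": self.transplant_age_j,
            "exit_age_x": self.exit_age_x,
            "event_theta": self.event_theta,
            "donor_source": self.donor_source,
            "post_transplant_days": self.post_transplant_days,
            "transplant_year": self.transplant_year,
        }
        for name in COVARIATE_NAMES:
            row[name] = self.covariates.get(name, np.nan)
        return row


@dataclasses.dataclass
class CohortTable:
    """Ordered collection of patient records backed by a DataFrame."""

    df: pd.DataFrame
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cohort table missing required column(s): {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> "CohortTable":
        """Check record-level invariants; raise SchemaError on violation."""
        df = self.df
        ids = df["id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SchemaError(f"duplicate patient id: {dup!r}")
        # missing values are tolerated here (the eligibility filter excludes
        # and counts them); only observed values are checked
        bad_theta = df["event_theta"].notna() & ~df["event_theta"].isin([0, 1])
        if bad_theta.any():
            raise SchemaError(
                f"event_theta must be 0/1; bad row index {int(np.flatnonzero(bad_theta)[0])}"
            )
        bad_donor = df["donor_source"].notna() & ~df["donor_source"].isin(DONOR_SOURCES)
        if bad_donor.any():
            val = df.loc[np.flatnonzero(bad_donor)[0], "donor_source"]
            raise SchemaError(f"donor_source must be one of {DONOR_SOURCES}; got {val!r}")
        ages_seen = df["exit_age_x"].notna() & df["transplant_age_j"].notna()
        if (df.loc[ages_seen, "exit_age_x"] <= df.loc[ages_seen, "transplant_age_j"]).any():
            raise SchemaError("exit_age_x must exceed transplant_age_j for every record")
        dur_seen = ages_seen & df["post_transplant_days"].notna()
        expected = (
            df.loc[dur_seen, "exit_age_x"] - df.loc[dur_seen, "transplant_age_j"]
        ) * DAYS_PER_YEAR
        if (np.abs(expected - df.loc[dur_seen, "post_transplant_days"]) > 1.0).any():
            raise SchemaError(
                "post_transplant_days inconsistent with (exit_age_x - transplant_age_j)"
            )
        return self

    def intervals(self) -> pd.Series:
        """Post-transplant interval label (I1/I2/I3) per record."""
        return pd.Series(
            categorize_interval(self.df["post_transplant_days"].to_numpy()),
            index=self.df.index,
            name="interval",
        )

    def records(self) -> Iterable[PatientRecord]:
        for _, row in self.df.iterrows():
            yield record_from_row(row)

    def equals(self, other: "CohortTable") -> bool:
        a = self.df[list(REQUIRED_COLUMNS)].reset_index(drop=True)
        b = other.df[list(REQUIRED_COLUMNS)].reset_index(drop=True)
        if len(a) != len(b):
            return False
        for col in REQUIRED_COLUMNS:
            if col in _NUMERIC_COLUMNS:
                if not np.allclose(
                    a[col].astype(float), b[col].astype(float), rtol=0, atol=0, equal_nan=True
                ):
                    return False
            else:
                if not (a[col].astype(str) == b[col].astype(str)).all():
                    return False
        return True


def record_from_row(row: pd.Series) -> PatientRecord:
    return PatientRecord(
        id=str(row["id"]),
        transplant_age_j=float(row["transplant_age_j"]),
        exit_age_x=float(row["exit_age_x"]),
        event_theta=int(row["event_theta"]),
        donor_source=str(row["donor_source"]),
        post_transplant_days=float(row["post_transplant_days"]),
        transplant_year=int(row["transplant_year"]),
        covariates={name: row[name] for name in COVARIATE_NAMES},
    )


def cohort_from_records(records: Iterable[PatientRecord]) -> CohortTable:
    return CohortTable(pd.DataFrame([r.to_row() for r in records]))


def categorize_interval(post_transplant_days):
    """Map post-transplant duration (days) to its time-lapse interval.

    Cut-offs are right-closed: 100 days falls in I1 and 365 days in I2.
    Accepts a scalar (returns :class:`IntervalCategory`) or an array
    (returns an object array of labels "I1"/"I2"/"I3").
    """
    arr = np.asarray(post_transplant_days, dtype=float)
    if (arr <= 0).any():
        raise ValueError("post_transplant_days must be positive")
    lo, hi = INTERVAL_BOUNDS_DAYS
    labels = np.where(arr <= lo, "I1", np.where(arr <= hi, "I2", "I3"))
    if np.isscalar(post_transplant_days) or arr.ndim == 0:
        return IntervalCategory(str(labels))
    return labels


def apply_eligibility_filters(cohort: CohortTable) -> tuple[CohortTable, dict]:
    """Apply the study's eligibility restrictions.

    Retains records with exit age above 30 years, transplant age below 70
    years and no missing required field.  A record failing several checks
    is counted once, under the first reason in the order: missing,
    exit_age, transplant_age.  Returns the filtered cohort and a JSON-able
    exclusion report.
    """
    df = cohort.df
    missing_mask = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    exit_mask = (~missing_mask) & (df["exit_age_x"] <= 30.0)
    tx_mask = (~missing_mask) & (~exit_mask) & (df["transplant_age_j"] >= 70.0)
    keep = ~(missing_mask | exit_mask | tx_mask)
    report = {
        "n_input": int(len(df)),
        "n_retained": int(keep.sum()),
        "excluded": {
            "missing": int(missing_mask.sum()),
            "exit_age": int(exit_mask.sum()),
            "transplant_age": int(tx_mask.sum()),
        },
        "filters": {"exit_age_gt": 30.0, "transplant_age_lt": 70.0},
    }
    out = CohortTable(df.loc[keep].reset_index(drop=True), cohort.schema_version)
    return out, report


def write_exclusion_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort as UTF-8 comma-separated text with a header row."""
    # %.17g guarantees float64 round-trip through text
    cohort.df[list(REQUIRED_COLUMNS)].to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV, validating schema, types and enum codings."""
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = raw.copy()
    for col, typ in _NUMERIC_COLUMNS.items():
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"unparseable value in column {col!r} at data row {row + 1}: "
                f"{df.loc[row, col]!r}"
            )
        # cast from the raw strings (correctly rounded), not via to_numeric
        df[col] = df[col].astype(float) if typ is float else converted
    # integer columns: only cast fully observed values
    for col in ("event_theta", "transplant_year"):
        if df[col].notna().all():
            df[col] = df[col].astype(int)
    cohort = CohortTable(df)
    cohort.validate()
    return cohort
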