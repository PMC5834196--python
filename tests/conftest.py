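"""Shared fixtures: small synthetic cohorts and record builders."""
from __future__ import annotations

import numpy as np
import pytest

from allosurv import (
    CohortTable,
    GeneratorConfig,
    PatientRecord,
    cohort_from_records,
    generate_cohort,
)
from allosurv.data_model import COVARIATE_NAMES, DAYS_PER_YEAR


def make_record(
    rid="r1",
    j=40.0,
    x=45.0,
    theta=1,
    donor="related",
    year=2000,
    **covs,
) -> PatientRecord:
    covariates = {name: covs.get(name, 0) for name in COVARIATE_NAMES}
    covariates.setdefault("sex", covs.get("sex", "female"))
    covariates["sex"] = covs.get("sex", "female")
    covariates["disease"] = covs.get("disease", "AML")
    covariates["conditioning"] = covs.get("conditioning", "myeloablative")
    covariates["tbi_band"] = covs.get("tbi_band", "no_tbi")
    covariates["graft_type"] = covs.get("graft_type", "bone_marrow")
    covariates["region"] = covs.get("region", "pacific")
    return PatientRecord(
        id=rid,
        transplant_age_j=j,
        exit_age_x=x,
        event_theta=theta,
        donor_source=donor,
        post_transplant_days=(x - j) * DAYS_PER_YEAR,
        transplant_year=year,
        covariates=covariates,
    )


@pytest.fixture
def tiny_cohort() -> CohortTable:
    recs = [
        make_record("a", j=35.0, x=35.2, theta=1, donor="related", year=1998),
        make_record("b", j=50.0, x=50.5, theta=1, donor="unrelated", year=2001),
        make_record("c", j=42.0, x=55.0, theta=0, donor="unrelated", year=1996),
    ]
    return cohort_from_records(recs)


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-size cohort from the default (study-condition) generator."""
    cohort, truth = generate_cohort(GeneratorConfig(n_patients=1500, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def exponential_cohort():
    """Single-stratum exponential truth (lam=0.15, k=1)."""
    cfg = GeneratorConfig.single_stratum(0.15, 1.0, n_patients=1200, seed=7)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
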