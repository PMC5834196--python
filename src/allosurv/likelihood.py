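"""Stratified left-truncated, right-censored parametric log-likelihood.

Every patient enters one likelihood through a binary stratum matrix
(the "delta" matrix): rows are patients, columns are strata formed by
crossing post-transplant time-lapse interval with donor source.  Each
stratum carries its own baseline hazard parameters while covariates act
proportionally on the hazard, so the contribution of patient i assigned
to stratum s is::

    l_i = theta_i * (log h_s(x_i) + beta.Z_i)
          + exp(beta.Z_i) * (log S_s(x_i) - log S_s(j_i))

with x the exit age, j the transplant (recruitment) age handled as left
truncation, and theta the death indicator.  With a single all-ones
stratum column this is exactly the conventional pooled likelihood.  When
a frailty distribution is specified, h and S are the frailty-marginal
(population) forms and the frailty variance is a free parameter.

Baseline parameters and the frailty variance are optimized on the log
scale (positivity by construction); covariate coefficients beta on the
natural scale.  The proportional-hazards parametrization of a Weibull
baseline is a re-parametrization of the accelerated-failure-time form;
:func:`aft_time_ratio` reports the equivalent AFT time ratio
``exp(-beta / k)``.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CohortTable, PatientRecord, categorize_interval
from .hazards import (
    FAMILIES,
    NO_FRAILTY,
    FrailtySpec,
    FrailtySpec as _FrailtySpec,
    marginal_hazard,
    marginal_log_survival,
)

STRATIFICATIONS = ("none", "interval", "donor", "interval_by_donor")
INTERVALS = ("I1", "I2", "I3")
DONORS = ("related", "unrelated")


class LikelihoodError(ValueError):
    """Non-finite likelihood contribution, carrying the offending record ids."""


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Model definition: hazard family, frailty, stratification, covariates."""

    family: str = "weibull"
    frailty: FrailtySpec = NO_FRAILTY
    stratification: str = "interval_by_donor"
    covariate_names: tuple[str, ...] = ()
    beta_sharing: str = "shared"  # "shared" | "per_stratum"
    fixed: Mapping[str, float] = dataclasses.field(default_factory=dict)
    gh_nodes: int = 64

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.stratification not in STRATIFICATIONS:
            raise ValueError(f"unknown stratification {self.stratification!r}")
        if self.beta_sharing not in ("shared", "per_stratum"):
            raise ValueError(f"unknown beta_sharing {self.beta_sharing!r}")
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        object.__setattr__(self, "fixed", dict(self.fixed))

    def to_config(self) -> dict:
        return {
            "family": self.family,
            "frailty": {
                "distribution": self.frailty.distribution,
                "variance": self.frailty.variance,
            },
            "stratification": self.stratification,
            "covariate_names": list(self.covariate_names),
            "beta_sharing": self.beta_sharing,
            "fixed": dict(self.fixed),
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "ModelSpec":
        fr = cfg.get("frailty", {"distribution": "none", "variance": 0.0})
        if isinstance(fr, str):
            fr = {"distribution": fr, "variance": 0.0}
        return cls(
            family=cfg.get("family", "weibull"),
            frailty=FrailtySpec(fr.get("distribution", "none"), fr.get("variance", 0.0)),
            stratification=cfg.get("stratification", "interval_by_donor"),
            covariate_names=tuple(cfg.get("covariate_names", ())),
            beta_sharing=cfg.get("beta_sharing", "shared"),
            fixed=cfg.get("fixed", {}),
        )


class ParameterVector(dict):
    """Named natural-scale parameters of a fitted/evaluated model."""

    @property
    def omega(self) -> dict:
        return {k: v for k, v in self.items() if not k.startswith("beta_") and k != "sigma2"}

    @property
    def beta(self) -> dict:
        return {k: v for k, v in self.items() if k.startswith("beta_")}

    @property
    def sigma2(self):
        return self.get("sigma2")


@dataclasses.dataclass
class DeltaMatrix:
    """Binary patient-by-stratum membership matrix."""

    entries: np.ndarray  # (n_records, n_strata)
    stratum_labels: tuple[str, ...]

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.ndim != 2 or self.entries.shape[1] != len(self.stratum_labels):
            raise ValueError("delta entries shape inconsistent with stratum labels")

    @property
    def column_sums(self) -> np.ndarray:
        return self.entries.sum(axis=0)


def _stratum_labels(stratification: str) -> tuple[str, ...]:
    if stratification == "none":
        return ("all",)
    if stratification == "interval":
        return INTERVALS
    if stratification == "donor":
        return DONORS
    return tuple(f"{iv}:{d}" for iv in INTERVALS for d in DONORS)


def _record_labels(df: pd.DataFrame, stratification: str) -> np.ndarray:
    if stratification == "none":
        return np.full(len(df), "all", dtype=object)
    intervals = categorize_interval(df["post_transplant_days"].to_numpy())
    if stratification == "interval":
        return np.asarray(intervals, dtype=object)
    if stratification == "donor":
        return df["donor_source"].to_numpy(dtype=object)
    return np.array(
        [f"{iv}:{d}" for iv, d in zip(intervals, df["donor_source"])], dtype=object
    )


def build_delta(cohort: CohortTable | pd.DataFrame, stratification: str) -> DeltaMatrix:
    """One-hot stratum membership; ``none`` yields a single all-ones column
    (the conventional pooled likelihood)."""
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    if stratification not in STRATIFICATIONS:
        raise ValueError(f"unknown stratification {stratification!r}")
    labels = _stratum_labels(stratification)
    rec = _record_labels(df, stratification)
    entries = (rec[:, None] == np.array(labels, dtype=object)[None, :]).astype(np.int8)
    if not (entries.sum(axis=1) == 1).all():
        bad = int(np.flatnonzero(entries.sum(axis=1) != 1)[0])
        raise ValueError(f"record at row {bad} has no defined stratum")
    return DeltaMatrix(entries, labels)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design(df: pd.DataFrame, covariate_names: Sequence[str]):
    """Encode covariates: 0/1 columns pass through, other categoricals are
    dummy-coded against the first sorted level, numeric columns with more
    than two values enter as a single mean-centered continuous term.

    Returns ``(Z, column_names, info)`` where ``info`` maps covariate ->
    encoding metadata (levels, reference, modal level, design columns).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    info: dict[str, dict] = {}
    for cov in covariate_names:
        if cov not in df.columns:
            raise ValueError(f"unknown covariate {cov!r}")
        vals = df[cov]
        numeric = pd.api.types.is_numeric_dtype(vals)
        uniq = pd.unique(vals.dropna())
        if numeric and set(np.asarray(uniq, dtype=float)) <= {0.0, 1.0}:
            z = vals.to_numpy(dtype=float)
            name = f"beta_{cov}"
            cols.append(z)
            names.append(name)
            info[cov] = {
                "type": "binary",
                "columns": [name],
                "modal": int(round(float(vals.mode().iloc[0]))) if len(vals) else 0,
            }
        elif numeric and len(uniq) > 2:
            center = float(vals.mean())
            cols.append(vals.to_numpy(dtype=float) - center)
            name = f"beta_{cov}"
            names.append(name)
            info[cov] = {
                "type": "continuous",
                "columns": [name],
                "center": center,
                "modal": center,
            }
        else:
            levels = sorted(str(v) for v in uniq)
            ref = levels[0] if levels else None
            block = []
            sv = vals.astype(str)
            for level in levels[1:]:
                name = f"beta_{cov}[{level}]"
                cols.append((sv == level).to_numpy(dtype=float))
                names.append(name)
                block.append(name)
            info[cov] = {
                "type": "categorical",
                "levels": levels,
                "reference": ref,
                "columns": block,
                "modal": str(sv.mode().iloc[0]) if len(sv) else ref,
            }
    Z = np.column_stack(cols) if cols else np.zeros((len(df), 0))
    return Z, names, info


# ---------------------------------------------------------------------------
# compiled model: packed parameter layout + vectorized log-likelihood
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ParamInfo:
    name: str
    transform: str  # "log" | "identity"
    kind: str  # "baseline" | "beta" | "sigma2"
    base: str  # underlying parameter or design-column name
    stratum: str | None = None


class CompiledModel:
    """Cohort + spec compiled to a fast packed-vector log-likelihood."""

    def __init__(self, cohort, spec: ModelSpec, delta: DeltaMatrix | None = None):
        df = cohort.df if isinstance(cohort, CohortTable) else cohort
        self.spec = spec
        self.df = df.reset_index(drop=True)
        if delta is None:
            delta = build_delta(self.df, spec.stratification)
        self.delta = delta
        n = len(self.df)
        if delta.entries.shape[0] != n:
            raise ValueError("delta row count does not match cohort size")
        self.x = self.df["exit_age_x"].to_numpy(dtype=float)
        self.j = self.df["transplant_age_j"].to_numpy(dtype=float)
        self.theta = self.df["event_theta"].to_numpy(dtype=float)
        self.ids = self.df["id"].astype(str).to_numpy()
        # strata with no members are dropped from the parameter layout
        counts = delta.column_sums
        active = [i for i, c in enumerate(counts) if c > 0]
        self.stratum_labels = tuple(delta.stratum_labels[i] for i in active)
        self.dropped_strata = tuple(
            delta.stratum_labels[i] for i, c in enumerate(counts) if c == 0
        )
        sub = delta.entries[:, active]
        self.stratum_idx = np.argmax(sub, axis=1)
        # per-stratum index and data sub-arrays, precomputed once for speed
        self._sub_idx = [
            np.flatnonzero(self.stratum_idx == s) for s in range(len(self.stratum_labels))
        ]
        self._sub_x = [self.x[ix] for ix in self._sub_idx]
        self._sub_j = [self.j[ix] for ix in self._sub_idx]
        self._sub_theta = [self.theta[ix] for ix in self._sub_idx]
        self.Z, self.beta_names, self.design_info = build_design(
            self.df, spec.covariate_names
        )
        self._build_layout()

    # -- layout -------------------------------------------------------------
    def _build_layout(self):
        spec = self.spec
        layout: list[ParamInfo] = []
        single = len(self.stratum_labels) == 1
        for s in self.stratum_labels:
            for p in FAMILIES[spec.family]:
                if p in spec.fixed:
                    continue
                name = p if single else f"{p}[{s}]"
                layout.append(ParamInfo(name, "log", "baseline", p, s))
        if spec.beta_sharing == "shared":
            for bn in self.beta_names:
                layout.append(ParamInfo(bn, "identity", "beta", bn, None))
        else:
            for s in self.stratum_labels:
                for bn in self.beta_names:
                    layout.append(ParamInfo(f"{bn}[{s}]", "identity", "beta", bn, s))
        if spec.frailty.active:
            layout.append(ParamInfo("sigma2", "log", "sigma2", "sigma2", None))
        self.layout = tuple(layout)
        self.param_names = tuple(p.name for p in layout)
        self.transforms = tuple(p.transform for p in layout)
        self.n_params = len(layout)
        self._baseline_slices = []
        idx = {p.name: i for i, p in enumerate(layout)}
        for s in self.stratum_labels:
            entries = {}
            for p in FAMILIES[spec.family]:
                if p in spec.fixed:
                    entries[p] = ("fixed", float(spec.fixed[p]))
                else:
                    name = p if single_name(self.stratum_labels) else f"{p}[{s}]"
                    entries[p] = ("free", idx[name])
            self._baseline_slices.append(entries)
        if spec.beta_sharing == "shared":
            self._beta_idx = np.array([idx[bn] for bn in self.beta_names], dtype=int)
        else:
            self._beta_idx = np.array(
                [
                    [idx[f"{bn}[{s}]"] for bn in self.beta_names]
                    for s in self.stratum_labels
                ],
                dtype=int,
            )
        self._sigma2_idx = idx.get("sigma2")

    # -- packing ------------------------------------------------------------
    def to_internal(self, params: Mapping[str, float]) -> np.ndarray:
        vec = np.empty(self.n_params)
        for i, p in enumerate(self.layout):
            if p.name not in params:
                raise KeyError(f"parameter {p.name!r} missing")
            v = float(params[p.name])
            vec[i] = math.log(v) if p.transform == "log" else v
        return vec

    def to_natural(self, vec: np.ndarray) -> ParameterVector:
        out = ParameterVector()
        for i, p in enumerate(self.layout):
            out[p.name] = math.exp(vec[i]) if p.transform == "log" else float(vec[i])
        return out

    def _stratum_params(self, vec: np.ndarray, s: int) -> dict:
        return {
            p: (val if src == "fixed" else math.exp(vec[val]))
            for p, (src, val) in self._baseline_slices[s].items()
        }

    # -- evaluation ----------------------------------------------------------
    def contributions(self, vec: np.ndarray) -> np.ndarray:
        """Per-record log-likelihood contributions at internal parameters."""
        spec = self.spec
        if spec.frailty.active:
            sigma2 = math.exp(vec[self._sigma2_idx])
            frailty = _FrailtySpec(spec.frailty.distribution, sigma2)
        else:
            frailty = NO_FRAILTY
        if spec.beta_sharing == "shared":
            eta = self.Z @ vec[self._beta_idx] if self.Z.shape[1] else np.zeros(len(self.x))
        else:
            if self.Z.shape[1]:
                beta_rows = vec[self._beta_idx][self.stratum_idx]
                eta = np.einsum("ij,ij->i", self.Z, beta_rows)
            else:
                eta = np.zeros(len(self.x))
        ll = np.empty(len(self.x))
        for s, ix in enumerate(self._sub_idx):
            params = self._stratum_params(vec, s)
            xs, js, th = self._sub_x[s], self._sub_j[s], self._sub_theta[s]
            logh = np.log(
                marginal_hazard(spec.family, params, frailty, xs, gh_nodes=spec.gh_nodes)
            )
            logS_x = marginal_log_survival(
                spec.family, params, frailty, xs, gh_nodes=spec.gh_nodes
            )
            logS_j = marginal_log_survival(
                spec.family, params, frailty, js, gh_nodes=spec.gh_nodes
            )
            eta_s = eta[ix]
            ll[ix] = th * (logh + eta_s) + np.exp(eta_s) * (logS_x - logS_j)
        return ll

    def loglik(self, vec: np.ndarray) -> float:
        """Total log-likelihood; raises LikelihoodError on non-finite rows."""
        ll = self.contributions(vec)
        bad = ~np.isfinite(ll)
        if bad.any():
            raise LikelihoodError(
                f"non-finite log-likelihood for record id(s) {list(self.ids[bad][:5])}"
            )
        return float(ll.sum())

    def loglik_safe(self, vec: np.ndarray) -> float:
        """Optimizer-facing evaluation: non-finite maps to -inf."""
        try:
            with np.errstate(all="ignore"):
                ll = self.contributions(vec)
        except (ValueError, FloatingPointError, OverflowError):
            return -np.inf
        total = ll.sum()
        return float(total) if np.isfinite(total) else -np.inf

    # -- covariate profiles ---------------------------------------------------
    def encode_profile(self, profile: Mapping[str, object] | None) -> np.ndarray:
        """Design-row for a covariate profile; unspecified covariates take
        their modal (most frequent) level in the compiled cohort."""
        profile = dict(profile or {})
        z = np.zeros(len(self.beta_names))
        pos = {bn: i for i, bn in enumerate(self.beta_names)}
        for cov in self.spec.covariate_names:
            inf = self.design_info[cov]
            val = profile.get(cov, inf["modal"])
            if inf["type"] == "binary":
                z[pos[f"beta_{cov}"]] = float(val)
            elif inf["type"] == "continuous":
                z[pos[f"beta_{cov}"]] = float(val) - inf["center"]
            else:
                val = str(val)
                if val not in inf["levels"]:
                    raise ValueError(f"unknown level {val!r} for covariate {cov!r}")
                name = f"beta_{cov}[{val}]"
                if name in pos:
                    z[pos[name]] = 1.0
        return z

    def default_profile(self) -> dict:
        return {cov: self.design_info[cov]["modal"] for cov in self.spec.covariate_names}


def single_name(labels) -> bool:
    return len(labels) == 1


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def total_loglik(
    cohort,
    spec: ModelSpec,
    params: Mapping[str, float],
    delta: DeltaMatrix | None = None,
) -> float:
    """Total log-likelihood of a cohort at natural-scale parameters."""
    model = CompiledModel(cohort, spec, delta)
    return model.loglik(model.to_internal(params))


def _record_frame(record: PatientRecord) -> pd.DataFrame:
    return pd.DataFrame([record.to_row()])


def individual_loglik(
    record: PatientRecord,
    spec: ModelSpec,
    params: Mapping[str, float],
    delta_row: np.ndarray | None = None,
) -> float:
    """One record's contribution log[h(x)^theta e^(theta beta.Z) S(x)/S(j)].

    With theta = 0 this is the conditional log-survival
    log S(x) - log S(j); with j = 0 the truncation term vanishes.
    ``delta_row``, when given, must match the record's one-hot stratum row.
    """
    df = _record_frame(record)
    delta = build_delta(df, spec.stratification)
    if delta_row is not None:
        if not np.array_equal(
            np.asarray(delta_row, dtype=np.int8).ravel(), delta.entries.ravel()
        ):
            raise ValueError("delta_row does not match the record's stratum")
    model = CompiledModel(df, spec, delta)
    return model.loglik(model.to_internal(params))


def truncation_term(
    record: PatientRecord, spec: ModelSpec, params: Mapping[str, float]
) -> float:
    """Left-truncation term -log S(j) (log of tr.S(j) = 1/S(j)); 0 at j = 0."""
    df = _record_frame(record)
    model = CompiledModel(df, spec)
    vec = model.to_internal(params)
    p = model._stratum_params(vec, 0)
    fr = (
        _FrailtySpec(spec.frailty.distribution, math.exp(vec[model._sigma2_idx]))
        if spec.frailty.active
        else NO_FRAILTY
    )
    val = -marginal_log_survival(
        spec.family, p, fr, record.transplant_age_j, gh_nodes=spec.gh_nodes
    )
    if not np.isfinite(val):
        raise LikelihoodError(f"impossible truncation (S(j)=0) for record {record.id}")
    return float(val)


def aft_time_ratio(beta: float, k: float) -> float:
    """AFT time ratio exp(-beta/k) equivalent to a proportional-hazards
    log-hazard-ratio beta under a Weibull baseline with shape k."""
    return math.exp(-beta / k)
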