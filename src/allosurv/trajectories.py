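"""Age-specific mortality trajectories and rate-of-aging curves.

A fitted model induces, per stratum, a hazard over an age grid at a
stated covariate profile: mu(x) = h_stratum(x) * exp(beta . Z_profile)
(frailty-marginal h when the fit carries frailty).  The trajectory table
holds the hazard, its log (plotted on a semi-log axis in the field's
standard presentation) and the rate of aging d(log mu)/dx.  Crossing
ages of two trajectories — where the log-hazard difference changes sign
— mark the hazard-line convergence that signals either heterogeneity or,
in its absence, a senescence ceiling.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .estimation import FitResult
from .hazards import NO_FRAILTY, FrailtySpec, marginal_hazard, rate_of_aging

#: default grid matches the eligibility window (exit ages above 30, entries below 70)
DEFAULT_AGE_GRID = np.arange(30.0, 70.0 + 1e-9, 0.5)


@dataclasses.dataclass
class TrajectoryTable:
    """Hazard, log-hazard and rate of aging on an age grid for one stratum."""

    stratum: str
    covariate_profile: dict
    table: pd.DataFrame  # columns: age, hazard, log_hazard, rate_of_aging

    @property
    def age_grid(self) -> np.ndarray:
        return self.table["age"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _stratum_params(fit: FitResult, stratum: str) -> dict:
    from .hazards import FAMILIES

    model = fit.model
    if model is None:
        raise ValueError("fit result carries no compiled model")
    if stratum not in model.stratum_labels:
        raise ValueError(
            f"stratum {stratum!r} absent from fit (have {model.stratum_labels})"
        )
    single = len(model.stratum_labels) == 1
    out = {}
    for p in FAMILIES[fit.spec.family]:
        if p in fit.spec.fixed:
            out[p] = float(fit.spec.fixed[p])
        else:
            name = p if single else f"{p}[{stratum}]"
            out[p] = float(fit.params_hat[name])
    return out


def trajectory(
    fit: FitResult,
    stratum: str = "all",
    covariate_profile: dict | None = None,
    age_grid: np.ndarray | None = None,
) -> TrajectoryTable:
    """Evaluate mu(x) = h_stratum(x) exp(beta.Z_profile) on an age grid.

    The default profile sets every covariate to its most frequent level in
    the fitted cohort; the default grid is 30-70 years in 0.5-year steps.
    """
    if not fit.converged:
        raise ValueError("trajectory requires a converged fit")
    model = fit.model
    grid = DEFAULT_AGE_GRID if age_grid is None else np.asarray(age_grid, dtype=float)
    params = _stratum_params(fit, stratum)
    profile = dict(model.default_profile())
    profile.update(covariate_profile or {})
    z = model.encode_profile(profile)
    if fit.spec.beta_sharing == "shared":
        beta = np.array([fit.params_hat[bn] for bn in model.beta_names])
    else:
        beta = np.array([fit.params_hat[f"{bn}[{stratum}]"] for bn in model.beta_names])
    eta = float(z @ beta) if len(beta) else 0.0
    if fit.spec.frailty.active:
        frailty = FrailtySpec(fit.spec.frailty.distribution, fit.params_hat["sigma2"])
    else:
        frailty = NO_FRAILTY
    haz = (
        np.asarray(marginal_hazard(fit.spec.family, params, frailty, grid)) * math.exp(eta)
    )
    roa = np.asarray(rate_of_aging(fit.spec.family, params, grid, frailty))
    table = pd.DataFrame(
        {
            "age": grid,
            "hazard": haz,
            "log_hazard": np.log(haz),
            "rate_of_aging": roa,
        }
    )
    return TrajectoryTable(stratum=stratum, covariate_profile=profile, table=table)


def crossing_age(traj_a: TrajectoryTable, traj_b: TrajectoryTable):
    """Ages where two trajectories' log-hazards cross, by linear interpolation.

    Returns ``None`` when the difference is identically zero (degenerate:
    the trajectories coincide), otherwise a tuple of crossing ages in
    increasing order (empty when the curves never cross — e.g. parallel
    Gompertz lines).
    """
    ga, gb = traj_a.age_grid, traj_b.age_grid
    if len(ga) != len(gb) or not np.allclose(ga, gb):
        raise ValueError("trajectories must share an age grid")
    diff = traj_a.table["log_hazard"].to_numpy() - traj_b.table["log_hazard"].to_numpy()
    if np.max(np.abs(diff)) < 1e-12:
        return None
    crossings = []
    sign = np.sign(diff)
    for i in range(len(diff) - 1):
        if sign[i] == 0:
            crossings.append(float(ga[i]))
        elif sign[i] * sign[i + 1] < 0:
            frac = diff[i] / (diff[i] - diff[i + 1])
            crossings.append(float(ga[i] + frac * (ga[i + 1] - ga[i])))
    if sign[-1] == 0:
        crossings.append(float(ga[-1]))
    return tuple(crossings)


def plot_trajectories(tables, path=None, ax=None, title=None, panel_label=None):
    """Semi-log hazard plot of one or more trajectories.

    ``tables`` maps a line label to a TrajectoryTable; related/unrelated
    pairs follow the dashed/solid convention of the field's figures.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, tt in tables.items():
        style = "--" if "related" in label and "unrelated" not in label else "-"
        ax.plot(tt.age_grid, tt.table["hazard"], style, label=label)
    ax.set_yscale("log")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("hazard (/year)")
    if title:
        ax.set_title(title)
    if panel_label:
        ax.annotate(panel_label, xy=(0.02, 0.95), xycoords="axes fraction", weight="bold")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
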