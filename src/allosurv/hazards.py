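"""Parametric hazard families, frailty-marginal forms and the rate of aging.

Baseline families
-----------------
gompertz            mu(x) = a * exp(b * x)
gompertz_makeham    mu(x) = c + a * exp(b * x)
weibull             mu(x) = lam * k * x**(k - 1)
weibull_makeham     mu(x) = c + lam * k * x**(k - 1)

All baseline parameters are positive on the natural scale (`c >= 0`).  The
Weibull shape ``k`` controls the hazard's bend: ``k < 1`` gives a
decelerating (inverse-J tail) hazard, ``k = 1`` a flat hazard (negligible
senescence), ``k > 1`` an accelerating one.

Frailty
-------
An unobserved multiplicative individual risk ``z`` with mean 1 and variance
``sigma2`` mixes the baseline; the population (marginal) survival is the
Laplace transform of the frailty distribution evaluated at the cumulative
hazard.  Gamma and inverse-Gaussian frailty have closed forms; log-normal
frailty is marginalized by Gauss-Hermite quadrature.

Rate of aging
-------------
d(log mu(x))/dx — the relative derivative of the hazard.  For Gompertz it
is the slope ``b`` at every age; for Weibull it is ``(k - 1)/x``; for
Makeham and frailty-marginal hazards it is evaluated by central
differences of the log marginal hazard.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy.special import logsumexp

FAMILIES: dict[str, tuple[str, ...]] = {
    "gompertz": ("a", "b"),
    "gompertz_makeham": ("a", "b", "c"),
    "weibull": ("lam", "k"),
    "weibull_makeham": ("lam", "k", "c"),
}

FRAILTY_DISTRIBUTIONS = ("none", "gamma", "inverse_gaussian", "log_normal")

#: below this frailty variance the marginal forms use the degenerate limit
_SIGMA2_EPS = 1e-8


@dataclasses.dataclass(frozen=True)
class FrailtySpec:
    """Frailty choice: distribution family and variance (mean fixed at 1)."""

    distribution: str = "none"
    variance: float = 0.0

    def __post_init__(self):
        if self.distribution not in FRAILTY_DISTRIBUTIONS:
            raise ValueError(f"unknown frailty distribution {self.distribution!r}")
        if self.variance < 0:
            raise ValueError("frailty variance must be nonnegative")

    @property
    def active(self) -> bool:
        return self.distribution != "none"


NO_FRAILTY = FrailtySpec()


def _check_family(family: str, params: Mapping[str, float]) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown hazard family {family!r}")
    missing = [p for p in FAMILIES[family] if p not in params]
    if missing:
        raise ValueError(f"family {family!r} missing parameter(s) {missing}")


def hazard(family: str, params: Mapping[str, float], x):
    """Baseline hazard mu(x) at age x (> 0), in events per year."""
    _check_family(family, params)
    x = np.asarray(x, dtype=float)
    if family.startswith("gompertz"):
        out = params["a"] * np.exp(params["b"] * x)
    else:
        k = params["k"]
        if np.any(x <= 0) and k < 1:
            raise ValueError("weibull hazard with k < 1 is singular at x <= 0")
        out = params["lam"] * k * x ** (k - 1.0)
    if family.endswith("makeham"):
        out = out + params["c"]
    return out if out.ndim else float(out)


def cumulative_hazard(family: str, params: Mapping[str, float], x):
    """Integrated hazard Lambda(x) = int_0^x mu(u) du (dimensionless)."""
    _check_family(family, params)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be nonnegative")
    if family.startswith("gompertz"):
        a, b = params["a"], params["b"]
        # expm1 keeps the b -> 0 limit (a * x) accurate; b == 0 handled exactly
        out = a * x if b == 0 else (a / b) * np.expm1(b * x)
    else:
        out = params["lam"] * x ** params["k"]
    if family.endswith("makeham"):
        out = out + params["c"] * x
    return out if out.ndim else float(out)


def survival(family: str, params: Mapping[str, float], x):
    """Baseline survival S(x) = exp(-Lambda(x)); S(0) = 1."""
    return np.exp(-np.asarray(cumulative_hazard(family, params, x)))[()]


# ---------------------------------------------------------------------------
# frailty marginals
# ---------------------------------------------------------------------------

def _gh_frailty_nodes(sigma2: float, n_nodes: int):
    """Gauss-Hermite nodes/weights for a mean-1 log-normal frailty.

    If z ~ LogNormal(mu, s^2) with E z = 1 and Var z = sigma2 then
    s^2 = log(1 + sigma2) and mu = -s^2 / 2.
    """
    s2 = np.log1p(sigma2)
    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    z = np.exp(-0.5 * s2 + np.sqrt(2.0 * s2) * t)
    logw = np.log(w) - 0.5 * np.log(np.pi)
    return z, logw


def marginal_log_survival(
    family: str,
    params: Mapping[str, float],
    frailty: FrailtySpec,
    x,
    *,
    gh_nodes: int = 64,
):
    """log of the population survival marginalized over frailty.

    gamma:            -(1/s2) * log(1 + s2 * Lambda)
    inverse-Gaussian: (1/s2) * (1 - sqrt(1 + 2 * s2 * Lambda))
    log-normal:       log E[exp(-z * Lambda)] by Gauss-Hermite quadrature
    The sigma2 -> 0 limit of every form is the baseline -Lambda.
    """
    lam = np.asarray(cumulative_hazard(family, params, x), dtype=float)
    s2 = frailty.variance
    if not frailty.active or s2 <= _SIGMA2_EPS:
        return lam * -1.0 if lam.ndim else -float(lam)
    if frailty.distribution == "gamma":
        out = -np.log1p(s2 * lam) / s2
    elif frailty.distribution == "inverse_gaussian":
        out = (1.0 - np.sqrt(1.0 + 2.0 * s2 * lam)) / s2
    else:  # log_normal
        z, logw = _gh_frailty_nodes(s2, gh_nodes)
        out = logsumexp(logw[:, None] - z[:, None] * np.atleast_1d(lam)[None, :], axis=0)
        out = out.reshape(np.shape(lam))
    return out if np.ndim(out) else float(out)


def marginal_survival(family, params, frailty, x, *, gh_nodes: int = 64):
    """Population survival marginalized over frailty (probability)."""
    return np.exp(marginal_log_survival(family, params, frailty, x, gh_nodes=gh_nodes))


# Backwards-friendly alias matching the operation name used elsewhere.
frailty_marginal_survival = marginal_survival


def marginal_hazard(family, params, frailty, x, *, gh_nodes: int = 64):
    """Population hazard -d/dx log marginal survival.

    gamma:            mu(x) / (1 + s2 * Lambda(x))
    inverse-Gaussian: mu(x) / sqrt(1 + 2 * s2 * Lambda(x))
    log-normal:       mu(x) * E[z e^{-z Lambda}] / E[e^{-z Lambda}]
    """
    h = np.asarray(hazard(family, params, x), dtype=float)
    s2 = frailty.variance
    if not frailty.active or s2 <= _SIGMA2_EPS:
        return h if h.ndim else float(h)
    lam = np.asarray(cumulative_hazard(family, params, x), dtype=float)
    if frailty.distribution == "gamma":
        out = h / (1.0 + s2 * lam)
    elif frailty.distribution == "inverse_gaussian":
        out = h / np.sqrt(1.0 + 2.0 * s2 * lam)
    else:
        z, logw = _gh_frailty_nodes(s2, gh_nodes)
        lam1 = np.atleast_1d(lam)
        log_num = logsumexp(
            logw[:, None] + np.log(z)[:, None] - z[:, None] * lam1[None, :], axis=0
        )
        log_den = logsumexp(logw[:, None] - z[:, None] * lam1[None, :], axis=0)
        out = (h * np.exp(log_num - log_den).reshape(np.shape(lam)))
    return out if np.ndim(out) else float(out)


frailty_marginal_hazard = marginal_hazard


def rate_of_aging(
    family: str,
    params: Mapping[str, float],
    x,
    frailty: FrailtySpec = NO_FRAILTY,
    *,
    gh_nodes: int = 64,
    step: float = 1e-5,
):
    """Rate of aging d(log mu(x))/dx of the (marginal) hazard.

    Closed forms: Gompertz without frailty returns b for every age;
    Weibull without frailty returns (k - 1)/x (zero when k = 1, negative
    when k < 1 — a decelerating hazard).  Makeham and frailty-marginal
    hazards use central differences of the log hazard with a relative
    step.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("rate of aging requires x > 0")
    if not frailty.active or frailty.variance <= _SIGMA2_EPS:
        if family == "gompertz":
            out = np.full_like(x, params["b"], dtype=float)
            return out if out.ndim else float(out)
        if family == "weibull":
            out = (params["k"] - 1.0) / x
            return out if out.ndim else float(out)
    h = step * np.maximum(1.0, x)
    lo = np.maximum(x - h, x * 0.5)
    hi = x + h
    f_hi = np.log(marginal_hazard(family, params, frailty, hi, gh_nodes=gh_nodes))
    f_lo = np.log(marginal_hazard(family, params, frailty, lo, gh_nodes=gh_nodes))
    out = (np.asarray(f_hi) - np.asarray(f_lo)) / (hi - lo)
    if np.any(~np.isfinite(out)):
        raise ValueError("hazard vanished on the rate-of-aging grid")
    return out if out.ndim else float(out)


@dataclasses.dataclass(frozen=True)
class HazardFamily:
    """Convenience bundle of a family name and its natural-scale parameters."""

    name: str
    params: Mapping[str, float]

    def __post_init__(self):
        _check_family(self.name, self.params)

    def hazard(self, x):
        return hazard(self.name, self.params, x)

    def cumulative_hazard(self, x):
        return cumulative_hazard(self.name, self.params, x)

    def survival(self, x):
        return survival(self.name, self.params, x)

    def rate_of_aging(self, x, frailty: FrailtySpec = NO_FRAILTY):
        return rate_of_aging(self.name, self.params, x, frailty)
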