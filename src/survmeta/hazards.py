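"""Parametric hazard families and covariate machinery for aggregate survival models.

Three proportional-hazard time shapes are supported, each parameterized by an
initial death risk ``beta0`` (events per month at the start of follow-up) and,
except for the constant family, a shape parameter ``beta1``:

========= ==========================  =================================
family    hazard h(t)                 cumulative hazard  Lambda(0, t)
========= ==========================  =================================
constant  beta0                       beta0 * t
gompertz  beta0 * exp(beta1 * t)      beta0/beta1 * (exp(beta1*t) - 1)
weibull   beta0 * t**beta1            beta0/(beta1+1) * t**(beta1+1)
========= ==========================  =================================

Survival is ``S(t) = exp(-Lambda(0, t))``.  Study-level covariates act
multiplicatively on ``beta0`` through a log-linear model centered at reference
(median) covariate values, together with a log-scale random study effect eta:

    beta_i = beta_typical * exp(sum_k (COV_ik - REF_k) * theta_k + eta_i)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FAMILIES",
    "InvalidParameterError",
    "CovariateError",
    "HazardModelSpec",
    "CovariateTerm",
    "CovariateModel",
    "SurvivalCurve",
    "hazard",
    "cumulative_hazard",
    "survival",
    "median_survival_time",
    "apply_covariates",
]

FAMILIES = ("constant", "gompertz", "weibull")

#: below this |beta1| the Gompertz cumulative hazard switches to a series
#: expansion to avoid catastrophic cancellation in expm1(beta1*t)/beta1
_GOMPERTZ_SERIES_CUTOFF = 1e-8


class InvalidParameterError(ValueError):
    """A hazard-model parameter is outside its admissible domain."""


class CovariateError(KeyError):
    """A covariate required by the model is missing from the supplied values."""


@dataclass(frozen=True)
class HazardModelSpec:
    """A hazard family with its parameters.

    Parameters
    ----------
    family : {"constant", "gompertz", "weibull"}
    beta0 : float
        Initial death risk per month; must be positive.
    beta1 : float, default 0.0
        Shape parameter. Ignored by the constant family.  For the Weibull
        family ``beta1 > -1`` so the cumulative hazard converges at 0.
    """

    family: str
    beta0: float
    beta1: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidParameterError(
                f"unknown hazard family {self.family!r}; expected one of {FAMILIES}"
            )
        if not (np.isfinite(self.beta0) and self.beta0 > 0):
            raise InvalidParameterError(f"beta0 must be positive, got {self.beta0}")
        if self.family == "weibull" and self.beta1 <= -1.0:
            raise InvalidParameterError(
                f"weibull shape beta1 must exceed -1 for an integrable hazard, got {self.beta1}"
            )

    @property
    def n_params(self) -> int:
        return 1 if self.family == "constant" else 2

    def with_beta0(self, beta0: float) -> "HazardModelSpec":
        return HazardModelSpec(self.family, beta0, self.beta1)


def hazard(spec: HazardModelSpec, t):
    """Instantaneous death risk per month at time ``t`` (months)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    if spec.family == "constant":
        out = np.full_like(t_arr, spec.beta0)
    elif spec.family == "gompertz":
        out = spec.beta0 * np.exp(spec.beta1 * t_arr)
    else:  # weibull: h(t) = beta0 * exp(beta1 * ln t) = beta0 * t**beta1
        if spec.beta1 < 0 and np.any(t_arr == 0):
            raise InvalidParameterError(
                "weibull hazard with beta1 < 0 diverges at t = 0"
            )
        out = spec.beta0 * np.power(t_arr, spec.beta1)
    return out.item() if np.isscalar(t) or t_arr.ndim == 0 else out


def cumulative_hazard(spec: HazardModelSpec, t0, t):
    """Cumulative death risk over the interval ``[t0, t]`` (closed form)."""
    t0_arr = np.asarray(t0, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t0_arr < 0) or np.any(t_arr < t0_arr):
        raise ValueError("require 0 <= t0 <= t")
    b0, b1 = spec.beta0, spec.beta1
    if spec.family == "constant":
        out = b0 * (t_arr - t0_arr)
    elif spec.family == "gompertz":
        if abs(b1) < _GOMPERTZ_SERIES_CUTOFF:
            # series in beta1 around 0: b0*(dt + b1*(t^2-t0^2)/2 + b1^2*(t^3-t0^3)/6)
            out = b0 * (
                (t_arr - t0_arr)
                + b1 * (t_arr**2 - t0_arr**2) / 2.0
                + b1**2 * (t_arr**3 - t0_arr**3) / 6.0
            )
        else:
            out = b0 / b1 * (np.exp(b1 * t_arr) - np.exp(b1 * t0_arr))
    else:
        p = b1 + 1.0
        out = b0 / p * (np.power(t_arr, p) - np.power(t0_arr, p))
    scalar = np.isscalar(t) and np.isscalar(t0)
    return out.item() if scalar or out.ndim == 0 else out


def survival(spec: HazardModelSpec, t):
    """Survival probability ``S(t) = exp(-Lambda(0, t))``."""
    return np.exp(-cumulative_hazard(spec, 0.0, t))


def median_survival_time(spec: HazardModelSpec, tol: float = 1e-8) -> float:
    """Time in months at which the survival function crosses 0.5.

    Exact ``ln 2 / beta0`` for the constant family; otherwise solved by
    bracketed root finding to an absolute tolerance of ``tol`` months.
    """
    if spec.family == "constant":
        return math.log(2.0) / spec.beta0
    f = lambda t: survival(spec, t) - 0.5
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("median survival exceeds 1e9 months; check parameters")
    lo = hi / 2.0 if hi > 1.0 else 0.0
    while lo > 0 and f(lo) < 0:
        lo /= 2.0
    return brentq(f, lo, hi, xtol=tol)


@dataclass(frozen=True)
class CovariateTerm:
    """One log-linear covariate term: coefficient and centering reference."""

    name: str
    theta: float
    reference: float


@dataclass(frozen=True)
class CovariateModel:
    """Ordered collection of covariate terms acting on log beta0."""

    terms: tuple[CovariateTerm, ...] = ()

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate covariate names in {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    def linear_predictor(self, cov_values: Mapping[str, float]) -> float:
        """``sum_k (COV_k - REF_k) * theta_k`` for the supplied covariates."""
        lp = 0.0
        for term in self.terms:
            if term.name not in cov_values:
                raise CovariateError(f"missing covariate {term.name!r}")
            lp += (float(cov_values[term.name]) - term.reference) * term.theta
        return lp

    def multiplier(self, cov_values: Mapping[str, float]) -> float:
        return math.exp(self.linear_predictor(cov_values))


def apply_covariates(
    beta_typical: float,
    cov_model: CovariateModel,
    cov_values: Mapping[str, float],
    eta: float = 0.0,
) -> float:
    """Study-level hazard parameter from the typical value, covariates and eta.

    Returns ``beta_typical * exp(sum_k (COV_k - REF_k)*theta_k + eta)``.
    At the reference covariate values with ``eta = 0`` this is the identity.
    """
    return beta_typical * math.exp(cov_model.linear_predictor(cov_values) + eta)


@dataclass(frozen=True)
class SurvivalCurve:
    """A survival function tabulated on a time grid (months, fraction in [0,1])."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", surv)
        if times.ndim != 1 or surv.shape != times.shape:
            raise ValueError("times and survival must be matching 1-D arrays")
        if np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any((surv < 0) | (surv > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(surv) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if times.size and times[0] == 0 and surv[0] != 1.0:
            raise ValueError("survival at t=0 must be 1")

    @classmethod
    def from_spec(cls, spec: HazardModelSpec, times: Sequence[float]) -> "SurvivalCurve":
        t = np.asarray(times, dtype=float)
        return cls(t, survival(spec, t))
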