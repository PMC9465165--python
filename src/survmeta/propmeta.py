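"""Single-arm random-effects meta-analysis of response and toxicity proportions.

Arm-level proportions are pooled on a transformed scale (logit by default, so
back-transformed confidence intervals stay inside [0, 100]%) with inverse-
variance weights and a DerSimonian-Laird moment estimate of the between-study
variance tau^2 (REML and a fixed-effect mode are selectable).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit

from .data import ENDPOINTS, REGIMENS, Dataset

__all__ = [
    "PooledProportion",
    "dersimonian_laird",
    "reml_tau2",
    "pool_proportions",
    "endpoint_report",
    "format_report",
]


def dersimonian_laird(
    y: np.ndarray, v: np.ndarray
) -> tuple[float, float, float, float]:
    """DerSimonian-Laird random-effects pooling of estimates ``y`` with variances ``v``.

    Returns ``(pooled, se, tau2, Q)`` where Q is Cochran's heterogeneity
    statistic and tau2 the truncated moment estimate of the between-study
    variance.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = len(y)
    w = 1.0 / v
    ybar = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - ybar) ** 2))
    if k > 1:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (Q - (k - 1)) / c) if c > 0 else 0.0
    else:
        tau2 = 0.0
    wstar = 1.0 / (v + tau2)
    pooled = float(np.sum(wstar * y) / np.sum(wstar))
    se = float(1.0 / math.sqrt(np.sum(wstar)))
    return pooled, se, tau2, Q


def reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """Restricted-maximum-likelihood estimate of the between-study variance."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(y) < 2:
        return 0.0

    def neg_restricted_ll(tau2):
        wi = 1.0 / (v + tau2)
        mu = np.sum(wi * y) / np.sum(wi)
        return 0.5 * (
            np.sum(np.log(v + tau2))
            + math.log(np.sum(wi))
            + np.sum(wi * (y - mu) ** 2)
        )

    hi = max(float(np.var(y)), float(np.max(v))) * 10.0 + 1e-6
    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


@dataclass(frozen=True)
class PooledProportion:
    """Random-effects pooled proportion for one endpoint/regimen cell."""

    endpoint: str
    regimen: Optional[str]
    pooled_pct: float
    ci_pct: tuple[float, float]
    tau2: float
    k: int
    n_total: int
    transform: str = "logit"
    method: str = "dl"

    def formatted(self) -> str:
        lo, hi = self.ci_pct
        return f"{self.pooled_pct:.1f} ({lo:.1f}-{hi:.1f})"


def _transform(events, totals, transform):
    events = np.asarray(events, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if transform == "logit":
        boundary = (events == 0) | (events == totals)
        if boundary.any():
            warnings.warn(
                "boundary counts under logit transform: applying 0.5 "
                "continuity correction"
            )
            events = events + np.where(boundary, 0.5, 0.0)
            totals = totals + np.where(boundary, 1.0, 0.0)
        y = logit(events / totals)
        v = 1.0 / events + 1.0 / (totals - events)
    elif transform == "raw":
        p = events / totals
        y = p
        v = p * (1.0 - p) / totals
        v = np.maximum(v, 1.0 / (4.0 * totals**2))  # guard zero variance
    elif transform == "ft":
        # Freeman-Tukey double-arcsine
        y = 0.5 * (
            np.arcsin(np.sqrt(events / (totals + 1)))
            + np.arcsin(np.sqrt((events + 1) / (totals + 1)))
        )
        v = 1.0 / (4.0 * totals + 2.0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return y, v, totals


def _ft_inverse(t: float, n_harmonic: float) -> float:
    """Miller's inverse of the Freeman-Tukey double-arcsine transform."""
    t = min(max(t, 0.0), math.pi / 2.0)
    if t == 0.0:
        return 0.0
    s2t = math.sin(2.0 * t)
    inner = s2t + (s2t - 1.0 / s2t) / n_harmonic
    return 0.5 * (
        1.0
        - math.copysign(1.0, math.cos(2.0 * t))
        * math.sqrt(max(0.0, 1.0 - inner**2))
    )


def _back_transform(mu, lo, hi, transform, totals):
    if transform == "logit":
        vals = expit([mu, lo, hi])
    elif transform == "raw":
        vals = np.clip([mu, lo, hi], 0.0, 1.0)
    else:  # ft: Miller inverse with the harmonic mean of the arm sizes
        n_h = len(totals) / float(np.sum(1.0 / np.asarray(totals, dtype=float)))
        vals = [_ft_inverse(t, n_h) for t in (mu, lo, hi)]
    return [100.0 * float(x) for x in vals]


def pool_proportions(
    counts: Sequence[tuple[int, int]],
    transform: str = "logit",
    method: str = "dl",
    endpoint: str = "",
    regimen: Optional[str] = None,
) -> PooledProportion:
    """Pool per-arm (events, total) counts into one proportion with a 95% CI.

    ``transform``: "logit" (default), "raw", or "ft" (Freeman-Tukey);
    ``method``: "dl" (DerSimonian-Laird), "reml", or "fixed" (tau2 = 0).
    Boundary counts (0 or total) under the logit transform get a 0.5
    continuity correction with a warning.
    """
    events = [e for e, _t in counts]
    totals = [t for _e, t in counts]
    if any(t < 1 for t in totals) or any(not 0 <= e <= t for e, t in counts):
        raise ValueError("each arm needs total >= 1 and 0 <= events <= total")
    y, v, adj_totals = _transform(events, totals, transform)
    if method == "dl":
        pooled, se, tau2, _Q = dersimonian_laird(y, v)
    elif method == "reml":
        tau2 = reml_tau2(y, v)
        wstar = 1.0 / (v + tau2)
        pooled = float(np.sum(wstar * y) / np.sum(wstar))
        se = float(1.0 / math.sqrt(np.sum(wstar)))
    elif method == "fixed":
        w = 1.0 / v
        pooled = float(np.sum(w * y) / np.sum(w))
        se = float(1.0 / math.sqrt(np.sum(w)))
        tau2 = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    mu_pct, lo_pct, hi_pct = _back_transform(
        pooled, pooled - 1.96 * se, pooled + 1.96 * se, transform, adj_totals
    )
    return PooledProportion(
        endpoint=endpoint,
        regimen=regimen,
        pooled_pct=mu_pct,
        ci_pct=(lo_pct, hi_pct),
        tau2=tau2,
        k=len(counts),
        n_total=int(sum(totals)),
        transform=transform,
        method=method,
    )


def endpoint_report(
    dataset: Dataset,
    endpoints: Sequence[str] = ENDPOINTS,
    regimens: Sequence[str] = REGIMENS,
    transform: str = "logit",
    method: str = "dl",
) -> pd.DataFrame:
    """Pool every endpoint x regimen cell present in the dataset's counts.

    Returns a long table with one row per available cell; combinations with no
    counts are absent (not rendered as zero).
    """
    if dataset.counts is None:
        raise ValueError("dataset has no counts table")
    regimen_of = {a.arm_id: a.regimen for a in dataset.arms}
    counts = dataset.counts.copy()
    counts["regimen"] = counts["arm_id"].map(regimen_of)
    rows = []
    for endpoint in endpoints:
        for regimen in regimens:
            sub = counts[(counts["endpoint"] == endpoint)
                         & (counts["regimen"] == regimen)]
            if sub.empty:
                continue
            pooled = pool_proportions(
                list(zip(sub["events"].astype(int), sub["total"].astype(int))),
                transform=transform, method=method,
                endpoint=endpoint, regimen=regimen,
            )
            rows.append(
                {"endpoint": endpoint, "regimen": regimen,
                 "pooled_pct": pooled.pooled_pct,
                 "ci_lo_pct": pooled.ci_pct[0], "ci_hi_pct": pooled.ci_pct[1],
                 "tau2": pooled.tau2, "k": pooled.k, "n_total": pooled.n_total,
                 "formatted": pooled.formatted()}
            )
    return pd.DataFrame(
        rows,
        columns=["endpoint", "regimen", "pooled_pct", "ci_lo_pct", "ci_hi_pct",
                 "tau2", "k", "n_total", "formatted"],
    )


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long endpoint report into an endpoint x regimen grid."""
    return report.pivot(index="endpoint", columns="regimen", values="formatted")
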