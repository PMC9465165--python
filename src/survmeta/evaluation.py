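"""Goodness-of-fit, visual predictive check, and leave-one-out diagnostics."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, resolve_se
from .hazards import apply_covariates
from .nlme import FitResult, _predict_survival, fit_model

logger = logging.getLogger(__name__)

__all__ = ["VPCResult", "LOOResult", "visual_predictive_check", "goodness_of_fit",
           "leave_one_out"]


@dataclass
class VPCResult:
    """Pointwise simulation bands at the observed design, plus band coverage."""

    table: pd.DataFrame   # arm_id, regimen, time, n, obs, lo, med, hi, inside
    coverage: float
    n_sim: int

    def plot(self, path=None, by_regimen: bool = True):
        """Percentile-band VPC panels (one per regimen plus combined)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        tab = self.table
        regimens = list(tab["regimen"].unique()) if by_regimen else []
        panels = regimens + ["all"]
        fig, axes = plt.subplots(1, len(panels), figsize=(4 * len(panels), 3.5),
                                 squeeze=False)
        for ax, panel in zip(axes[0], panels):
            sub = tab if panel == "all" else tab[tab["regimen"] == panel]
            sub = sub.sort_values("time")
            grid = sub.groupby("time")[["lo", "med", "hi"]].median()
            ax.plot(grid.index, grid["med"], "k--", lw=1, label="simulated median")
            ax.plot(grid.index, grid["lo"], color="grey", lw=1)
            ax.plot(grid.index, grid["hi"], color="grey", lw=1)
            ax.scatter(sub["time"], sub["obs"].clip(0, 1),
                       s=4 + 40 * sub["n"] / max(sub["n"].max(), 1),
                       alpha=0.5, label="observed")
            ax.set_xlabel("time (months)")
            ax.set_ylabel("overall survival")
            ax.set_ylim(-0.02, 1.02)
            ax.set_title(panel)
        axes[0][0].legend(fontsize=7)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def visual_predictive_check(
    fit: FitResult,
    dataset: Dataset,
    n_sim: int = 1000,
    seed: Optional[int] = None,
) -> VPCResult:
    """Simulate the fitted model at the observed design and band the results.

    Each replicate draws one eta per arm from N(0, omega^2) and one residual
    per point from N(0, (SE * sigma_eps)^2); bands are the pointwise 2.5/50/
    97.5 percentiles across replicates (not truncated to [0, 1], so the band
    math stays faithful to the additive residual model).  Coverage is the
    fraction of observed points inside the 95% band.
    """
    if n_sim < 100:
        warnings.warn(f"n_sim={n_sim} < 100 gives unstable percentile bands")
    dataset = resolve_se(dataset)
    p = fit.params
    rng = np.random.default_rng(seed)
    rows = []
    for arm in dataset.arms:
        points = dataset.curves.get(arm.arm_id, ())
        if not points:
            continue
        t = np.array([pt.time for pt in points])
        obs = np.array([pt.survival_obs for pt in points])
        se = np.array([pt.se for pt in points])
        mean_beta = apply_covariates(p.spec.beta0, p.cov_model, arm.covariates(), 0.0)
        eta = (rng.normal(0.0, np.sqrt(p.omega2), size=n_sim)
               if p.omega2 > 0 else np.zeros(n_sim))
        beta_i = mean_beta * np.exp(eta)[:, None]
        pred = _predict_survival(p.spec.family, beta_i, p.spec.beta1, t[None, :])
        sims = pred + se[None, :] * p.sigma_eps * rng.standard_normal((n_sim, len(t)))
        lo, med, hi = np.percentile(sims, [2.5, 50.0, 97.5], axis=0)
        inside = (obs >= lo) & (obs <= hi)
        for j in range(len(t)):
            rows.append(
                {"arm_id": arm.arm_id, "regimen": arm.regimen, "time": t[j],
                 "n": arm.n, "obs": obs[j], "lo": lo[j], "med": med[j],
                 "hi": hi[j], "inside": bool(inside[j])}
            )
    table = pd.DataFrame(rows)
    coverage = float(table["inside"].mean())
    return VPCResult(table=table, coverage=coverage, n_sim=n_sim)


def goodness_of_fit(fit: FitResult, dataset: Dataset) -> pd.DataFrame:
    """Observation-level population/individual predictions and weighted residuals.

    Population predictions set eta = 0; individual predictions use the
    empirical-Bayes eta of the arm's fitting unit; the weighted residual is
    ``(obs - pred_individual) / (SE * sigma_eps)``.  One row per KM point.
    """
    dataset = resolve_se(dataset)
    p = fit.params
    rows = []
    for arm in dataset.arms:
        points = dataset.curves.get(arm.arm_id, ())
        if not points:
            continue
        unit_id = arm.study_id if fit.eta_level == "study" else arm.arm_id
        eta = fit.eta_hat.get(unit_id, 0.0)
        t = np.array([pt.time for pt in points])
        obs = np.array([pt.survival_obs for pt in points])
        se = np.array([pt.se for pt in points])
        beta_pop = apply_covariates(p.spec.beta0, p.cov_model, arm.covariates(), 0.0)
        beta_ind = beta_pop * np.exp(eta)
        pred_pop = _predict_survival(p.spec.family, beta_pop, p.spec.beta1, t)
        pred_ind = _predict_survival(p.spec.family, beta_ind, p.spec.beta1, t)
        wres = (obs - pred_ind) / (se * p.sigma_eps)
        for j in range(len(t)):
            rows.append(
                {"arm_id": arm.arm_id, "time": t[j], "obs": obs[j],
                 "pred_population": pred_pop[j], "pred_individual": pred_ind[j],
                 "weighted_residual": wres[j]}
            )
    return pd.DataFrame(rows)


@dataclass
class LOOResult:
    """Per-fold estimates and a min/median/max stability summary."""

    folds: pd.DataFrame
    summary: pd.DataFrame


def leave_one_out(
    dataset: Dataset,
    family: str = "constant",
    covariate_terms: Sequence[str] = (),
    by: str = "study",
    **fit_kwargs,
) -> LOOResult:
    """Refit the model with one study (or arm) held out at a time.

    Requires at least 3 units.  Covariate centering references are frozen at
    the full-dataset medians so every fold estimates the same parameters.
    Non-converging folds are flagged in the ``converged`` column, not dropped.
    """
    units = dataset.study_ids if by == "study" else dataset.arm_ids
    if len(units) < 3:
        raise ValueError(f"leave-one-out needs >= 3 {by} units, got {len(units)}")
    from .nlme import _dataset_medians

    refs = fit_kwargs.pop("covariate_refs", None)
    if refs is None and covariate_terms:
        refs = _dataset_medians(dataset, covariate_terms)
    rows = []
    for unit in units:
        if by == "study":
            fold_data = dataset.drop_study(unit)
        else:
            fold_data = dataset.subset(a for a in dataset.arm_ids if a != unit)
        fit = fit_model(
            fold_data, family=family, covariate_terms=covariate_terms,
            covariate_refs=refs, compute_covariance=False, **fit_kwargs,
        )
        if not fit.converged:
            logger.warning("fold dropping %s did not converge", unit)
        rows.append({"held_out": unit, "converged": fit.converged,
                     "ofv": fit.ofv, **fit.estimates})
    folds = pd.DataFrame(rows)
    param_cols = [c for c in folds.columns if c not in ("held_out", "converged", "ofv")]
    summary = folds[param_cols].agg(["min", "median", "max"]).T.reset_index(
        names="parameter")
    return LOOResult(folds=folds, summary=summary)
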