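"""Stepwise covariate screening on objective-function-value drops.

Forward inclusion repeatedly adds the candidate whose entry lowers the OFV
most, provided the drop clears the chi2(alpha=0.05, df=1) threshold of 3.84;
backward deletion then removes any retained term whose deletion raises the
OFV by less than the stricter chi2(alpha=0.01, df=1) threshold of 6.63,
until the model is stable.  Centering constants are frozen at the full-dataset
covariate medians before the first step and stored in the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from scipy.stats import chi2

from .data import COVARIATE_NAMES, Dataset
from .nlme import FitResult, fit_model, _dataset_medians

logger = logging.getLogger(__name__)

__all__ = ["SelectionStep", "SelectionTrace", "chi2_threshold", "stepwise_select"]


def chi2_threshold(alpha: float, df: int) -> float:
    """Upper-alpha quantile of the chi-squared distribution with ``df`` d.f."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(chi2.ppf(1.0 - alpha, df))


@dataclass(frozen=True)
class SelectionStep:
    direction: str          # "forward" | "backward"
    covariate: str
    delta_ofv: float
    accepted: bool
    note: str = ""


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    final_terms: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": i + 1,
                    "direction": s.direction,
                    "covariate": s.covariate,
                    "delta_ofv": s.delta_ofv,
                    "accepted": s.accepted,
                    "note": s.note,
                }
                for i, s in enumerate(self.steps)
            ],
            columns=["step", "direction", "covariate", "delta_ofv", "accepted", "note"],
        )


def stepwise_select(
    dataset: Dataset,
    candidates: Sequence[str] = COVARIATE_NAMES,
    forward_threshold: float = 3.84,
    backward_threshold: float = 6.63,
    family: str = "constant",
    **fit_kwargs,
) -> tuple[FitResult, SelectionTrace]:
    """Forward-inclusion / backward-deletion covariate selection on OFV.

    Candidates are screened in the fixed order given (ties on delta-OFV break
    toward the earlier candidate).  A refit failure during a step skips that
    candidate with a note in the trace.  Returns the refitted final model and
    the full trace.
    """
    unknown = set(candidates) - set(COVARIATE_NAMES)
    if unknown:
        raise ValueError(f"unknown candidate covariates {sorted(unknown)}")
    candidates = list(candidates)
    refs = fit_kwargs.pop("covariate_refs", None)
    if refs is None:
        refs = _dataset_medians(dataset, candidates)

    trace = SelectionTrace()

    def fit_terms(terms):
        return fit_model(
            dataset, family=family, covariate_terms=tuple(terms),
            covariate_refs={k: refs[k] for k in terms},
            compute_covariance=False, **fit_kwargs,
        )

    current_terms: list[str] = []
    current_fit = fit_terms(current_terms)

    # forward inclusion
    remaining = [c for c in candidates]
    while remaining:
        results = []
        for cand in remaining:
            try:
                fit = fit_terms(current_terms + [cand])
            except Exception as exc:
                trace.steps.append(
                    SelectionStep("forward", cand, float("nan"), False,
                                  f"refit failed: {exc}")
                )
                logger.warning("forward step for %s failed: %s", cand, exc)
                continue
            results.append((cand, current_fit.ofv - fit.ofv, fit))
        if not results:
            break
        best_cand, best_drop, best_fit = max(results, key=lambda r: r[1])
        for cand, drop, _fit in results:
            if cand != best_cand:
                trace.steps.append(SelectionStep("forward", cand, drop, False))
        accepted = best_drop >= forward_threshold
        trace.steps.append(SelectionStep("forward", best_cand, best_drop, accepted))
        if not accepted:
            break
        current_terms.append(best_cand)
        current_fit = best_fit
        remaining.remove(best_cand)

    # backward deletion: repeatedly drop the weakest term below the threshold
    stable = False
    while current_terms and not stable:
        results = []
        for term in current_terms:
            reduced = [t for t in current_terms if t != term]
            try:
                fit = fit_terms(reduced)
            except Exception as exc:
                trace.steps.append(
                    SelectionStep("backward", term, float("nan"), False,
                                  f"refit failed: {exc}")
                )
                logger.warning("backward step for %s failed: %s", term, exc)
                continue
            results.append((term, fit.ofv - current_fit.ofv, fit))
        if not results:
            break
        weakest, rise, reduced_fit = min(results, key=lambda r: r[1])
        if rise < backward_threshold:
            trace.steps.append(SelectionStep("backward", weakest, rise, True,
                                             "removed"))
            current_terms.remove(weakest)
            current_fit = reduced_fit
        else:
            for term, rise_t, _fit in results:
                trace.steps.append(SelectionStep("backward", term, rise_t, False,
                                                 "retained"))
            stable = True

    trace.final_terms = tuple(current_terms)
    # refit the final model with covariance for reporting
    final_fit = fit_model(
        dataset, family=family, covariate_terms=tuple(current_terms),
        covariate_refs={k: refs[k] for k in current_terms},
        **fit_kwargs,
    )
    return final_fit, trace
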