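"""Synthetic study-level datasets with the exact structure the analysis assumes.

The generator runs the analysis model forward: per arm it samples baseline
covariates and a sample size within the published per-regimen ranges, draws a
log-scale study effect eta ~ N(0, omega^2), forms the arm's hazard parameter
through the covariate model, evaluates the survival curve on a monthly grid
truncated at a sampled follow-up horizon, attaches binomial-rule standard
errors, and adds SE-weighted Gaussian residual noise.  Ground truth (the
generating parameters, every eta, and the pre-clip observations) is retained
so recovery tests can score the fitted estimates.

The default configuration reproduces the published study conditions: 17
studies contributing 20 arms (6 GV, 6 GD, 8 G), per-regimen covariate ranges
as published (notably the age-regimen confounding: GV arms enrol the youngest
and G arms the oldest cohorts), hazard truth beta0 = 0.098/month with age and
PS2 coefficients 0.017 and 0.004 centered at 72.5 years / 14%, omega = 0.146
and sigma_eps = 0.822.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, KMPoint, StudyArm
from .hazards import CovariateModel, CovariateTerm, HazardModelSpec, apply_covariates
from .nlme import PopulationParams, _predict_survival

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "TABLE1_RANGES",
    "TABLE1_OVERALL",
    "DEFAULT_TRUE_PROPORTIONS",
    "default_true_params",
    "generate_survival_dataset",
    "generate_count_data",
]

#: published per-regimen (min, max) ranges of the baseline summaries
TABLE1_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "GV": {
        "n": (20, 215), "age": (59.0, 65.0), "male_pct": (59.0, 86.0),
        "ps2_pct": (2.0, 26.0), "stage4_pct": (67.0, 93.0),
        "scc_pct": (21.0, 40.0), "adc_pct": (46.0, 55.0), "lcc_pct": (4.0, 10.5),
    },
    "GD": {
        "n": (19, 144), "age": (61.4, 76.0), "male_pct": (66.0, 90.0),
        "ps2_pct": (0.0, 19.6), "stage4_pct": (65.0, 100.0),
        "scc_pct": (12.0, 38.0), "adc_pct": (30.4, 58.0), "lcc_pct": (7.1, 16.0),
    },
    "G": {
        "n": (28, 122), "age": (72.0, 76.0), "male_pct": (57.0, 86.9),
        "ps2_pct": (20.5, 100.0), "stage4_pct": (61.9, 96.0),
        "scc_pct": (18.0, 50.0), "adc_pct": (27.4, 57.0), "lcc_pct": (4.9, 15.4),
    },
}

#: overall (min, max) bounds across regimens; config ranges must stay inside
TABLE1_OVERALL: dict[str, tuple[float, float]] = {
    "n": (19, 215), "age": (59.0, 76.0), "male_pct": (57.0, 90.0),
    "ps2_pct": (0.0, 100.0), "stage4_pct": (61.9, 100.0),
    "scc_pct": (12.0, 50.0), "adc_pct": (27.4, 58.0), "lcc_pct": (4.0, 21.0),
}

#: published pooled proportions used as generating truths (fractions)
DEFAULT_TRUE_PROPORTIONS: dict[str, dict[str, float]] = {
    "ORR": {"GV": 0.284, "GD": 0.285, "G": 0.138},
    "anemia": {"GV": 0.021, "GD": 0.051, "G": 0.047},
    "leukopenia": {"GV": 0.083, "GD": 0.150, "G": 0.116},
    "neutropenia": {"GV": 0.209, "GD": 0.164, "G": 0.187},
    "thrombocytopenia": {"GV": 0.030, "GD": 0.046, "G": 0.034},
    "nausea_vomiting": {"GV": 0.027, "GD": 0.026, "G": 0.036},
    "fatigue_asthenia": {"GV": 0.067, "GD": 0.093, "G": 0.033},
}


def default_true_params() -> PopulationParams:
    """Generating truth: the published final-model parameter values."""
    return PopulationParams(
        spec=HazardModelSpec("constant", 0.098),
        cov_model=CovariateModel(
            (CovariateTerm("age", 0.017, 72.5), CovariateTerm("ps2_pct", 0.004, 14.0))
        ),
        omega2=0.146**2,
        sigma_eps=0.822,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    ``seed`` is mandatory; everything else defaults to the published design.
    ``n_scale`` multiplies sampled arm sizes (a power knob for operating-
    characteristic studies; 1.0 reproduces the published sample-size range).
    ``stratify_covariates`` keeps the per-regimen covariate ranges (and hence
    the age-regimen confounding); switching it off samples every arm from the
    overall ranges.
    """

    seed: int
    n_studies: int = 17
    regimen_arms: Mapping[str, int] = field(
        default_factory=lambda: {"GV": 6, "GD": 6, "G": 8}
    )
    true_params: PopulationParams = field(default_factory=default_true_params)
    covariate_ranges: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {r: dict(v) for r, v in TABLE1_RANGES.items()}
    )
    grid_months: int = 36
    followup_range: tuple[int, int] = (12, 36)
    n_scale: float = 1.0
    stratify_covariates: bool = True
    eta_level: str = "arm"
    se_floor: float = 0.005

    def __post_init__(self) -> None:
        for regimen, ranges in self.covariate_ranges.items():
            for name, (lo, hi) in ranges.items():
                blo, bhi = TABLE1_OVERALL[name]
                if lo < blo - 1e-9 or hi > bhi + 1e-9 or lo > hi:
                    raise ValueError(
                        f"{regimen}/{name} range ({lo}, {hi}) outside the "
                        f"published bounds {TABLE1_OVERALL[name]}"
                    )
        total_arms = sum(self.regimen_arms.values())
        if total_arms < self.n_studies:
            raise ValueError("more studies than arms")


@dataclass
class SyntheticTruth:
    """Everything needed to recompute every noiseless curve and score a fit."""

    params: PopulationParams
    eta: dict[str, float]                      # per random-effect unit
    covariates: dict[str, dict[str, float]]    # per arm
    preclip_obs: dict[str, np.ndarray]         # per arm, before [0,1] clipping
    true_proportions: Optional[dict] = None

    def to_json(self) -> str:
        p = self.params
        return json.dumps(
            {
                "family": p.spec.family,
                "beta0": p.spec.beta0,
                "beta1": p.spec.beta1,
                "cov_terms": [
                    {"name": t.name, "theta": t.theta, "reference": t.reference}
                    for t in p.cov_model.terms
                ],
                "omega2": p.omega2,
                "sigma_eps": p.sigma_eps,
                "eta": self.eta,
                "covariates": self.covariates,
                "preclip_obs": {k: list(map(float, v))
                                for k, v in self.preclip_obs.items()},
                "true_proportions": self.true_proportions,
            },
            indent=1,
        )


def _sample_arm_covariates(rng, ranges) -> dict[str, float]:
    return {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()
            if name != "n"}


def generate_survival_dataset(
    config: GeneratorConfig,
) -> tuple[Dataset, SyntheticTruth]:
    """Generate arms and noisy KM curves by running the model forward.

    Deterministic given ``config.seed``; CSV exports of the same config are
    byte-identical.  Observations are clipped to [0, 1] only at emission; the
    truth record keeps the pre-clip values.
    """
    rng = np.random.default_rng(config.seed)
    p = config.true_params
    arm_specs: list[str] = []
    for regimen in ("GV", "GD", "G"):
        arm_specs += [regimen] * int(config.regimen_arms.get(regimen, 0))

    # 20 arms over 17 studies: the surplus arms attach as second arms to the
    # first studies, pairing different regimens where possible
    n_arms = len(arm_specs)
    n_extra = n_arms - config.n_studies
    study_of: list[str] = []
    for i in range(config.n_studies):
        study_of.append(f"S{i + 1:02d}")
    extra_hosts = list(range(n_extra))
    # interleave regimens round-robin so multi-arm studies mix regimens
    by_reg: dict[str, list[int]] = {}
    for i, r in enumerate(arm_specs):
        by_reg.setdefault(r, []).append(i)
    rr: list[int] = []
    while any(by_reg.values()):
        for r in ("GV", "GD", "G"):
            if by_reg.get(r):
                rr.append(by_reg[r].pop(0))

    arms: list[StudyArm] = []
    curves: dict[str, tuple[KMPoint, ...]] = {}
    eta_map: dict[str, float] = {}
    cov_map: dict[str, dict[str, float]] = {}
    preclip: dict[str, np.ndarray] = {}

    omega = math.sqrt(p.omega2)
    for slot, arm_idx in enumerate(rr):
        regimen = arm_specs[arm_idx]
        arm_id = f"A{slot + 1:02d}"
        study_id = (study_of[slot] if slot < config.n_studies
                    else study_of[extra_hosts[slot - config.n_studies]])
        ranges = (config.covariate_ranges[regimen]
                  if config.stratify_covariates else TABLE1_OVERALL)
        covs = _sample_arm_covariates(rng, ranges)
        n_lo, n_hi = config.covariate_ranges[regimen].get("n", TABLE1_OVERALL["n"])
        n = int(round(rng.integers(int(n_lo), int(n_hi) + 1) * config.n_scale))
        arm = StudyArm(
            study_id=study_id, arm_id=arm_id, regimen=regimen, n=n,
            age_median=covs["age"], male_pct=covs["male_pct"],
            ps2_pct=covs["ps2_pct"], stage4_pct=covs["stage4_pct"],
            scc_pct=covs["scc_pct"], adc_pct=covs["adc_pct"],
            lcc_pct=covs["lcc_pct"],
        )
        unit_id = study_id if config.eta_level == "study" else arm_id
        if unit_id not in eta_map:
            eta_map[unit_id] = float(rng.normal(0.0, omega)) if omega > 0 else 0.0
        eta = eta_map[unit_id]
        beta_i = apply_covariates(p.spec.beta0, p.cov_model, covs, eta)
        horizon = int(rng.integers(config.followup_range[0],
                                   config.followup_range[1] + 1))
        t = np.arange(1.0, horizon + 1.0)
        s_true = _predict_survival(p.spec.family, beta_i, p.spec.beta1, t)
        se = np.maximum(np.sqrt(s_true * (1.0 - s_true) / n), config.se_floor)
        z = rng.standard_normal(len(t))
        obs_raw = s_true + se * p.sigma_eps * z
        # clip to [0, 1] only at emission; non-monotone wiggles are left in,
        # mimicking digitization noise (read_dataset repairs them on ingest)
        obs = np.clip(obs_raw, 0.0, 1.0)
        arms.append(arm)
        curves[arm_id] = tuple(
            KMPoint(float(tj), float(oj), float(sj))
            for tj, oj, sj in zip(t, obs, se)
        )
        cov_map[arm_id] = covs
        preclip[arm_id] = obs_raw

    dataset = Dataset(tuple(arms), curves, None)
    truth = SyntheticTruth(params=p, eta=eta_map, covariates=cov_map,
                           preclip_obs=preclip)
    return dataset, truth


def generate_count_data(
    arms: Sequence[StudyArm],
    true_proportions: Optional[Mapping[str, Mapping[str, float]]] = None,
    heterogeneity_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-arm endpoint counts from a logit-normal / binomial hierarchy.

    Each arm's endpoint-level proportion is drawn on the logit scale around the
    regimen's true value with ``heterogeneity_sd``, then the event count is
    binomial in the arm's sample size.  Deterministic given ``seed``.
    """
    props = true_proportions or DEFAULT_TRUE_PROPORTIONS
    for endpoint, per_reg in props.items():
        for regimen, p0 in per_reg.items():
            if not 0.0 < p0 < 1.0:
                raise ValueError(
                    f"true proportion for {endpoint}/{regimen} must lie in "
                    f"(0, 1), got {p0}"
                )
    rng = np.random.default_rng(seed)
    rows = []
    for endpoint, per_reg in props.items():
        for arm in arms:
            if arm.regimen not in per_reg:
                continue
            p0 = per_reg[arm.regimen]
            logit_p = math.log(p0 / (1.0 - p0)) + rng.normal(0.0, heterogeneity_sd)
            p_arm = 1.0 / (1.0 + math.exp(-logit_p))
            events = int(rng.binomial(arm.n, p_arm))
            rows.append({"arm_id": arm.arm_id, "endpoint": endpoint,
                         "events": events, "total": arm.n})
    return pd.DataFrame(rows, columns=["arm_id", "endpoint", "events", "total"])
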