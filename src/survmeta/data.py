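"""Data model and CSV I/O for study-level treatment arms and aggregate KM curves.

The unit of observation is a published treatment arm: its baseline covariates
(Table-1-style summaries) plus overall-survival probabilities digitized from a
Kaplan-Meier figure at a set of time points, optionally with standard errors.
Endpoint count tables (responders / grade 3-4 adverse events) ride along for
the proportion meta-analysis.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "REGIMENS",
    "COVARIATE_NAMES",
    "ENDPOINTS",
    "DatasetError",
    "StudyArm",
    "KMPoint",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "resolve_se",
]

REGIMENS = ("GV", "GD", "G")

#: covariate names usable in the hazard model, in the fixed screening order
COVARIATE_NAMES = (
    "age",
    "male_pct",
    "ps2_pct",
    "stage4_pct",
    "scc_pct",
    "adc_pct",
    "lcc_pct",
)

ENDPOINTS = (
    "ORR",
    "anemia",
    "leukopenia",
    "neutropenia",
    "thrombocytopenia",
    "nausea_vomiting",
    "fatigue_asthenia",
)

_ARM_COLUMNS = [
    "study_id",
    "arm_id",
    "regimen",
    "n",
    "age_median",
    "male_pct",
    "ps2_pct",
    "stage4_pct",
    "scc_pct",
    "adc_pct",
    "lcc_pct",
]
_CURVE_COLUMNS = ["arm_id", "time_months", "survival", "se"]
_COUNT_COLUMNS = ["arm_id", "endpoint", "events", "total"]

#: default floor on the standard error of a digitized survival probability,
#: so points at S in {0, 1} do not receive infinite weight
DEFAULT_SE_FLOOR = 0.005


class DatasetError(ValueError):
    """Malformed or inconsistent study-level input data."""


@dataclass(frozen=True)
class StudyArm:
    """One treatment arm with its sample size and baseline covariates."""

    study_id: str
    arm_id: str
    regimen: str
    n: int
    age_median: float
    male_pct: float
    ps2_pct: float
    stage4_pct: float
    scc_pct: float
    adc_pct: float
    lcc_pct: float

    def __post_init__(self) -> None:
        if self.regimen not in REGIMENS:
            raise DatasetError(
                f"arm {self.arm_id!r}: unknown regimen {self.regimen!r}; "
                f"expected one of {REGIMENS}"
            )
        if self.n < 1:
            raise DatasetError(f"arm {self.arm_id!r}: sample size must be >= 1")
        for name in COVARIATE_NAMES[1:]:
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise DatasetError(
                    f"arm {self.arm_id!r}: {name}={value} outside [0, 100]"
                )

    def covariates(self) -> dict[str, float]:
        """Covariate values keyed by the model's covariate names."""
        out = {"age": self.age_median}
        for name in COVARIATE_NAMES[1:]:
            out[name] = getattr(self, name)
        return out


@dataclass(frozen=True)
class KMPoint:
    """One digitized (time, survival) observation, optionally with its SE."""

    time: float
    survival_obs: float
    se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DatasetError(f"KM point time {self.time} is negative")
        if not 0.0 <= self.survival_obs <= 1.0:
            raise DatasetError(
                f"KM survival {self.survival_obs} outside [0, 1] at t={self.time}"
            )
        if self.se is not None and not self.se > 0:
            raise DatasetError(f"KM point SE must be positive, got {self.se}")


@dataclass(frozen=True)
class Dataset:
    """Validated collection of arms, their KM curves and optional count tables."""

    arms: tuple[StudyArm, ...]
    curves: dict[str, tuple[KMPoint, ...]]
    counts: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        ids = [a.arm_id for a in self.arms]
        if len(set(ids)) != len(ids):
            raise DatasetError(f"duplicate arm ids: {sorted(ids)}")
        known = set(ids)
        for arm_id, points in self.curves.items():
            if arm_id not in known:
                raise DatasetError(f"curve references unknown arm {arm_id!r}")
            times = [p.time for p in points]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise DatasetError(
                    f"arm {arm_id!r}: times must be strictly increasing"
                )
        if self.counts is not None:
            missing = set(_COUNT_COLUMNS) - set(self.counts.columns)
            if missing:
                raise DatasetError(f"counts table missing columns {sorted(missing)}")
            bad = ~self.counts["arm_id"].isin(known)
            if bad.any():
                raise DatasetError(
                    f"counts reference unknown arms {sorted(self.counts.loc[bad, 'arm_id'].unique())}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def arm_ids(self) -> tuple[str, ...]:
        return tuple(a.arm_id for a in self.arms)

    @property
    def study_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for a in self.arms:
            if a.study_id not in seen:
                seen.append(a.study_id)
        return tuple(seen)

    def arm(self, arm_id: str) -> StudyArm:
        for a in self.arms:
            if a.arm_id == arm_id:
                return a
        raise KeyError(arm_id)

    def curve(self, arm_id: str) -> tuple[KMPoint, ...]:
        return self.curves[arm_id]

    @property
    def n_obs(self) -> int:
        return sum(len(c) for c in self.curves.values())

    def subset(self, arm_ids: Iterable[str]) -> "Dataset":
        keep = set(arm_ids)
        arms = tuple(a for a in self.arms if a.arm_id in keep)
        curves = {k: v for k, v in self.curves.items() if k in keep}
        counts = None
        if self.counts is not None:
            counts = self.counts[self.counts["arm_id"].isin(keep)].reset_index(drop=True)
        return Dataset(arms, curves, counts)

    def drop_study(self, study_id: str) -> "Dataset":
        return self.subset(a.arm_id for a in self.arms if a.study_id != study_id)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, Optional[pd.DataFrame]]:
        arms_df = pd.DataFrame([vars(a) for a in self.arms], columns=_ARM_COLUMNS)
        rows = []
        for arm_id in self.arm_ids:
            for p in self.curves.get(arm_id, ()):
                rows.append(
                    {
                        "arm_id": arm_id,
                        "time_months": p.time,
                        "survival": p.survival_obs,
                        "se": np.nan if p.se is None else p.se,
                    }
                )
        curves_df = pd.DataFrame(rows, columns=_CURVE_COLUMNS)
        return arms_df, curves_df, self.counts


def _repair_monotone(points: list[KMPoint], arm_id: str) -> tuple[list[KMPoint], int]:
    """Cap each survival value at the running minimum (digitization repair)."""
    repaired: list[KMPoint] = []
    run_min = 1.0
    n_fixed = 0
    for p in points:
        s = p.survival_obs
        if s > run_min + 1e-12:
            s = run_min
            n_fixed += 1
            repaired.append(KMPoint(p.time, s, p.se))
        else:
            repaired.append(p)
        run_min = min(run_min, s)
    if n_fixed:
        logger.info("arm %r: clipped %d non-monotone survival point(s)",
                    arm_id, n_fixed)
    return repaired, n_fixed


def read_dataset(
    arm_table_path,
    curve_table_path,
    counts_table_path=None,
) -> Dataset:
    """Read and validate the arms/curves (and optional counts) CSV tables.

    Digitized curves that are non-monotone by a small margin are repaired by
    isotonic clipping with a warning; survival outside [0, 1] is an error that
    names the offending file and row.
    """
    arms_df = pd.read_csv(arm_table_path, float_precision="round_trip")
    missing = set(_ARM_COLUMNS) - set(arms_df.columns)
    if missing:
        raise DatasetError(f"{arm_table_path}: missing columns {sorted(missing)}")
    arms = []
    for idx, row in arms_df.iterrows():
        try:
            arms.append(
                StudyArm(
                    study_id=str(row["study_id"]),
                    arm_id=str(row["arm_id"]),
                    regimen=str(row["regimen"]),
                    n=int(row["n"]),
                    **{name2: float(row[name2]) for name2 in _ARM_COLUMNS[4:]},
                )
            )
        except (DatasetError, ValueError) as exc:
            raise DatasetError(f"{arm_table_path}, row {idx}: {exc}") from exc

    curves_df = pd.read_csv(curve_table_path, float_precision="round_trip")
    missing = set(_CURVE_COLUMNS) - set(curves_df.columns) - {"se"}
    if missing:
        raise DatasetError(f"{curve_table_path}: missing columns {sorted(missing)}")
    if "se" not in curves_df.columns:
        curves_df["se"] = np.nan
    curves: dict[str, tuple[KMPoint, ...]] = {}
    n_repaired = 0
    for arm_id, group in curves_df.groupby("arm_id", sort=False):
        group = group.sort_values("time_months")
        points = []
        for idx, row in group.iterrows():
            try:
                se = None if pd.isna(row["se"]) else float(row["se"])
                points.append(
                    KMPoint(float(row["time_months"]), float(row["survival"]), se)
                )
            except (DatasetError, ValueError) as exc:
                raise DatasetError(f"{curve_table_path}, row {idx}: {exc}") from exc
        repaired, n_fixed = _repair_monotone(points, str(arm_id))
        n_repaired += n_fixed
        curves[str(arm_id)] = tuple(repaired)
    if n_repaired:
        warnings.warn(
            f"{curve_table_path}: clipped {n_repaired} non-monotone survival "
            "point(s) to the running minimum (digitization repair)",
            stacklevel=2,
        )

    counts = None
    if counts_table_path is not None:
        counts = pd.read_csv(counts_table_path)
        missing = set(_COUNT_COLUMNS) - set(counts.columns)
        if missing:
            raise DatasetError(f"{counts_table_path}: missing columns {sorted(missing)}")
        for idx, row in counts.iterrows():
            if not 0 <= row["events"] <= row["total"]:
                raise DatasetError(
                    f"{counts_table_path}, row {idx}: events must lie in [0, total]"
                )
    return Dataset(tuple(arms), curves, counts)


def write_dataset(
    dataset: Dataset,
    arm_table_path,
    curve_table_path,
    counts_table_path=None,
) -> None:
    """Write a dataset back to the CSV dialects `read_dataset` accepts."""
    arms_df, curves_df, counts = dataset.to_frames()
    arms_df.to_csv(arm_table_path, index=False)
    curves_df.to_csv(curve_table_path, index=False)
    if counts_table_path is not None:
        if counts is None:
            raise DatasetError("dataset has no counts table to write")
        counts.to_csv(counts_table_path, index=False)


def resolve_se(dataset: Dataset, se_floor: float = DEFAULT_SE_FLOOR) -> Dataset:
    """Fill in missing KM standard errors with the binomial approximation.

    Where a point's SE is absent it becomes ``max(sqrt(S*(1-S)/n), se_floor)``
    using the arm's sample size; reported SEs are authoritative and untouched.
    Idempotent.
    """
    curves: dict[str, tuple[KMPoint, ...]] = {}
    for arm_id, points in dataset.curves.items():
        n = dataset.arm(arm_id).n
        resolved = []
        for p in points:
            if p.se is None:
                se = max(math.sqrt(p.survival_obs * (1.0 - p.survival_obs) / n), se_floor)
                resolved.append(KMPoint(p.time, p.survival_obs, se))
            else:
                resolved.append(p)
        curves[arm_id] = tuple(resolved)
    return Dataset(dataset.arms, curves, dataset.counts)
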