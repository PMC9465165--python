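"""End-to-end pipeline: simulate/ingest, fit, select, evaluate, summarize.

All randomness flows from a single master seed: `numpy.random.SeedSequence`
children are spawned in a fixed stage order (simulate, counts, vpc, subgroup,
regimen), so running stages one at a time reproduces a full run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .data import Dataset, read_dataset, write_dataset
from .evaluation import goodness_of_fit, leave_one_out, visual_predictive_check
from .nlme import FitResult, compare_families
from .propmeta import endpoint_report, format_report
from .selection import stepwise_select
from .simulate import GeneratorConfig, generate_count_data, generate_survival_dataset
from .subgroups import regimen_table, subgroup_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_stage", "STAGES"]

STAGES = ("simulate", "fit", "select", "vpc", "loo", "subgroup", "meta", "report")

#: fixed spawn order of per-stage seeds off the master seed
_SEED_CHILDREN = ("simulate", "counts", "vpc", "subgroup", "regimen")


@dataclass
class PipelineConfig:
    """Resolved configuration for a pipeline run (YAML/JSON loadable)."""

    seed: int = 0
    # input CSVs; when absent, data are simulated
    arms_csv: Optional[str] = None
    curves_csv: Optional[str] = None
    counts_csv: Optional[str] = None
    simulate: bool = True
    family: str = "auto"               # "auto" compares the three families
    candidates: Sequence[str] = ("age", "male_pct", "ps2_pct", "stage4_pct",
                                 "scc_pct", "adc_pct", "lcc_pct")
    forward_threshold: float = 3.84
    backward_threshold: float = 6.63
    n_sim: int = 1000                  # VPC replicates
    n_draws: int = 10000               # Monte Carlo parameter draws
    se_floor: float = 0.005
    eta_level: str = "arm"
    transform: str = "logit"
    tau_method: str = "dl"
    family_criterion: str = "lrt"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["candidates"] = list(self.candidates)
        return d


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(_SEED_CHILDREN))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(_SEED_CHILDREN, children)
    }


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _require(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise StageError(
            stage, f"missing prerequisite artifact {path.name!r}; run the "
            f"{producer!r} stage first"
        )
    return path


def _load_dataset(config: PipelineConfig, out: Path, stage: str) -> Dataset:
    if config.simulate:
        arms = _require(out / "arms.csv", stage, "simulate")
        curves = _require(out / "curves.csv", stage, "simulate")
        counts = out / "counts.csv"
    else:
        if not config.arms_csv or not config.curves_csv:
            raise StageError(stage, "config must give arms_csv and curves_csv "
                                    "when simulate is false")
        arms, curves = Path(config.arms_csv), Path(config.curves_csv)
        counts = Path(config.counts_csv) if config.counts_csv else Path("missing")
    return read_dataset(arms, curves, counts if counts.exists() else None)


def _load_fit(out: Path, stage: str) -> FitResult:
    path = _require(out / "fit.json", stage, "select")
    return FitResult.from_dict(json.loads(path.read_text()))


def run_stage(config: PipelineConfig, stage: str, out_dir) -> None:
    """Run one pipeline stage with file-based hand-off in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    if stage == "simulate":
        gen = GeneratorConfig(seed=seeds["simulate"], se_floor=config.se_floor,
                              eta_level=config.eta_level)
        dataset, truth = generate_survival_dataset(gen)
        counts = generate_count_data(dataset.arms, seed=seeds["counts"])
        dataset = Dataset(dataset.arms, dataset.curves, counts)
        write_dataset(dataset, out / "arms.csv", out / "curves.csv",
                      out / "counts.csv")
        (out / "truth.json").write_text(truth.to_json())
        return

    if stage == "fit":
        dataset = _load_dataset(config, out, stage)
        if config.family == "auto":
            table = compare_families(dataset, criterion=config.family_criterion,
                                     se_floor=config.se_floor,
                                     eta_level=config.eta_level)
            table.to_csv(out / "families.csv", index=False)
            family = str(table.loc[0, "family"])
        else:
            family = config.family
        (out / "family.txt").write_text(family + "\n")
        return

    if stage == "select":
        dataset = _load_dataset(config, out, stage)
        family_file = _require(out / "family.txt", stage, "fit")
        family = family_file.read_text().strip()
        fit, trace = stepwise_select(
            dataset, candidates=tuple(config.candidates),
            forward_threshold=config.forward_threshold,
            backward_threshold=config.backward_threshold,
            family=family, se_floor=config.se_floor, eta_level=config.eta_level,
        )
        trace.to_frame().to_csv(out / "selection_trace.csv", index=False)
        (out / "fit.json").write_text(json.dumps(fit.to_dict(), indent=1))
        (out / "parameter_table.txt").write_text(fit.summary() + "\n")
        return

    if stage == "vpc":
        dataset = _load_dataset(config, out, stage)
        fit = _load_fit(out, stage)
        vpc = visual_predictive_check(fit, dataset, n_sim=config.n_sim,
                                      seed=seeds["vpc"])
        vpc.table.to_csv(out / "vpc.csv", index=False)
        vpc.plot(out / "vpc.png")
        gof = goodness_of_fit(fit, dataset)
        gof.to_csv(out / "gof.csv", index=False)
        return

    if stage == "loo":
        dataset = _load_dataset(config, out, stage)
        fit = _load_fit(out, stage)
        terms = tuple(t.name for t in fit.params.cov_model.terms)
        refs = {t.name: t.reference for t in fit.params.cov_model.terms}
        loo = leave_one_out(dataset, family=fit.family, covariate_terms=terms,
                            covariate_refs=refs, se_floor=config.se_floor,
                            eta_level=config.eta_level)
        loo.folds.to_csv(out / "loo_folds.csv", index=False)
        loo.summary.to_csv(out / "loo_summary.csv", index=False)
        return

    if stage == "subgroup":
        dataset = _load_dataset(config, out, stage)
        fit = _load_fit(out, stage)
        sub = subgroup_table(fit, n_draws=config.n_draws, seed=seeds["subgroup"])
        sub.to_csv(out / "subgroups.csv", index=False)
        reg = regimen_table(fit, dataset, n_draws=config.n_draws,
                            seed=seeds["regimen"])
        reg.to_csv(out / "regimens.csv", index=False)
        return

    if stage == "meta":
        dataset = _load_dataset(config, out, stage)
        if dataset.counts is None:
            raise StageError(stage, "no counts table available")
        report = endpoint_report(dataset, transform=config.transform,
                                 method=config.tau_method)
        report.to_csv(out / "proportions.csv", index=False)
        format_report(report).to_csv(out / "proportions_grid.csv")
        return

    if stage == "report":
        lines = [
            "# Aggregate-survival meta-analysis report",
            "",
            f"survmeta version: {__version__}",
            "",
            "## Resolved configuration",
            "```yaml",
            yaml.safe_dump(config.to_dict(), sort_keys=False).strip(),
            "```",
            "",
            "## Stage seeds",
            "```json",
            json.dumps(seeds, indent=1),
            "```",
            "",
            "## Artifacts",
        ]
        for name in sorted(f.name for f in out.iterdir() if f.is_file()):
            if name != "report.md":
                lines.append(f"- {name}")
        table_path = out / "parameter_table.txt"
        if table_path.exists():
            lines += ["", "## Final model parameters", "```",
                      table_path.read_text().rstrip(), "```"]
        (out / "report.md").write_text("\n".join(lines) + "\n")
        return

    raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute every stage in order; halts with the stage name on failure.

    On failure a ``manifest.json`` listing the artifacts produced so far is
    written before the error propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES)
    if not config.simulate:
        stages.remove("simulate")
    for stage in stages:
        try:
            run_stage(config, stage, out)
        except Exception as exc:
            manifest = {
                "failed_stage": stage,
                "error": str(exc),
                "artifacts": sorted(f.name for f in out.iterdir() if f.is_file()),
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            if isinstance(exc, StageError):
                raise
            raise StageError(stage, str(exc)) from exc
    (out / "manifest.json").write_text(json.dumps(
        {"failed_stage": None,
         "artifacts": sorted(f.name for f in out.iterdir() if f.is_file())},
        indent=1))
    return out
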