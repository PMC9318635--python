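"""End-to-end orchestration: data -> features -> selection -> model -> report.

One config drives the whole flow for each requested day stage: build the
stage's feature dataset, split 70/30, select a feature subset by RFE-CV on
the training portion, train the forest on it, evaluate on the held-out
30%, and run fivefold CV over the stage dataset.  A run manifest records
the config hash, derived per-stage seeds, instance counts, and the
selected subsets, so runs are reproducible and comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io as aio
from .errors import ActimindError
from .evaluation import EvaluationReport, evaluate_model, kfold_cv
from .features import DayStageDataset, build_feature_table
from .model import ForestConfig, train_forest
from .preprocessing import DAY_STAGES, segment_hourly, split_train_test, standardize_by_group
from .selection import rfe_cv
from .synthetic import GROUP_NAMES, SyntheticCohortSpec, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)

_GROUP_BY_NAME = {name: g for g, name in GROUP_NAMES.items()}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across processes)."""
    return (zlib.crc32(stage.encode()) ^ seed) % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; exactly one input mode."""

    input_mode: str = "synthetic"  # "synthetic" | "csv-dirs"
    synthetic: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)
    control_dir: str | None = None
    depression_dir: str | None = None
    schizophrenia_dir: str | None = None
    standardize: str = "per-class"
    stages: Sequence[str] = DAY_STAGES
    train_fraction: float = 0.7
    split_level: str = "segment"
    forest: ForestConfig = field(default_factory=ForestConfig)
    selection_folds: int = 5
    selection_step: int = 1
    selection_tolerance: float = 0.001
    rfe_n_trees: int | None = 100
    cv_folds: int = 5
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "csv-dirs"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        unknown = set(self.stages) - set(DAY_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            syn = dict(raw["synthetic"])
            for key in ("class_amplitude", "night_floor", "zero_inflation_night"):
                if key in syn:
                    syn[key] = {
                        _GROUP_BY_NAME.get(k, k): float(v) for k, v in syn[key].items()
                    }
            raw["synthetic"] = SyntheticCohortSpec(**syn)
        if "forest" in raw and isinstance(raw["forest"], dict):
            raw["forest"] = ForestConfig(**raw["forest"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        return out


@dataclass(frozen=True)
class StageOutcome:
    """Everything the pipeline computed for one day stage."""

    report: EvaluationReport
    selection: object
    n_segments: int
    n_train: int
    n_test: int


def _load_cohort(config: RunConfig):
    if config.input_mode == "synthetic":
        spec = replace(config.synthetic, seed=stage_seed(config.seed, "cohort"))
        return generate_cohort(spec)
    manifest = aio.manifest_from_dirs(
        control_dir=config.control_dir,
        depression_dir=config.depression_dir,
        schizophrenia_dir=config.schizophrenia_dir,
    )
    return aio.assemble_cohort(manifest)


def _restrict(dataset: DayStageDataset, names: Sequence[str]) -> DayStageDataset:
    return DayStageDataset(
        stage=dataset.stage,
        X=dataset.X.loc[:, list(names)],
        y=dataset.y,
        meta=dataset.meta,
    )


def run_pipeline(config: RunConfig) -> tuple[dict[str, EvaluationReport], dict]:
    """Run the full flow; returns per-stage reports and the run manifest."""
    cohort = _load_cohort(config)
    standardized, params = standardize_by_group(cohort, mode=config.standardize)
    segments = segment_hourly(standardized)

    reports: dict[str, EvaluationReport] = {}
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_subjects": len(cohort),
        "standardization": {
            "mode": params.mode,
            "mean": {str(k): v for k, v in params.mean.items()},
            "sd": {str(k): v for k, v in params.sd.items()},
        },
        "stages": {},
    }

    for stage in config.stages:
        try:
            s_seed = stage_seed(config.seed, stage)
            stage_segments = [s for s in segments if s.stage == stage]
            dataset = build_feature_table(stage_segments, stage)
            train, test = split_train_test(
                dataset, config.train_fraction, seed=s_seed, level=config.split_level
            )
            forest = replace(config.forest, seed=s_seed)
            selection = rfe_cv(
                train,
                forest,
                cv_folds=config.selection_folds,
                step=config.selection_step,
                seed=s_seed,
                tolerance=config.selection_tolerance,
                rfe_n_trees=config.rfe_n_trees,
                revalidate=False,
            )
            selected = selection.selected_feature_names
            model = train_forest(_restrict(train, selected), forest)
            cv = kfold_cv(_restrict(dataset, selected), forest, k=config.cv_folds, seed=s_seed)
            report = evaluate_model(model, _restrict(test, selected), cv=cv)
            reports[stage] = report
            manifest["stages"][stage] = {
                "seed": s_seed,
                "n_segments": dataset.n,
                "n_train": train.n,
                "n_test": test.n,
                "selected_features": list(selected),
                "n_selected": selection.n_selected,
                "cv_overall_accuracy": cv.overall,
                "test_accuracy": report.accuracy,
                "mcc": report.mcc,
            }
        except ActimindError as exc:
            raise ActimindError(f"stage {stage!r} failed: {exc}") from exc

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for stage, report in reports.items():
            stage_dir = outdir / stage
            stage_dir.mkdir(exist_ok=True)
            report.to_json(stage_dir / "report.json")
            np.savetxt(
                stage_dir / "confusion.csv",
                np.asarray(report.confusion.counts),
                fmt="%d",
                delimiter=",",
            )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return reports, manifest
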