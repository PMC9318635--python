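"""Standardization, hourly segmentation, day-stage tagging, and splitting.

Raw counts are z-scored per diagnostic class (the pipeline's default,
matching how the reference analysis pools each class before scaling), then
cut into complete clock-hour rows of 60 standardized counts tagged with one
of four day stages: night 00:00-05:59, morning 06:00-11:59, afternoon
12:00-17:59, evening 18:00-23:59.

Per-class standardization consults the group label and therefore leaks
label information into the features; ``mode="global"`` and
``mode="per-subject"`` are the leakage-free alternatives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SplitError
from .synthetic import GROUPS, SubjectRecording

__all__ = [
    "DAY_STAGES",
    "SEGMENT_LENGTH",
    "HourlySegment",
    "StandardizationParams",
    "assign_day_stage",
    "standardize_by_group",
    "segment_hourly",
    "split_train_test",
]

logger = logging.getLogger(__name__)

DAY_STAGES = ("night", "morning", "afternoon", "evening")
SEGMENT_LENGTH = 60

StandardizeMode = Literal["per-class", "global", "per-subject"]


def assign_day_stage(hour: int) -> str:
    """Map a clock hour to its day stage (night/morning/afternoon/evening)."""
    if not 0 <= hour <= 23:
        raise ValueError(f"hour {hour} outside [0, 23]")
    return DAY_STAGES[hour // 6]


@dataclass(frozen=True)
class StandardizationParams:
    """Per-group mean and sample standard deviation of raw activity counts.

    Keys are group labels for per-class mode, subject ids for per-subject
    mode, or the single key ``"all"`` for global mode.
    """

    mode: str
    mean: dict
    sd: dict

    def __post_init__(self) -> None:
        for key, s in self.sd.items():
            if not s > 0:
                raise DegenerateDataError(f"zero variance for {key!r}")


@dataclass(frozen=True)
class HourlySegment:
    """Sixty standardized counts for one (subject, date, clock hour)."""

    subject_id: str
    date: str
    hour: int
    stage: str
    label: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != SEGMENT_LENGTH:
            raise ValueError(f"segment must hold {SEGMENT_LENGTH} values")
        if assign_day_stage(self.hour) != self.stage:
            raise ValueError(f"stage {self.stage!r} inconsistent with hour {self.hour}")


def _zscore(values: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return (values - mu) / sd


def standardize_by_group(
    cohort: Sequence[SubjectRecording],
    mode: StandardizeMode = "per-class",
) -> tuple[list[SubjectRecording], StandardizationParams]:
    """Z-score activity counts; returns the transformed cohort and params.

    In the default per-class mode mu and sigma are the mean and sample
    standard deviation of all counts pooled within each diagnostic class,
    so each class's pooled standardized values have mean 0 and sample sd 1
    exactly.  Ordering and timestamps are untouched.
    """
    if not cohort:
        raise DegenerateDataError("empty cohort")

    def stats(values: np.ndarray, what: str) -> tuple[float, float]:
        if len(values) < 2 or np.ptp(values) == 0:
            raise DegenerateDataError(f"{what}: needs >= 2 distinct values")
        return float(values.mean()), float(values.std(ddof=1))

    mean: dict = {}
    sd: dict = {}
    if mode == "per-class":
        for g in sorted({rec.group for rec in cohort}):
            pooled = np.concatenate(
                [rec.data["activity"].to_numpy(float) for rec in cohort if rec.group == g]
            )
            mean[g], sd[g] = stats(pooled, f"group {g}")
        key = lambda rec: rec.group
    elif mode == "global":
        pooled = np.concatenate([rec.data["activity"].to_numpy(float) for rec in cohort])
        mean["all"], sd["all"] = stats(pooled, "cohort")
        key = lambda rec: "all"
    elif mode == "per-subject":
        for rec in cohort:
            mean[rec.subject_id], sd[rec.subject_id] = stats(
                rec.data["activity"].to_numpy(float), f"subject {rec.subject_id}"
            )
        key = lambda rec: rec.subject_id
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")

    params = StandardizationParams(mode=mode, mean=mean, sd=sd)
    out = []
    for rec in cohort:
        k = key(rec)
        frame = rec.data.copy()
        frame["activity"] = _zscore(frame["activity"].to_numpy(float), mean[k], sd[k])
        out.append(replace(rec, data=frame, standardized=True))
    return out, params


def segment_hourly(cohort: Sequence[SubjectRecording]) -> list[HourlySegment]:
    """Cut recordings into complete clock-hour segments of 60 counts.

    Hours covered by fewer than 60 samples (interrupted recording, partial
    first/last hour) are dropped; the dropped count is logged.
    """
    segments: list[HourlySegment] = []
    dropped = 0
    for rec in cohort:
        ts = pd.to_datetime(rec.data["timestamp"])
        frame = pd.DataFrame(
            {
                "date": ts.dt.strftime("%Y-%m-%d"),
                "hour": ts.dt.hour,
                "activity": rec.data["activity"].to_numpy(),
            }
        )
        for (date, hour), block in frame.groupby(["date", "hour"], sort=True):
            if len(block) != SEGMENT_LENGTH:
                dropped += 1
                continue
            segments.append(
                HourlySegment(
                    subject_id=rec.subject_id,
                    date=str(date),
                    hour=int(hour),
                    stage=assign_day_stage(int(hour)),
                    label=rec.group,
                    values=block["activity"].to_numpy(float),
                )
            )
    if dropped:
        logger.info("segment_hourly: dropped %d incomplete hour(s)", dropped)
    return segments


def split_train_test(dataset, train_fraction: float, seed: int, level: str = "segment"):
    """Partition a day-stage dataset into disjoint, exhaustive train/test.

    Segment level (default) shuffles rows and takes
    ``floor(train_fraction * n)`` for training.  Subject level keeps all of
    a subject's segments on one side, splitting subjects within each class.
    """
    if not 0.0 < train_fraction < 1.0:
        raise SplitError("train_fraction must lie strictly between 0 and 1")
    n = dataset.n
    if n == 0:
        raise SplitError("empty dataset")
    rng = np.random.default_rng(seed)

    if level == "segment":
        order = rng.permutation(n)
        n_train = math.floor(train_fraction * n)
        return dataset.subset(order[:n_train]), dataset.subset(order[n_train:])

    if level == "subject":
        subjects = dataset.meta["subject_id"].to_numpy()
        labels = np.asarray(dataset.y)
        train_subjects: set[str] = set()
        for g in np.unique(labels):
            group_subjects = np.unique(subjects[labels == g])
            if len(group_subjects) < 2:
                raise SplitError(f"class {g}: need >= 2 subjects for a subject-level split")
            order = rng.permutation(len(group_subjects))
            n_train = max(1, min(len(group_subjects) - 1,
                                 math.floor(train_fraction * len(group_subjects))))
            train_subjects.update(group_subjects[order[:n_train]])
        mask = np.isin(subjects, sorted(train_subjects))
        return dataset.subset(np.flatnonzero(mask)), dataset.subset(np.flatnonzero(~mask))

    raise ValueError(f"unknown split level {level!r}")
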