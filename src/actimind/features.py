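"""Statistical feature extraction from hourly activity segments.

Each 60-value standardized segment is reduced to 23 time-domain statistics:
location (mean, sum, max, min, median), spread (sample sd, variance, mean
absolute deviation, standard error of the mean), eleven positional
quantiles (deciles 10-90 plus quartiles 25/75 and the 50% point), shape
(skewness and non-excess kurtosis, both normalized by the sample sd), and
the distinct-value count.

Quantiles use the positional (n+1) convention: the p-quantile is the value
at position ``h = p * (n + 1)``, linearly interpolated between order
statistics and clamped to the extremes when h falls outside [1, n].  This
differs from the more common ``h = 1 + p * (n - 1)`` convention.  Under it
the median and the 50% quantile coincide by construction, so two of the 23
columns are perfectly collinear; both are kept to preserve the published
feature contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError
from .preprocessing import HourlySegment

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "DayStageDataset",
    "positional_quantile",
    "extract_features",
    "feature_values",
    "build_feature_table",
]

#: fixed, versioned column order; selection masks and saved models
#: reference features by these names
FEATURE_NAMES = (
    "mean",
    "sum",
    "max",
    "min",
    "median",
    "sd",
    "quantile10",
    "quantile20",
    "quantile25",
    "quantile30",
    "quantile40",
    "quantile50",
    "quantile60",
    "quantile70",
    "quantile75",
    "quantile80",
    "quantile90",
    "kurtosis",
    "mad",
    "sem",
    "skewness",
    "variance",
    "unique",
)

_QUANTILE_LEVELS = {
    "quantile10": 0.10,
    "quantile20": 0.20,
    "quantile25": 0.25,
    "quantile30": 0.30,
    "quantile40": 0.40,
    "quantile50": 0.50,
    "quantile60": 0.60,
    "quantile70": 0.70,
    "quantile75": 0.75,
    "quantile80": 0.80,
    "quantile90": 0.90,
}


def positional_quantile(values: Sequence[float], p: float) -> float:
    """Quantile at position ``p * (n + 1)`` with linear interpolation.

    Positions below 1 clamp to the minimum and above n to the maximum.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("positional_quantile of empty input")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    h = p * (n + 1)
    if h <= 1.0:
        return float(x[0])
    if h >= n:
        return float(x[-1])
    lo = math.floor(h)
    frac = h - lo
    return float(x[lo - 1] + frac * (x[lo] - x[lo - 1]))


def feature_values(values: Sequence[float]) -> np.ndarray:
    """The 23 statistics of one segment, ordered as FEATURE_NAMES.

    Moments are normalized by the sample standard deviation (denominator
    n - 1); skewness and kurtosis of a zero-variance segment are defined
    as 0 so that all-zero night hours still yield complete rows.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    mean = x.mean()
    dev = x - mean
    sd = x.std(ddof=1) if n > 1 else 0.0
    if sd > 0:
        skewness = float(np.mean(dev**3) / sd**3)
        kurtosis = float(np.mean(dev**4) / sd**4)
    else:
        skewness = 0.0
        kurtosis = 0.0
    out = {
        "mean": float(mean),
        "sum": float(x.sum()),
        "max": float(x.max()),
        "min": float(x.min()),
        "median": positional_quantile(x, 0.5),
        "sd": float(sd),
        "kurtosis": kurtosis,
        "mad": float(np.mean(np.abs(dev))),
        "sem": float(sd / math.sqrt(n)),
        "skewness": skewness,
        "variance": float(sd**2),
        "unique": float(len(np.unique(x))),
    }
    for name, p in _QUANTILE_LEVELS.items():
        out[name] = positional_quantile(x, p)
    return np.array([out[name] for name in FEATURE_NAMES])


@dataclass(frozen=True)
class FeatureVector:
    """The 23 segment statistics plus segment metadata and label."""

    subject_id: str
    date: str
    hour: int
    stage: str
    label: int
    values: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def extract_features(segment: HourlySegment) -> FeatureVector:
    """Compute the statistics of one hourly segment."""
    return FeatureVector(
        subject_id=segment.subject_id,
        date=segment.date,
        hour=segment.hour,
        stage=segment.stage,
        label=segment.label,
        values=feature_values(segment.values),
    )


@dataclass(frozen=True)
class DayStageDataset:
    """Feature matrix, labels, and segment metadata for one day stage."""

    stage: str
    X: pd.DataFrame
    y: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.meta):
            raise ValueError("feature matrix, labels and metadata must align")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)

    def subset(self, indices) -> "DayStageDataset":
        idx = np.asarray(indices)
        return DayStageDataset(
            stage=self.stage,
            X=self.X.iloc[idx].reset_index(drop=True),
            y=np.asarray(self.y)[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        """Metadata columns, label, then the feature columns in fixed order."""
        frame = self.meta.copy()
        frame["stage"] = self.stage
        frame["label"] = self.y
        return pd.concat([frame, self.X], axis=1)


def build_feature_table(segments: Iterable[HourlySegment], stage: str) -> DayStageDataset:
    """Assemble the feature dataset for one day stage.

    All segments must already carry the requested stage; mixed input is an
    error naming the offending segments.
    """
    segments = list(segments)
    if not segments:
        raise EmptyDatasetError(f"no segments for stage {stage!r}")
    offending = [
        f"{s.subject_id}/{s.date}/h{s.hour:02d}" for s in segments if s.stage != stage
    ]
    if offending:
        raise ValueError(
            f"segments not in stage {stage!r}: {', '.join(offending[:5])}"
            + ("..." if len(offending) > 5 else "")
        )
    rows = np.vstack([feature_values(s.values) for s in segments])
    return DayStageDataset(
        stage=stage,
        X=pd.DataFrame(rows, columns=list(FEATURE_NAMES)),
        y=np.array([s.label for s in segments]),
        meta=pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in segments],
                "date": [s.date for s in segments],
                "hour": [s.hour for s in segments],
            }
        ),
    )
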