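"""Random-forest multiclass classifier with the fixed study configuration.

The classifier is a 900-tree forest in which every tree sees the entire
training set (no bootstrap), a node needs at least 3 samples to split, a
leaf at least 6 samples, and trees are capped at 90 leaf nodes.  With
bootstrapping off, the only randomness left is the per-split feature
subsampling (sqrt of the feature count, the conventional default), so
retraining under a different seed perturbs predictions only mildly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import DataError, SchemaError
from .features import DayStageDataset

__all__ = ["ForestConfig", "TrainedModel", "train_forest", "predict", "predict_proba",
           "save_model", "load_model"]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters; defaults are the study configuration."""

    n_trees: int = 900
    min_samples_to_split_node: int = 3
    min_samples_at_leaf: int = 6
    max_leaf_nodes_per_tree: int = 90
    bootstrap: bool = False
    max_features: str | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "min_samples_to_split_node",
                     "min_samples_at_leaf", "max_leaf_nodes_per_tree"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")

    def to_estimator(self, n_jobs: int = 1) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            min_samples_split=self.min_samples_to_split_node,
            min_samples_leaf=self.min_samples_at_leaf,
            max_leaf_nodes=self.max_leaf_nodes_per_tree,
            bootstrap=self.bootstrap,
            max_features=self.max_features,
            random_state=self.seed,
            n_jobs=n_jobs,
        )


@dataclass(frozen=True)
class TrainedModel:
    """A fitted forest plus the feature names and classes it was trained on."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    classes: tuple[int, ...]
    config: ForestConfig


def train_forest(train: DayStageDataset, config: ForestConfig) -> TrainedModel:
    """Fit the forest on a day-stage training dataset.

    Deterministic given ``config.seed``.  Missing feature values or
    single-class labels abort before any fitting.
    """
    if train.X.isna().any().any():
        raise DataError("training features contain missing values")
    labels = np.unique(train.y)
    if len(labels) < 2:
        raise DataError("training data must contain at least 2 classes")
    estimator = config.to_estimator()
    estimator.fit(train.X.to_numpy(), np.asarray(train.y))
    return TrainedModel(
        estimator=estimator,
        feature_names=tuple(train.X.columns),
        classes=tuple(int(c) for c in estimator.classes_),
        config=config,
    )


def _align(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Reorder columns by name to the training order; mismatch is an error."""
    if set(features.columns) != set(model.feature_names):
        raise SchemaError(
            f"feature columns {sorted(features.columns)} do not match "
            f"model features {sorted(model.feature_names)}"
        )
    return features.loc[:, list(model.feature_names)].to_numpy()


def predict(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Class label per row; ties in the vote resolve to the lowest class."""
    if len(features) == 0:
        _align(model, features)
        return np.array([], dtype=int)
    return model.estimator.predict(_align(model, features)).astype(int)


def predict_proba(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Per-class scores (mean leaf class frequencies); rows sum to 1."""
    if len(features) == 0:
        _align(model, features)
        return np.empty((0, len(model.classes)))
    return model.estimator.predict_proba(_align(model, features))


def save_model(model: TrainedModel, path: Path | str) -> None:
    joblib.dump(model, path)


def load_model(path: Path | str) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise DataError(f"{path} does not contain a trained model")
    return model
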