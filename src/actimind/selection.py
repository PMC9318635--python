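"""Recursive feature elimination with cross-validated accuracy (RFE-CV).

Starting from the full feature set, the forest is fitted and the `step`
least important features (impurity-based importance) are dropped,
repeating down to a single feature.  The elimination path is walked
independently inside each stratified CV fold, scoring the held-out part
at every visited subset size; keeping the ranking inside the training
folds avoids the selection bias that inflates the accuracy curve when
features are ranked on the full dataset.  The returned subset — taken
from an elimination path over the full dataset at the chosen size — is
the smallest whose mean CV accuracy is within a small tolerance of the
best observed, preferring parsimony over marginal accuracy.

The elimination loop may use a lighter forest than the final study
configuration for tractability; the chosen subset is then re-validated
under the full configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .errors import StratificationError
from .features import DayStageDataset
from .model import ForestConfig

__all__ = ["SelectionResult", "rfe_cv"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    """Chosen feature subset for one day stage plus the CV accuracy path."""

    stage: str
    selected_feature_names: tuple[str, ...]
    cv_accuracy_by_subset_size: dict[int, float]
    n_selected: int
    #: CV accuracy of the selected subset under the full forest configuration
    selected_cv_accuracy: float | None = None


def _mean_cv_accuracy(X, y, estimator, splitter) -> float:
    return float(np.mean(cross_val_score(estimator, X, y, cv=splitter, scoring="accuracy")))


def rfe_cv(
    dataset: DayStageDataset,
    estimator_config: ForestConfig,
    cv_folds: int = 5,
    step: int = 1,
    seed: int = 0,
    tolerance: float = 0.001,
    rfe_n_trees: int | None = 100,
    revalidate: bool = True,
) -> SelectionResult:
    """Select a day stage's feature subset by recursive elimination.

    ``rfe_n_trees`` caps the forest size inside the elimination loop
    (None: use ``estimator_config`` unchanged).  ``tolerance`` is the
    absolute accuracy slack for "as good as the best subset".
    Deterministic given ``seed``.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    y = np.asarray(dataset.y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("need at least 2 classes for selection")
    if counts.min() < cv_folds:
        raise StratificationError(
            f"every class needs >= {cv_folds} segments for {cv_folds}-fold CV"
        )

    loop_config = (
        estimator_config if rfe_n_trees is None
        else replace(estimator_config, n_trees=rfe_n_trees)
    )
    loop_config = replace(loop_config, seed=seed)
    splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)

    X_all = dataset.X.to_numpy()
    n_features = X_all.shape[1]

    def walk(train_idx, test_idx=None):
        """One elimination path; yields (size, held-out accuracy or None)."""
        current = list(range(n_features))
        scores: dict[int, float | None] = {}
        while True:
            estimator = loop_config.to_estimator()
            estimator.fit(X_all[np.ix_(train_idx, current)], y[train_idx])
            if test_idx is None:
                scores[len(current)] = None
            else:
                scores[len(current)] = float(
                    estimator.score(X_all[np.ix_(test_idx, current)], y[test_idx])
                )
            if len(current) == 1:
                return scores, current
            n_drop = min(step, len(current) - 1)
            drop = set(np.argsort(estimator.feature_importances_, kind="stable")[:n_drop])
            current = [i for j, i in enumerate(current) if j not in drop]

    # accuracy curve: elimination rerun inside every fold, scored held-out
    fold_scores: list[dict[int, float]] = []
    for train_idx, test_idx in splitter.split(X_all, y):
        scores, _ = walk(train_idx, test_idx)
        fold_scores.append(scores)
    accuracy_path = {
        size: float(np.mean([s[size] for s in fold_scores]))
        for size in fold_scores[0]
    }

    # feature subsets per size come from an elimination path on all data
    subsets: dict[int, tuple[str, ...]] = {}
    current = list(range(n_features))
    while True:
        subsets[len(current)] = tuple(dataset.feature_names[i] for i in current)
        if len(current) == 1:
            break
        estimator = loop_config.to_estimator()
        estimator.fit(X_all[:, current], y)
        n_drop = min(step, len(current) - 1)
        drop = set(np.argsort(estimator.feature_importances_, kind="stable")[:n_drop])
        current = [i for j, i in enumerate(current) if j not in drop]

    best = max(accuracy_path.values())
    n_selected = min(size for size, acc in accuracy_path.items() if acc >= best - tolerance)
    selected = subsets[n_selected]
    logger.info(
        "rfe_cv[%s]: selected %d/%d features (cv acc %.4f, best %.4f)",
        dataset.stage, n_selected, len(dataset.feature_names),
        accuracy_path[n_selected], best,
    )

    selected_cv_accuracy = None
    if revalidate:
        full_config = replace(estimator_config, seed=seed)
        selected_cv_accuracy = _mean_cv_accuracy(
            dataset.X.loc[:, list(selected)].to_numpy(), y,
            full_config.to_estimator(), splitter,
        )

    # report the subset in the dataset's canonical column order
    canonical = tuple(f for f in dataset.feature_names if f in selected)
    return SelectionResult(
        stage=dataset.stage,
        selected_feature_names=canonical,
        cv_accuracy_by_subset_size=accuracy_path,
        n_selected=n_selected,
        selected_cv_accuracy=selected_cv_accuracy,
    )
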