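import numpy as np
import pandas as pd
import pytest

from actimind.features import FEATURE_NAMES, DayStageDataset
from actimind.preprocessing import segment_hourly, standardize_by_group
from actimind.synthetic import SyntheticCohortSpec, generate_cohort
from actimind.features import build_feature_table


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticCohortSpec(n_per_class=3, n_days=2, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_night_dataset(tiny_cohort):
    standardized, _ = standardize_by_group(tiny_cohort)
    segments = [s for s in segment_hourly(standardized) if s.stage == "night"]
    return build_feature_table(segments, "night")


def make_random_dataset(n, seed, n_classes=3, stage="night", informative=()):
    """Random 23-column dataset; labels depend only on `informative` columns
    (empty: labels are pure noise)."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, len(FEATURE_NAMES))), columns=list(FEATURE_NAMES))
    y = rng.integers(0, n_classes, size=n)
    if informative:
        # carve well-separated class blobs into the informative columns
        for col in informative:
            X[col] = rng.normal(loc=3.0 * y, scale=0.5)
    meta = pd.DataFrame(
        {
            "subject_id": [f"s{i % 12:02d}" for i in range(n)],
            "date": "2020-01-06",
            "hour": 1,
        }
    )
    return DayStageDataset(stage=stage, X=X, y=y, meta=meta)


@pytest.fixture(scope="session")
def separable_dataset():
    """600 segments whose labels are fully determined by 3 feature columns."""
    return make_random_dataset(600, seed=21, informative=("min", "quantile10", "quantile25"))
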