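"""Per-class z-scoring, hourly segmentation, day stages, train/test splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actimind.errors import DegenerateDataError, SplitError
from actimind.features import build_feature_table
from actimind.preprocessing import (
    assign_day_stage,
    segment_hourly,
    split_train_test,
    standardize_by_group,
)
from actimind.synthetic import SubjectRecording, SyntheticCohortSpec, generate_cohort

from .conftest import make_random_dataset


def make_recording(values, subject_id="s0", group=0, start="2020-01-06 00:00:00"):
    ts = pd.date_range(start, periods=len(values), freq="min")
    return SubjectRecording(
        subject_id=subject_id,
        group=group,
        data=pd.DataFrame({"timestamp": ts, "activity": np.asarray(values)}),
    )


class TestAssignDayStage:
    @pytest.mark.parametrize(
        "hour,stage",
        [(0, "night"), (5, "night"), (6, "morning"), (11, "morning"),
         (12, "afternoon"), (17, "afternoon"), (18, "evening"), (23, "evening")],
    )
    def test_stage_boundaries(self, hour, stage):
        assert assign_day_stage(hour) == stage

    @pytest.mark.parametrize("hour", [-1, 24])
    def test_out_of_range(self, hour):
        with pytest.raises(ValueError):
            assign_day_stage(hour)


class TestStandardizeByGroup:
    def test_hand_computed_zscores(self):
        rec = make_recording([2, 4, 6])
        out, params = standardize_by_group([rec])
        np.testing.assert_allclose(out[0].data["activity"].to_numpy(), [-1.0, 0.0, 1.0])
        assert params.mean[0] == 4.0
        assert params.sd[0] == 2.0

    def test_idempotent_on_already_standard_values(self):
        values = np.array([-1.0, 0.0, 1.0])  # mean 0, sample sd 1
        rec = SubjectRecording(
            subject_id="s0", group=0, standardized=True,
            data=pd.DataFrame(
                {"timestamp": pd.date_range("2020-01-06", periods=3, freq="min"),
                 "activity": values}
            ),
        )
        out, _ = standardize_by_group([rec])
        np.testing.assert_allclose(out[0].data["activity"].to_numpy(), values, atol=1e-9)

    def test_per_group_mean_zero_sd_one_pooled_unconstrained(self, tiny_cohort):
        out, _ = standardize_by_group(tiny_cohort)
        pooled = []
        for g in (0, 1, 2):
            vals = np.concatenate(
                [r.data["activity"].to_numpy() for r in out if r.group == g]
            )
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std(ddof=1) - 1.0) < 1e-9
            pooled.append(vals)
        # groups built with different raw means: per-group means are 0 but a
        # differently-scaled mixture need not pool to sd exactly 1
        assert abs(np.concatenate(pooled).mean()) < 1e-9

    def test_conserves_sample_count_and_order(self, tiny_cohort):
        out, _ = standardize_by_group(tiny_cohort)
        assert sum(r.n_samples for r in out) == sum(r.n_samples for r in tiny_cohort)
        for a, b in zip(out, tiny_cohort):
            assert a.data["timestamp"].equals(b.data["timestamp"])

    def test_zero_variance_group_rejected(self):
        rec = make_recording([5, 5, 5])
        with pytest.raises(DegenerateDataError):
            standardize_by_group([rec])

    @pytest.mark.parametrize("mode", ["global", "per-subject"])
    def test_alternative_modes(self, tiny_cohort, mode):
        out, params = standardize_by_group(tiny_cohort, mode=mode)
        assert params.mode == mode
        pooled = np.concatenate([r.data["activity"].to_numpy() for r in out])
        if mode == "global":
            assert abs(pooled.mean()) < 1e-9
            assert abs(pooled.std(ddof=1) - 1.0) < 1e-9
        else:
            for r in out:
                assert abs(r.data["activity"].mean()) < 1e-9

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=3, max_size=60)
           .filter(lambda v: len(set(v)) > 1))
    @settings(derandomize=True, max_examples=50)
    def test_order_preserving_affine_map(self, values):
        out, _ = standardize_by_group([make_recording(values)])
        z = out[0].data["activity"].to_numpy()
        assert np.array_equal(np.argsort(np.asarray(values), kind="stable"),
                              np.argsort(z, kind="stable"))


class TestSegmentHourly:
    def test_two_complete_days_give_48_segments(self):
        rec = make_recording(np.arange(2 * 1440))
        segments = segment_hourly([rec])
        assert len(segments) == 48
        stages = {s.stage for s in segments}
        assert stages == {"night", "morning", "afternoon", "evening"}

    def test_partial_first_hour_dropped(self):
        rec = make_recording(np.arange(120), start="2020-01-06 06:30:00")
        hours = {s.hour for s in segment_hourly([rec])}
        assert 6 not in hours
        assert 7 in hours

    def test_segment_values_contiguous_in_source(self):
        values = np.arange(1440)
        segments = segment_hourly([make_recording(values)])
        for s in segments:
            start = s.hour * 60
            np.testing.assert_array_equal(s.values, values[start : start + 60])

    def test_synthetic_cohort_segment_count(self):
        cohort = generate_cohort(SyntheticCohortSpec(n_per_class=3, n_days=13, seed=1))
        segments = segment_hourly(cohort)
        assert len(segments) == 9 * 13 * 24 == 2808

    def test_stage_totals_sum_to_all_complete_hours(self, tiny_cohort):
        segments = segment_hourly(tiny_cohort)
        per_stage = {stage: 0 for stage in ("night", "morning", "afternoon", "evening")}
        for s in segments:
            per_stage[s.stage] += 1
        assert sum(per_stage.values()) == len(segments) == 9 * 2 * 24


class TestSplitTrainTest:
    def test_8738_rows_split_6116_2622(self):
        ds = make_random_dataset(8738, seed=0)
        train, test = split_train_test(ds, 0.7, seed=1)
        assert (train.n, test.n) == (6116, 2622)

    def test_disjoint_and_exhaustive(self):
        ds = make_random_dataset(10, seed=0)
        ds = ds.subset(np.arange(10))
        train, test = split_train_test(ds, 0.7, seed=3)
        assert (train.n, test.n) == (7, 3)
        # tag rows through a unique feature value to check the partition
        ids = set(train.X["mean"]).union(test.X["mean"])
        assert len(ids) == 10

    def test_deterministic_under_seed(self):
        ds = make_random_dataset(100, seed=5)
        a = split_train_test(ds, 0.7, seed=11)
        b = split_train_test(ds, 0.7, seed=11)
        c = split_train_test(ds, 0.7, seed=12)
        assert a[0].X.equals(b[0].X)
        assert not a[0].X.equals(c[0].X)

    def test_subject_level_keeps_subjects_together(self):
        ds = make_random_dataset(120, seed=9)
        train, test = split_train_test(ds, 0.7, seed=2, level="subject")
        overlap = set(train.meta["subject_id"]) & set(test.meta["subject_id"])
        assert not overlap
        assert train.n + test.n == 120

    def test_subject_level_needs_two_subjects_per_class(self):
        ds = make_random_dataset(30, seed=3)
        meta = ds.meta.copy()
        meta["subject_id"] = "only_one"
        ds = type(ds)(stage=ds.stage, X=ds.X, y=ds.y, meta=meta)
        with pytest.raises(SplitError):
            split_train_test(ds, 0.7, seed=0, level="subject")

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2])
    def test_bad_fraction(self, fraction):
        ds = make_random_dataset(10, seed=0)
        with pytest.raises(SplitError):
            split_train_test(ds, fraction, seed=0)
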