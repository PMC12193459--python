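"""Resampling, encoding, outlier handling and tiered imputation."""

import numpy as np
import pandas as pd
import pytest

from hemexpand.preprocess import (
    EmptySubjectError,
    FeatureMatrix,
    PipelineFailureError,
    PreprocessPipeline,
    UnknownCategoryError,
    clean_outliers,
    one_hot,
    resample_hourly,
    tiered_impute,
)
from hemexpand.schema import FeatureDef


def make_events(rows):
    base = pd.Timestamp("2120-01-01")
    return pd.DataFrame(
        {
            "subject_id": [r[0] for r in rows],
            "hadm_id": [r[0] + 100 for r in rows],
            "charttime": [base + pd.Timedelta(hours=r[1]) for r in rows],
            "item": [r[2] for r in rows],
            "value": [r[3] for r in rows],
        }
    )


def make_demo(subjects, **extra):
    base = pd.Timestamp("2120-01-01")
    data = {"subject_id": subjects, "admittime": [base] * len(subjects)}
    data.update(extra)
    return pd.DataFrame(data)


SIMPLE_FEATURES = [
    FeatureDef("hr", "continuous", 20, 250),
    FeatureDef("drug", "binary"),
]


class TestResampleHourly:
    def test_last_observation_wins_within_hour(self):
        events = make_events([(1, 0.2, "hr", 70.0), (1, 0.8, "hr", 90.0)])
        fm = resample_hourly(events, make_demo([1]), SIMPLE_FEATURES, duration=2)
        assert fm.frame.loc[(1, 0), "hr"] == 90.0
        assert np.isnan(fm.frame.loc[(1, 1), "hr"])

    def test_fully_absent_feature_has_missing_rate_one(self):
        events = make_events([(1, 0.5, "drug", 1.0)])
        fm = resample_hourly(events, make_demo([1]), SIMPLE_FEATURES, duration=72)
        assert fm.missing_rates["hr"] == 1.0

    def test_half_open_final_bin(self):
        events = make_events([(1, 71.5, "hr", 80.0), (1, 0.0, "hr", 70.0)])
        fm = resample_hourly(events, make_demo([1]), SIMPLE_FEATURES, duration=72)
        assert fm.frame.loc[(1, 71), "hr"] == 80.0

    def test_medication_presence_flag(self):
        events = make_events([(1, 3.5, "drug", 1.0), (1, 0.1, "hr", 75.0)])
        fm = resample_hourly(events, make_demo([1]), SIMPLE_FEATURES, duration=6)
        drug = fm.frame["drug"].to_numpy()
        np.testing.assert_array_equal(drug, [0, 0, 0, 1, 0, 0])

    def test_empty_subject_error(self):
        events = make_events([(1, 0.5, "hr", 80.0)])
        with pytest.raises(EmptySubjectError):
            resample_hourly(events, make_demo([1, 2]), SIMPLE_FEATURES, duration=4)


class TestOneHot:
    adm = FeatureDef("adm", "categorical", categories=("A", "B", "C"))
    sex = FeatureDef("sex", "categorical", categories=("F", "M"))

    def test_indicators_sum_to_one(self):
        frame = pd.DataFrame({"adm": ["A", "C", "B", "A"]})
        out, defs = one_hot(frame, [self.adm])
        assert list(out.columns) == ["adm=A", "adm=B", "adm=C"]
        np.testing.assert_array_equal(out.sum(axis=1).to_numpy(), np.ones(4))

    def test_binary_with_drop_first(self):
        frame = pd.DataFrame({"sex": ["F", "M", "F"]})
        out, _ = one_hot(frame, [self.sex])
        assert out.shape[1] == 2
        out_dropped, _ = one_hot(frame, [self.sex], drop_first=True)
        assert list(out_dropped.columns) == ["sex=M"]

    def test_missing_category_routes_to_imputation(self):
        frame = pd.DataFrame({"adm": ["A", None, "B"]})
        out, _ = one_hot(frame, [self.adm])
        assert out.loc[1].isna().all()
        assert not out.loc[0].isna().any()

    def test_unseen_category(self):
        frame = pd.DataFrame({"adm": ["A", "Z"]})
        with pytest.raises(UnknownCategoryError):
            one_hot(frame, [self.adm])
        out, _ = one_hot(frame, [self.adm], unseen="other")
        assert out.loc[1, "adm=__other__"] == 1.0


def frame_from_columns(n_subjects, n_hours, columns):
    idx = pd.MultiIndex.from_product(
        [range(n_subjects), range(n_hours)], names=["subject_id", "hour"]
    )
    return pd.DataFrame(columns, index=idx)


class TestTieredImputation:
    def test_low_missing_median(self):
        """A sparsely missing feature is filled with the training median (3
        for observed values drawn from {1, 2, 4, 100})."""
        vals = np.array([1.0, 2.0, 4.0, 100.0] * 10 + [np.nan])
        fm = FeatureMatrix(
            frame_from_columns(41, 1, {"x": vals}),
            [FeatureDef("x", "continuous")],
        )
        out, audit = tiered_impute(fm)
        assert out.frame["x"].iloc[-1] == 3.0
        assert (audit["step"] == "median_imputed").any()

    def test_high_missing_dropped_and_logged(self, rng):
        vals = rng.normal(size=100)
        vals[:30] = np.nan
        fm = FeatureMatrix(
            frame_from_columns(100, 1, {"x": vals, "y": rng.normal(size=100)}),
            [FeatureDef("x", "continuous"), FeatureDef("y", "continuous")],
        )
        out, audit = tiered_impute(fm)
        assert "x" not in out.frame.columns
        assert (audit["step"] == "dropped_high_missing").any()

    def test_whitelisted_high_missing_kept(self, rng):
        vals = rng.normal(size=100)
        vals[:30] = np.nan
        fm = FeatureMatrix(
            frame_from_columns(100, 1, {"x": vals, "y": rng.normal(size=100)}),
            [FeatureDef("x", "continuous"), FeatureDef("y", "continuous")],
        )
        out, audit = tiered_impute(fm, whitelist=["x"])
        assert "x" in out.frame.columns
        assert not out.frame["x"].isna().any()

    def test_knn_tier_uses_similar_patients(self, rng):
        """10%-missing feature: imputed values come from the K nearest
        patients and stay within the range of their observed values."""
        n, T = 30, 10
        level = np.repeat(rng.uniform(-2, 2, n), T)  # patient-specific level
        ref = level + rng.normal(0, 0.05, n * T)  # complete reference feature
        target = 5.0 + level + rng.normal(0, 0.05, n * T)
        # one staggered missing hour per patient -> exactly 10% missing
        patients, hours = np.arange(n * T) // T, np.arange(n * T) % T
        target[hours == patients % T] = np.nan
        fm = FeatureMatrix(
            frame_from_columns(n, T, {"ref": ref, "tgt": target}),
            [FeatureDef("ref", "continuous"), FeatureDef("tgt", "continuous")],
        )
        pipe = PreprocessPipeline(fm.features).fit(fm)
        assert pipe.state["tgt"].tier == "knn"
        out = pipe.transform(fm)
        filled = out.frame["tgt"].to_numpy().reshape(n, T)[np.arange(n), np.arange(n) % T]
        # neighbours share the level, so imputations track patient levels
        truth = 5.0 + level.reshape(n, T)[:, 0]
        assert np.abs(filled - truth).max() < 1.0

    def test_all_dropped_failure(self):
        vals = np.full(100, np.nan)
        vals[:10] = 1.0
        fm = FeatureMatrix(
            frame_from_columns(100, 1, {"x": vals}), [FeatureDef("x", "continuous")]
        )
        with pytest.raises(PipelineFailureError):
            tiered_impute(fm)


class TestCleanOutliers:
    def test_hard_range_removal(self):
        vals = np.array([120.0, 305.0, 130.0] + [125.0] * 37)
        fm = FeatureMatrix(
            frame_from_columns(40, 1, {"sbp": vals}),
            [FeatureDef("sbp", "continuous", 40, 300)],
        )
        cleaned, audit = clean_outliers(fm)
        assert np.isnan(cleaned.frame["sbp"].iloc[1])
        row = audit[audit["step"] == "hard_range_removed"]
        assert row["count"].sum() >= 1

    def test_winsorization_to_percentiles(self):
        vals = np.concatenate([np.arange(101.0), [10_000.0]])
        fm = FeatureMatrix(
            frame_from_columns(102, 1, {"x": vals}), [FeatureDef("x", "continuous")]
        )
        cleaned, audit = clean_outliers(fm)
        p975 = np.percentile(vals, 97.5)
        assert cleaned.frame["x"].iloc[-1] == pytest.approx(p975)
        assert (audit["step"] == "winsorized").any()

    def test_values_within_three_sd_untouched(self):
        # bounded draws: max deviation 5 is well inside 3 sample SDs (~8.7)
        vals = np.random.default_rng(31).uniform(45, 55, 200)
        fm = FeatureMatrix(
            frame_from_columns(200, 1, {"x": vals.copy()}),
            [FeatureDef("x", "continuous")],
        )
        cleaned, _ = clean_outliers(fm)
        np.testing.assert_array_equal(cleaned.frame["x"].to_numpy(), vals)

    def test_degenerate_feature_skipped(self):
        fm = FeatureMatrix(
            frame_from_columns(50, 1, {"x": np.full(50, 7.0)}),
            [FeatureDef("x", "continuous")],
        )
        cleaned, audit = clean_outliers(fm)
        assert (audit["step"] == "winsorize_skipped_degenerate").any()
        np.testing.assert_array_equal(cleaned.frame["x"].to_numpy(), 7.0)


@pytest.fixture(scope="module")
def fitted(small_cohort, small_split):
    spec = small_cohort.spec
    fm = resample_hourly(
        small_cohort.events, small_cohort.demographics, spec.features(), spec.duration
    )
    train_fm = FeatureMatrix(fm.frame.loc[list(small_split.train)], fm.features)
    test_fm = FeatureMatrix(fm.frame.loc[list(small_split.test)], fm.features)
    pipe = PreprocessPipeline(spec.features())
    pipe.fit(train_fm)
    return pipe, train_fm, test_fm


class TestPipelineOnCohort:
    def test_completeness(self, fitted):
        pipe, train_fm, test_fm = fitted
        out = pipe.transform(test_fm)
        assert not out.frame.isna().any().any()

    def test_idempotence(self, fitted):
        pipe, train_fm, test_fm = fitted
        once = pipe.transform(test_fm)
        twice = pipe.transform(FeatureMatrix(once.frame.copy(), once.features))
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_no_leakage_of_statistics(self, fitted):
        """Transform statistics are frozen from the training split."""
        pipe, train_fm, test_fm = fitted
        shifted = test_fm.frame.copy()
        shifted["glucose"] = shifted["glucose"] + 500.0  # shift the test split
        out = pipe.transform(FeatureMatrix(shifted, test_fm.features))
        # winsorization bounds come from training data, so the shifted values
        # are pulled back to the *training* 97.5th percentile
        assert out.frame["glucose"].max() <= pipe.state["glucose"].p_high + 1e-9

    def test_high_missing_lab_dropped(self, fitted):
        pipe, _, _ = fitted
        assert pipe.state["fibrinogen"].tier == "dropped"
        assert "dropped_high_missing" in set(e["step"] for e in pipe.audit_log)

    def test_one_hot_row_sums(self, fitted):
        pipe, _, test_fm = fitted
        out = pipe.transform(test_fm)
        adm = [c for c in out.frame.columns if c.startswith("admission_type=")]
        np.testing.assert_allclose(out.frame[adm].sum(axis=1).to_numpy(), 1.0)

    def test_serialization(self, fitted, tmp_path):
        pipe, _, _ = fitted
        text = pipe.to_json(tmp_path / "pipe.json")
        import json

        state = json.loads(text)
        assert "sbp" in state["state"]
        assert state["state"]["fibrinogen"]["tier"] == "dropped"

    def test_transform_before_fit_fails(self, small_cohort):
        pipe = PreprocessPipeline(small_cohort.spec.features())
        with pytest.raises(PipelineFailureError):
            pipe.transform(FeatureMatrix(pd.DataFrame(), []))
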