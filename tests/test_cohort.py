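"""Age-stratified analytics: oracles, closed forms, trajectory rule."""

import numpy as np
import pandas as pd
import pytest

from mdrquant.cohort import (
    TrajectoryRule,
    age_stratified_stats,
    annualized_decline,
    classify_trajectories,
    classify_trajectory,
    mdr_histogram,
    mean_median_divergence,
    temporal_differentiation,
)
from mdrquant.errors import DataError
from mdrquant.phantom import CohortParams, generate_cohort


def exams(rows):
    return pd.DataFrame(rows, columns=["subject_id", "age", "laterality", "mdr_percent"])


def sort_percentile(values, q):
    """Independent percentile oracle: linear interpolation between order stats."""
    v = sorted(values)
    if len(v) == 1:
        return v[0]
    pos = q / 100 * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


class TestAgeStats:
    def test_single_record(self):
        table = age_stratified_stats(exams([("a", 50, "left", 30.0)]))
        row = table.iloc[0]
        assert row["age"] == 50 and row["n_images"] == 1
        assert row["mean"] == 30 and row["sd"] == 0
        assert row["median"] == row["iqr1"] == row["iqr3"] == 30

    def test_symmetric_values(self):
        table = age_stratified_stats(
            exams([("a", 45, "left", v) for v in (10.0, 20.0, 30.0, 40.0)])
        )
        row = table.iloc[0]
        assert row["mean"] == 25 and row["median"] == 25

    def test_matches_sort_based_oracle_on_random_cohort(self):
        rng = np.random.default_rng(0)
        rows = [(f"s{i}", int(rng.integers(40, 80)), "left",
                 float(rng.uniform(0, 100))) for i in range(1000)]
        table = age_stratified_stats(exams(rows)).set_index("age")
        df = exams(rows)
        for age, grp in df.groupby("age"):
            v = grp["mdr_percent"].tolist()
            row = table.loc[age]
            assert row["n_images"] == len(v)
            assert row["mean"] == pytest.approx(sum(v) / len(v), abs=1e-9)
            assert row["median"] == pytest.approx(sort_percentile(v, 50), abs=1e-9)
            assert row["iqr1"] == pytest.approx(sort_percentile(v, 25), abs=1e-9)
            assert row["iqr3"] == pytest.approx(sort_percentile(v, 75), abs=1e-9)
            assert row["sd"] == pytest.approx(
                np.sqrt(sum((x - sum(v) / len(v)) ** 2 for x in v) / len(v)), abs=1e-9
            )

    def test_iqr_ordering_invariant(self):
        cohort = generate_cohort(CohortParams(n_subjects=50), seed=9)
        table = age_stratified_stats(cohort.exams)
        assert (table["iqr1"] <= table["median"]).all()
        assert (table["median"] <= table["iqr3"]).all()

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            age_stratified_stats(pd.DataFrame(columns=["subject_id", "age", "mdr_percent"]))


class TestDivergence:
    def test_symmetric_distribution_near_zero(self):
        rows = [("s", 50, "left", v) for v in (10.0, 20.0, 30.0, 40.0, 50.0)]
        d = mean_median_divergence(age_stratified_stats(exams(rows)))
        assert d.loc[50] == pytest.approx(0.0, abs=1e-12)

    def test_right_skewed_mixture_positive_at_late_ages(self):
        # persistent-dense subgroup drags the mean above the median once the
        # majority has declined
        cohort = generate_cohort(CohortParams(n_subjects=300, frac_persistent=0.2), seed=4)
        table = age_stratified_stats(cohort.exams)
        d = mean_median_divergence(table)
        late = d[d.index >= 55]
        assert (late > 0).all()
        # and the gap grows from entry to the last age
        assert late.iloc[-1] > d.iloc[0]


class TestTemporalDifferentiation:
    def test_constant_series_all_zeros(self):
        s = pd.Series(20.0, index=range(40, 50))
        d = temporal_differentiation(s, window=5)
        assert np.allclose(d.to_numpy(), 0.0)

    def test_linear_series_constant_slope(self):
        ages = np.arange(40, 60)
        s = pd.Series(80 - 1.33 * (ages - 40), index=ages)
        for window in (1, 3, 5):
            d = temporal_differentiation(s, window=window)
            assert np.allclose(d.to_numpy(), -1.33)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        ages = np.arange(40, 70)
        s = pd.Series(rng.uniform(0, 100, ages.size), index=ages)
        window = 5
        d = temporal_differentiation(s, window=window)
        diffs = [s.iloc[i + 1] - s.iloc[i] for i in range(len(s) - 1)]
        for i in range(len(diffs)):
            lo = max(0, i - window // 2)
            hi = min(len(diffs), i + window // 2 + 1)
            expected = sum(diffs[lo:hi]) / (hi - lo)
            assert d.iloc[i] == pytest.approx(expected, abs=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            temporal_differentiation(pd.Series([1.0, 2.0], index=[40, 41]), window=4)

    def test_non_consecutive_ages_rejected(self):
        with pytest.raises(DataError):
            temporal_differentiation(pd.Series([1.0, 2.0], index=[40, 45]))


class TestAnnualizedDecline:
    def test_late_age_plateau_figures(self):
        # 20.5% at 60 to 16.0% at 79: 4.5 points over 19 years = 0.24 %/yr
        rate = annualized_decline(20.5, 60, 16.0, 79)
        assert 20.5 - 16.0 == pytest.approx(4.5)
        assert round(rate, 2) == 0.24

    def test_flat_series_zero(self):
        assert annualized_decline(30.0, 40, 30.0, 50) == 0.0

    def test_simple_ratio(self):
        assert annualized_decline(30, 40, 20, 50) == pytest.approx(1.0)

    def test_equal_ages_rejected(self):
        with pytest.raises(ValueError):
            annualized_decline(30, 50, 20, 50)


class TestHistogram:
    def test_point_mass_in_first_bin(self):
        rows = [("s", 40, "left", 5.0) for _ in range(7)]
        h = mdr_histogram(exams(rows), 40)
        assert h["fraction"].iloc[0] == 1.0
        assert h["fraction"].iloc[1:].sum() == 0.0

    def test_fractions_sum_to_one_on_random_cohorts(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            cohort = generate_cohort(CohortParams(n_subjects=30), seed=seed)
            age = int(rng.choice(cohort.exams["age"].unique()))
            h = mdr_histogram(cohort.exams, age)
            assert h["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_value_100_counted_in_last_bin(self):
        rows = [("s", 40, "left", 100.0)]
        h = mdr_histogram(exams(rows), 40)
        assert h["count"].iloc[-1] == 1

    def test_missing_age_rejected(self):
        with pytest.raises(DataError):
            mdr_histogram(exams([("s", 40, "left", 5.0)]), 60)


class TestTrajectory:
    def test_constant_dense_series_is_persistent(self):
        rows = [("s", 40 + 5 * k, "left", 60.0) for k in range(5)]
        assert classify_trajectory(exams(rows)) == "persistently_dense"

    def test_two_percent_per_year_drop_is_rapid(self):
        rows = [("s", 40 + k, "left", 40.0 - 2.0 * k) for k in range(6)]
        assert classify_trajectory(exams(rows)) == "rapidly_decreasing"

    def test_single_exam_indeterminate(self):
        assert classify_trajectory(exams([("s", 50, "left", 80.0)])) == "indeterminate"

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            classify_trajectory(exams([]))

    def test_rule_thresholds_respected(self):
        rows = [("s", 40 + k, "left", 40.0 - 0.8 * k) for k in range(6)]
        assert classify_trajectory(exams(rows)) == "indeterminate"
        loose = TrajectoryRule(rapid_slope=-0.5)
        assert classify_trajectory(exams(rows), loose) == "rapidly_decreasing"

    def test_group_recovery_on_clean_cohort(self):
        params = CohortParams(n_subjects=60, noise_sd=0.5)
        cohort = generate_cohort(params, seed=2)
        pred = classify_trajectories(cohort.exams).set_index("subject_id")["group"]
        truth = cohort.truth.set_index("subject_id")["group"]
        accuracy = (pred.loc[truth.index] == truth).mean()
        assert accuracy >= 0.95
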