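"""Age-stratified MDR analytics for screening cohorts.

Works on exam tables with columns ``subject_id, age, laterality,
mdr_percent`` (percent scale, 0–100, matching how screening programs report
density; the per-image density layer works in proportions and the boundary
converts explicitly). Provides:

* per-age summary statistics (n, mean, SD, median, 25th/75th percentiles),
* the age-wise divergence between mean and median MDR — a growing gap with
  age signals a right-skewed mixture, i.e. a persistently dense
  subpopulation on top of a declining majority,
* smoothed temporal differentiation of the median-MDR-by-age curve (first
  difference + centered moving average), which localizes where the
  age-related decline plateaus,
* per-age MDR histograms on 10%-wide bins,
* annualized decline between two (MDR, age) points,
* a parameterized per-subject trajectory classifier separating rapidly
  declining from persistently dense series.

Percentiles use linear interpolation between order statistics (numpy's
default), stated here so ports can match. Statistics count images, not
women; averaging a woman's two sides first is an optional pre-step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "age_stratified_stats",
    "mean_median_divergence",
    "temporal_differentiation",
    "annualized_decline",
    "mdr_histogram",
    "TrajectoryRule",
    "classify_trajectory",
    "classify_trajectories",
    "average_lateralities",
]

_REQUIRED = ("subject_id", "age", "mdr_percent")


def _check_exams(records: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records)
    if len(records) == 0:
        raise DataError("empty exam table")
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise DataError(f"exam table missing columns {missing}")
    vals = records["mdr_percent"].to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals < 0).any() or (vals > 100).any():
        raise DataError("mdr_percent must be within [0, 100] and non-missing")
    return records


def average_lateralities(records: pd.DataFrame) -> pd.DataFrame:
    """Optional pre-step: one row per (subject, age), MDR averaged over sides."""
    records = _check_exams(records)
    out = (records.groupby(["subject_id", "age"], as_index=False)["mdr_percent"]
           .mean())
    out["laterality"] = "both"
    return out


def age_stratified_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Per-age MDR summary: one row per distinct age present.

    Columns: ``age, n_images, mean, sd, median, iqr1, iqr3`` (SD is the
    population-style ``ddof=0`` standard deviation so a single image gives
    sd = 0; iqr1/iqr3 are the 25th/75th percentiles).
    """
    records = _check_exams(records)
    rows = []
    for age, grp in records.groupby("age", sort=True):
        v = grp["mdr_percent"].to_numpy(dtype=float)
        rows.append({
            "age": int(age),
            "n_images": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=0)),
            "median": float(np.median(v)),
            "iqr1": float(np.percentile(v, 25)),
            "iqr3": float(np.percentile(v, 75)),
        })
    return pd.DataFrame(rows)


def mean_median_divergence(stats: pd.DataFrame) -> pd.Series:
    """Per-age (mean − median) MDR, indexed by age in ascending order."""
    if len(stats) == 0:
        raise DataError("empty age-stats table")
    s = stats.sort_values("age")
    return pd.Series((s["mean"] - s["median"]).to_numpy(),
                     index=s["age"].to_numpy(), name="mean_minus_median")


def temporal_differentiation(median_series: pd.Series, window: int = 5) -> pd.Series:
    """Smoothed per-age rate of change of a median-MDR-by-age series.

    First difference ``d(a) = median(a+1) − median(a)`` followed by a
    centered moving average of odd width ``window``; at the edges the window
    shrinks symmetrically to what is available. The series must be indexed
    by consecutive integer ages. Returns the smoothed differences indexed by
    the starting age of each difference (length = len(series) − 1).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    if not isinstance(median_series, pd.Series):
        median_series = pd.Series(np.asarray(median_series, dtype=float))
    ages = np.asarray(median_series.index)
    if len(ages) < 2:
        raise DataError("need at least two ages to differentiate")
    if not np.array_equal(np.diff(ages), np.ones(len(ages) - 1)):
        raise DataError("series must be indexed by consecutive integer ages")
    diffs = np.diff(median_series.to_numpy(dtype=float))
    half = window // 2
    sm = np.empty_like(diffs)
    for i in range(diffs.size):
        lo = max(0, i - half)
        hi = min(diffs.size, i + half + 1)
        sm[i] = diffs[lo:hi].mean()
    return pd.Series(sm, index=ages[:-1], name="d_mdr_per_year")


def annualized_decline(mdr_start: float, age_start: float,
                       mdr_end: float, age_end: float) -> float:
    """Average decline in percentage points of MDR per year between two ages.

    Positive values mean density decreased with age.
    """
    if age_end == age_start:
        raise ValueError("age_end must differ from age_start")
    if age_end < age_start:
        raise ValueError("age_end must exceed age_start")
    return (mdr_start - mdr_end) / (age_end - age_start)


def mdr_histogram(records: pd.DataFrame, age: int, bin_width: float = 10.0) -> pd.DataFrame:
    """Binned MDR distribution at one age.

    Bins are ``[0, w), [w, 2w), ..., [100−w, 100]`` (the last bin closed so
    MDR = 100 is counted). Returns columns ``bin_left, bin_right, count,
    fraction``; fractions sum to 1.
    """
    records = _check_exams(records)
    if not 0 < bin_width <= 100:
        raise ValueError("bin_width must be in (0, 100]")
    v = records.loc[records["age"] == age, "mdr_percent"].to_numpy(dtype=float)
    if v.size == 0:
        raise DataError(f"no records at age {age}")
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    counts, _ = np.histogram(v, bins=edges)  # numpy closes the last bin
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
        "fraction": counts / v.size,
    })


@dataclass(frozen=True)
class TrajectoryRule:
    """Thresholds for the per-subject trajectory classifier.

    These are this package's operational defaults for separating the two
    longitudinal patterns, not a published criterion: a least-squares slope
    of MDR on age at or below ``rapid_slope`` marks a rapidly decreasing
    series; a series averaging at least ``dense_level`` percent with slope
    above ``persistent_slope`` is persistently dense; anything else —
    including series with fewer than two exams — is indeterminate.
    """

    rapid_slope: float = -1.0        # %MDR per year
    persistent_slope: float = -0.5   # %MDR per year
    dense_level: float = 50.0        # mean %MDR


def classify_trajectory(subject_series: pd.DataFrame,
                        rule: TrajectoryRule | None = None) -> str:
    """Classify one subject's age-sorted MDR series.

    Returns ``"rapidly_decreasing"``, ``"persistently_dense"`` or
    ``"indeterminate"``.
    """
    rule = rule or TrajectoryRule()
    if len(subject_series) == 0:
        raise DataError("empty subject series")
    ages = subject_series["age"].to_numpy(dtype=float)
    vals = subject_series["mdr_percent"].to_numpy(dtype=float)
    if ages.size < 2 or np.ptp(ages) == 0:
        return "indeterminate"
    order = np.argsort(ages)
    ages, vals = ages[order], vals[order]
    slope = float(np.polyfit(ages, vals, 1)[0])
    if slope <= rule.rapid_slope:
        return "rapidly_decreasing"
    if vals.mean() >= rule.dense_level and slope > rule.persistent_slope:
        return "persistently_dense"
    return "indeterminate"


def classify_trajectories(records: pd.DataFrame,
                          rule: TrajectoryRule | None = None) -> pd.DataFrame:
    """Classify every subject in an exam table.

    Sides are averaged per (subject, age) first so the fit sees one value
    per time point. Returns columns ``subject_id, n_exams, slope, mean_mdr,
    group``.
    """
    records = _check_exams(records)
    per_point = (records.groupby(["subject_id", "age"], as_index=False)["mdr_percent"].mean())
    rule = rule or TrajectoryRule()
    rows = []
    for sid, grp in per_point.groupby("subject_id", sort=True):
        ages = grp["age"].to_numpy(dtype=float)
        vals = grp["mdr_percent"].to_numpy(dtype=float)
        slope = float(np.polyfit(ages, vals, 1)[0]) if ages.size >= 2 and np.ptp(ages) else float("nan")
        rows.append({
            "subject_id": sid,
            "n_exams": int(ages.size),
            "slope": slope,
            "mean_mdr": float(vals.mean()),
            "group": classify_trajectory(grp, rule),
        })
    return pd.DataFrame(rows)
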