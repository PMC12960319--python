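"""Phantom and cohort generator: determinism, geometry, ground-truth MDR."""

import numpy as np
import pandas as pd
import pytest

from mdrquant.errors import ConfigurationError, DegeneratePhantomError
from mdrquant.phantom import (
    CohortParams,
    PhantomParams,
    generate_cohort,
    generate_phantom,
    generate_phantom_set,
)
from mdrquant.types import FAT, GLAND, PECTORAL


def brute_force_mdr(image, mask):
    """Independent per-pixel loop: dense gland pixels / gland pixels."""
    px, lab = image.pixels, mask.labels
    pec_sum = pec_n = 0.0
    for i in range(px.shape[0]):
        for j in range(px.shape[1]):
            if lab[i, j] == PECTORAL:
                pec_sum += px[i, j]
                pec_n += 1
    d_mj = pec_sum / pec_n
    a_gl = a_d = 0
    for i in range(px.shape[0]):
        for j in range(px.shape[1]):
            if lab[i, j] == GLAND:
                a_gl += 1
                if px[i, j] > d_mj:
                    a_d += 1
    return a_d / a_gl


class TestGeneratePhantom:
    def test_shapes_and_labels(self, small_pair):
        img, mask = small_pair
        assert img.pixels.shape == mask.labels.shape
        assert set(np.unique(mask.labels)) <= {0, 1, 2, 3}

    def test_pectoral_touches_upper_corner(self):
        left, lmask = generate_phantom(PhantomParams(width=64, height=80, laterality="left"), 1)
        right, rmask = generate_phantom(PhantomParams(width=64, height=80, laterality="right"), 1)
        assert lmask.labels[0, 0] == PECTORAL
        assert rmask.labels[0, -1] == PECTORAL
        # mirroring: the right phantom is the column-flipped left phantom
        np.testing.assert_array_equal(rmask.labels, lmask.labels[:, ::-1])
        np.testing.assert_array_equal(right.pixels, left.pixels[:, ::-1])

    def test_seeded_determinism(self, small_params):
        a_img, a_mask = generate_phantom(small_params, seed=9)
        b_img, b_mask = generate_phantom(small_params, seed=9)
        np.testing.assert_array_equal(a_img.pixels, b_img.pixels)
        np.testing.assert_array_equal(a_mask.labels, b_mask.labels)
        c_img, _ = generate_phantom(small_params, seed=10)
        assert not np.array_equal(a_img.pixels, c_img.pixels)

    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_extreme_dense_fractions_exact(self, p, expected):
        params = PhantomParams(width=64, height=80, dense_fraction=p)
        img, mask = generate_phantom(params, seed=4)
        assert brute_force_mdr(img, mask) == expected

    def test_dense_fraction_recovered_near_target(self):
        # default geometry has a gland of ~5000 px at 160x192
        params = PhantomParams(dense_fraction=0.40)
        img, mask = generate_phantom(params, seed=7)
        assert int((mask.labels == GLAND).sum()) >= 2000
        assert 0.37 <= brute_force_mdr(img, mask) <= 0.43

    def test_dense_fraction_recovery_sweep(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            p = float(rng.uniform(0, 1))
            params = PhantomParams(width=96, height=112, dense_fraction=p)
            img, mask = generate_phantom(params, seed=int(rng.integers(2**31)))
            assert abs(brute_force_mdr(img, mask) - p) <= 0.03

    def test_dimension_not_divisible_by_16_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_phantom(PhantomParams(width=100, height=80), 0)

    def test_degenerate_gland_rejected(self):
        with pytest.raises(DegeneratePhantomError):
            generate_phantom(PhantomParams(width=64, height=80, gland_fraction=0.0005), 0)

    def test_fat_brighter_than_pectoral_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_phantom(
                PhantomParams(fat_intensity_mean=0.8, pectoral_intensity_mean=0.7), 0
            )

    def test_label_counts_match_manifest(self, small_params):
        ps = generate_phantom_set(4, small_params, seed=2)
        for (_, mask), (_, row) in zip(ps.items, ps.manifest.iterrows()):
            counts = mask.class_counts()
            assert counts[FAT] == row["area_fat"]
            assert counts[GLAND] == row["area_gland"]
            assert counts[PECTORAL] == row["area_pectoral"]


class TestGeneratePhantomSet:
    def test_rerun_identical(self, small_params):
        a = generate_phantom_set(3, small_params, seed=1)
        b = generate_phantom_set(3, small_params, seed=1)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        for (ia, ma), (ib, mb) in zip(a.items, b.items):
            np.testing.assert_array_equal(ia.pixels, ib.pixels)
            np.testing.assert_array_equal(ma.labels, mb.labels)

    def test_split_manifest_sizes(self, small_params):
        ps = generate_phantom_set(20, small_params, seed=1, split=(16, 4))
        manifests = ps.split_manifests()
        assert len(manifests["train"]) == 16
        assert len(manifests["test"]) == 4
        assert len(ps.subset("train").items) == 16

    def test_manifest_records_parameters(self, small_params):
        fixed = PhantomParams(width=64, height=80, dense_fraction=0.5)
        ps = generate_phantom_set(1, fixed, seed=0)
        assert ps.manifest.loc[0, "dense_fraction"] == 0.5

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom_set(0, None, seed=0)


class TestGenerateCohort:
    def test_no_noise_no_decline_is_constant(self):
        params = CohortParams(n_subjects=5, frac_persistent=0.0,
                              decline_rate_fast=0.0, noise_sd=0.0)
        cohort = generate_cohort(params, seed=0)
        per_subject = cohort.exams.groupby("subject_id")["mdr_percent"].nunique()
        assert (per_subject == 1).all()

    def test_closed_form_linear_decline(self):
        # 36.2% at entry, 1.33 %/yr, no noise: 19 years later = 36.2 - 19*1.33
        params = CohortParams(
            n_subjects=1, frac_persistent=0.0, decline_rate_fast=1.33,
            start_mdr_fast=(36.2, 0.0), noise_sd=0.0,
            exams_per_subject=2, exam_interval_years=19,
        )
        cohort = generate_cohort(params, seed=0)
        val = cohort.exams.loc[cohort.exams["age"] == 59, "mdr_percent"].iloc[0]
        assert val == pytest.approx(36.2 - 19 * 1.33, abs=1e-9)
        assert val == pytest.approx(10.9, abs=0.05)

    def test_persistent_count_exact(self):
        params = CohortParams(n_subjects=100, frac_persistent=0.2)
        cohort = generate_cohort(params, seed=123)
        assert (cohort.truth["group"] == "persistently_dense").sum() == 20

    def test_values_in_range_and_ages_distinct(self):
        cohort = generate_cohort(CohortParams(n_subjects=20), seed=6)
        assert cohort.exams["mdr_percent"].between(0, 100).all()
        for _, grp in cohort.exams.groupby("subject_id"):
            assert grp["age"].is_unique

    def test_inverted_age_range_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortParams(age_range=(79, 40)), seed=0)

    def test_seeded_determinism(self):
        a = generate_cohort(CohortParams(n_subjects=10), seed=3)
        b = generate_cohort(CohortParams(n_subjects=10), seed=3)
        pd.testing.assert_frame_equal(a.exams, b.exams)
        pd.testing.assert_frame_equal(a.truth, b.truth)
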