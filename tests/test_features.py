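"""Lesion load vectors, covariate scaling and feature assembly."""

import numpy as np
import pandas as pd
import pytest

import mlsm
from mlsm.errors import ContractError, FeaturizationError, GridMismatchError
from mlsm.features import SUBSCORES, assemble_features, encode_and_scale_covariates
from mlsm.imaging import AtlasDefinition, LesionVolume, VoxelGrid

from conftest import make_table_cohort


def _random_atlas(rng, dims=(12, 12, 12), n_labels=4):
    """Arbitrary (non-contiguous) labeling — valid input for LLV extraction."""
    while True:
        labels = rng.integers(0, n_labels + 1, size=dims).astype(np.int32)
        if len(np.unique(labels)) == n_labels + 1:
            break
    table = pd.DataFrame({"label": np.arange(1, n_labels + 1),
                          "name": [f"r{i}" for i in range(n_labels)],
                          "tissue_class": ["grey"] * n_labels})
    return AtlasDefinition(grid=VoxelGrid.isotropic(dims), labels=labels, roi_table=table)


def _brute_force_llv(values, atlas):
    """Per-voxel accumulation oracle: explicit triple loop."""
    sums = {lab: 0.0 for lab in atlas.roi_labels}
    counts = {lab: 0 for lab in atlas.roi_labels}
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            for k in range(values.shape[2]):
                lab = int(atlas.labels[i, j, k])
                if lab > 0:
                    sums[lab] += values[i, j, k]
                    counts[lab] += 1
    return np.array([min(1.0, sums[lab] / counts[lab]) for lab in atlas.roi_labels])


class TestComputeLlv:
    def test_empty_lesion_all_zero(self, small_atlas):
        vol = LesionVolume(grid=small_atlas.grid,
                           values=np.zeros(small_atlas.grid.dims), patient_id="p")
        assert np.all(mlsm.compute_llv(vol, small_atlas) == 0.0)

    def test_full_roi_coverage_gives_one(self, small_atlas):
        lab = small_atlas.roi_labels[3]
        values = (small_atlas.labels == lab).astype(float)
        vol = LesionVolume(grid=small_atlas.grid, values=values, patient_id="p")
        llv = mlsm.compute_llv(vol, small_atlas)
        assert llv[3] == 1.0
        assert np.all(llv[np.arange(len(llv)) != 3] == 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            atlas = _random_atlas(rng)
            values = rng.uniform(0, 1, atlas.grid.dims)
            vol = LesionVolume(grid=atlas.grid, values=values, patient_id="p",
                               is_binary=False)
            np.testing.assert_allclose(mlsm.compute_llv(vol, atlas),
                                       _brute_force_llv(values, atlas), atol=1e-12)

    def test_monotone_in_lesion_growth(self):
        """A superset lesion never decreases any LLV entry (no smoothing)."""
        rng = np.random.default_rng(5)
        atlas = _random_atlas(rng)
        small = rng.uniform(0, 1, atlas.grid.dims) > 0.8
        big = small | (rng.uniform(0, 1, atlas.grid.dims) > 0.8)
        llv_small = mlsm.compute_llv(
            LesionVolume(grid=atlas.grid, values=small.astype(float), patient_id="a"), atlas)
        llv_big = mlsm.compute_llv(
            LesionVolume(grid=atlas.grid, values=big.astype(float), patient_id="b"), atlas)
        assert np.all(llv_big >= llv_small)

    def test_grid_mismatch_raises(self, small_atlas):
        vol = LesionVolume(grid=VoxelGrid.isotropic((10, 10, 10)),
                           values=np.zeros((10, 10, 10)), patient_id="p")
        with pytest.raises(GridMismatchError):
            mlsm.compute_llv(vol, small_atlas)


class TestLesionExtent:
    def test_unit_conversion(self):
        values = np.zeros((10, 10, 10))
        values.flat[:1000] = 1.0
        vol = LesionVolume(grid=VoxelGrid.isotropic((10, 10, 10), 1.0), values=values,
                           patient_id="p")
        assert mlsm.lesion_extent_cm3(vol) == pytest.approx(1.0)

    def test_empty_mask(self):
        vol = LesionVolume(grid=VoxelGrid.isotropic((6, 6, 6)), values=np.zeros((6, 6, 6)),
                           patient_id="p")
        assert mlsm.lesion_extent_cm3(vol) == 0.0

    def test_790_voxels_at_2mm(self):
        values = np.zeros((20, 20, 20))
        values.flat[:790] = 1.0
        vol = LesionVolume(grid=VoxelGrid.isotropic((20, 20, 20), 2.0), values=values,
                           patient_id="p")
        assert mlsm.lesion_extent_cm3(vol) == pytest.approx(6.32)

    def test_non_binary_raises(self):
        vol = LesionVolume(grid=VoxelGrid.isotropic((6, 6, 6)),
                           values=np.full((6, 6, 6), 0.5), patient_id="p", is_binary=False)
        with pytest.raises(ContractError):
            mlsm.lesion_extent_cm3(vol)


class TestCovariateScaling:
    def test_midpoint(self):
        train = pd.DataFrame({"age": [20.0, 90.0]})
        apply = pd.DataFrame({"age": [55.0]})
        t, a = encode_and_scale_covariates(train, apply, columns=("age",))
        assert a["age"].iloc[0] == pytest.approx(0.5)
        assert list(t["age"]) == [0.0, 1.0]

    def test_constant_column_maps_to_zero(self):
        train = pd.DataFrame({"sex": ["M", "M", "M"]})
        t, _ = encode_and_scale_covariates(train, columns=("sex",))
        assert np.all(t["sex"] == 0.0)

    def test_out_of_range_clipped(self):
        train = pd.DataFrame({"age": [20.0, 90.0]})
        apply = pd.DataFrame({"age": [95.0, 5.0]})
        _, a = encode_and_scale_covariates(train, apply, columns=("age",))
        assert list(a["age"]) == [1.0, 0.0]

    def test_missing_covariate_raises(self):
        train = pd.DataFrame({"age": [20.0, np.nan]})
        with pytest.raises(FeaturizationError, match="missing"):
            encode_and_scale_covariates(train, columns=("age",))

    def test_unknown_category_raises(self):
        train = pd.DataFrame({"sex": ["M", "X"]})
        with pytest.raises(FeaturizationError, match="sex"):
            encode_and_scale_covariates(train, columns=("sex",))


class TestAssembleFeatures:
    def test_column_arithmetic(self, tiny_cohort):
        cohort, _ = tiny_cohort
        n_rois = cohort.atlas.n_rois
        fm = assemble_features(cohort, "overall", "acute", "llv")
        assert fm.n_features == n_rois + 1 + 5  # LLVs + extent + demographics
        fm_ip = assemble_features(cohort, "overall", "1mo", "llv_ip")
        assert fm_ip.n_features == n_rois + 1 + 5 + 1
        fm_demo = assemble_features(cohort, "overall", "acute", "reduced_no_llv_no_extent")
        assert fm_demo.n_features == 5
        assert fm_demo.column_names == ["age", "sex", "handedness", "education",
                                        "stroke_type"]

    def test_llv_columns_not_scaled(self, tiny_cohort):
        cohort, _ = tiny_cohort
        fm = assemble_features(cohort, "overall", "acute", "llv")
        assert not fm.scale_mask[:cohort.atlas.n_rois].any()
        assert fm.scale_mask[cohort.atlas.n_rois:].all()

    def test_deterministic_and_sorted(self, tiny_cohort):
        cohort, _ = tiny_cohort
        a = assemble_features(cohort, "overall", "1mo", "llv")
        b = assemble_features(cohort, "overall", "1mo", "llv")
        assert a.patient_ids == sorted(a.patient_ids) == b.patient_ids
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)
        assert a.column_names == b.column_names

    def test_ip_at_acute_rejected(self, tiny_cohort):
        cohort, _ = tiny_cohort
        with pytest.raises(FeaturizationError, match="acute"):
            assemble_features(cohort, "overall", "acute", "llv_ip")

    def test_empty_case_set_names_cell(self, small_atlas):
        cohort, _ = make_table_cohort(small_atlas, n=6, seed=2)
        cohort.scores = cohort.scores[~((cohort.scores["outcome"] == "reading")
                                        & (cohort.scores["timepoint"] == "12mo"))]
        cohort._score_cache.clear()
        with pytest.raises(FeaturizationError, match="reading.*12mo"):
            assemble_features(cohort, "reading", "12mo", "llv")

    def test_untestable_acute_filtering(self, untestable_cohort):
        """Untestable patients enter the acute overall model with response 0
        and are excluded from every acute subscore model."""
        cohort, true_scores = untestable_cohort
        acute = true_scores[true_scores["timepoint"] == "acute"]
        untestable_ids = set(acute.loc[acute["untestable"], "patient_id"])
        fm_overall = assemble_features(cohort, "overall", "acute", "llv")
        assert untestable_ids <= set(fm_overall.patient_ids)
        resp = dict(zip(fm_overall.patient_ids, fm_overall.y))
        assert all(resp[pid] == 0.0 for pid in untestable_ids)
        for sub in SUBSCORES:
            fm_sub = assemble_features(cohort, sub, "acute", "llv")
            assert untestable_ids.isdisjoint(fm_sub.patient_ids)
            assert len(fm_sub.patient_ids) == cohort.n_patients - len(untestable_ids)
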