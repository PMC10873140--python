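"""Synthetic atlas / lesion / score / dropout generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import mlsm
from mlsm.errors import GenerationError
from mlsm.features import SUBSCORES, TIMEPOINTS
from mlsm.synthetic import (
    GroundTruth,
    apply_dropout,
    make_synthetic_atlas,
    sample_lesion_sizes,
    simulate_lesion,
    simulate_scores,
)


class TestSyntheticAtlas:
    def test_partition_properties(self):
        atlas = make_synthetic_atlas((16, 16, 16), n_rois=4, seed=3, margin=2)
        interior = atlas.labels[2:-2, 2:-2, 2:-2]
        assert np.all(interior > 0)  # union covers the interior box
        assert set(np.unique(interior)) == {1, 2, 3, 4}
        rim = atlas.labels.copy()
        rim[2:-2, 2:-2, 2:-2] = 0
        assert np.all(rim == 0)  # background margin

    def test_parcels_contiguous(self, small_atlas):
        for lab in small_atlas.roi_labels:
            _, n_components = ndimage.label(small_atlas.labels == lab)
            assert n_components == 1

    def test_determinism(self):
        a = make_synthetic_atlas((20, 20, 20), n_rois=8, seed=9, margin=3)
        b = make_synthetic_atlas((20, 20, 20), n_rois=8, seed=9, margin=3)
        assert np.array_equal(a.labels, b.labels)
        assert a.roi_table.equals(b.roi_table)

    def test_paper_scale_atlas(self):
        atlas = make_synthetic_atlas((64, 64, 64), n_rois=150, seed=1)
        counts = atlas.voxel_counts()
        assert len(counts) == 150 and counts.min() >= 8
        assert set(atlas.roi_table["tissue_class"]) == {"grey", "white", "commissural"}

    def test_infeasible_raises(self):
        with pytest.raises(GenerationError):
            make_synthetic_atlas((10, 10, 10), n_rois=500, seed=0, margin=2)
        with pytest.raises(GenerationError):
            make_synthetic_atlas((16, 16, 16), n_rois=1, seed=0)


class TestSimulateLesion:
    def test_minimum_one_voxel(self, small_atlas):
        les = simulate_lesion(small_atlas, 0.0, np.random.default_rng(0))
        assert les.n_lesioned_voxels == 1

    def test_exact_voxel_count_and_connectivity(self, small_atlas):
        rng = np.random.default_rng(1)
        les = simulate_lesion(small_atlas, 4.0, rng)
        assert les.n_lesioned_voxels == round(4.0 * 1000 / 8)
        _, n_comp = ndimage.label(les.values > 0)
        assert n_comp == 1
        # lesion confined to labeled brain
        assert np.all(small_atlas.labels[les.values > 0] > 0)

    def test_unreachable_target_raises(self, small_atlas):
        brain_cm3 = (small_atlas.labels > 0).sum() * 8 / 1000
        with pytest.raises(GenerationError):
            simulate_lesion(small_atlas, 0.9 * brain_cm3, np.random.default_rng(0))

    def test_lognormal_size_scale(self):
        cfg = mlsm.SimConfig(n_patients=100, seed=12)
        sizes = sample_lesion_sizes(cfg, np.random.default_rng(12))
        assert abs(sizes.mean() - cfg.lesion_mean_cm3) / cfg.lesion_mean_cm3 < 0.25
        assert sizes.min() >= cfg.lesion_min_cm3 and sizes.max() <= cfg.lesion_max_cm3


def _truth_params(n_rois, noise_sd=0.0, recovery=None, **over):
    params = {
        "roi_weights": np.zeros(n_rois), "informative_rois": np.array([], dtype=int),
        "size_coefficient": 0.0, "baseline": 9.5,
        "noise_sd": {tp: noise_sd for tp in TIMEPOINTS}, "subscore_sd": 0.0,
        "recovery_fractions": recovery or {"1mo": 0.25, "3mo": 0.35, "12mo": 0.5},
        "untestable_threshold": -100.0, "untestable_prob": 0.0,
    }
    params.update(over)
    return params


def _llv_frame(n, n_rois, rng):
    return pd.DataFrame(rng.uniform(0, 1, (n, n_rois)),
                        index=[f"p{i:03d}" for i in range(n)],
                        columns=[f"llv_{j + 1}" for j in range(n_rois)])


class TestSimulateScores:
    def test_zero_lesion_no_noise_hits_baseline(self):
        """No deficit, no noise: every score is min(baseline, ceiling)."""
        rng = np.random.default_rng(0)
        llv = _llv_frame(3, 4, rng) * 0.0
        extents = pd.Series(0.0, index=llv.index)
        scores, _ = simulate_scores(llv, extents, _truth_params(4, baseline=10.5), rng)
        assert np.allclose(scores["value"], 10.0)
        # a sub-ceiling baseline is reproduced exactly at the acute timepoint
        scores2, _ = simulate_scores(llv, extents, _truth_params(4, baseline=9.5), rng)
        acute = scores2[scores2["timepoint"] == "acute"]
        assert np.allclose(acute["value"], 9.5)

    def test_full_recovery_limit(self):
        rng = np.random.default_rng(1)
        llv = _llv_frame(4, 4, rng)
        extents = pd.Series(10.0, index=llv.index)
        params = _truth_params(4, recovery={"1mo": 1.0, "3mo": 1.0, "12mo": 1.0})
        params["roi_weights"][:2] = -5.0
        scores, _ = simulate_scores(llv, extents, params, rng)
        followup = scores[scores["timepoint"] != "acute"]
        assert np.allclose(followup["value"], 10.0)

    def test_scores_bounded(self):
        rng = np.random.default_rng(2)
        llv = _llv_frame(30, 6, rng)
        params = _truth_params(6, noise_sd=3.0, subscore_sd=3.0)
        params["roi_weights"][:3] = -8.0
        scores, _ = simulate_scores(llv, pd.Series(50.0, index=llv.index), params, rng)
        vals = scores["value"].dropna()
        assert vals.min() >= 0.0 and vals.max() <= 10.0

    def test_untestable_convention(self):
        rng = np.random.default_rng(3)
        llv = _llv_frame(10, 4, rng)
        params = _truth_params(4, noise_sd=0.1, untestable_threshold=20.0,
                               untestable_prob=1.0)
        scores, truth = simulate_scores(llv, pd.Series(0.0, index=llv.index), params, rng)
        acute = scores[scores["timepoint"] == "acute"]
        assert np.all(acute.loc[acute["outcome"] == "overall", "value"] == 0.0)
        for sub in SUBSCORES:
            assert acute.loc[acute["outcome"] == sub, "value"].isna().all()
        assert truth.loc[truth["timepoint"] == "acute", "untestable"].all()

    def test_weight_length_mismatch(self):
        rng = np.random.default_rng(4)
        llv = _llv_frame(3, 4, rng)
        with pytest.raises(GenerationError):
            simulate_scores(llv, pd.Series(0.0, index=llv.index), _truth_params(5), rng)


class TestGroundTruthInvariants:
    def test_recovery_must_be_nondecreasing(self):
        with pytest.raises(GenerationError):
            GroundTruth(roi_weights=np.zeros(3), size_coefficient=0.0, baseline=9.5,
                        noise_sd={tp: 0.8 for tp in TIMEPOINTS},
                        recovery_fractions={"1mo": 0.5, "3mo": 0.3, "12mo": 0.6},
                        informative_rois=np.array([]), true_scores=pd.DataFrame())


def _fake_scores(n):
    rows = []
    for i in range(n):
        for tp in TIMEPOINTS:
            rows.append({"patient_id": f"p{i:04d}", "timepoint": tp,
                         "outcome": "overall", "value": 5.0})
    return pd.DataFrame(rows)


class TestApplyDropout:
    def test_zero_dropout_unchanged(self):
        scores = _fake_scores(20)
        out = apply_dropout(scores, {"1mo": 0.0, "3mo": 0.0, "12mo": 0.0},
                            np.random.default_rng(0))
        assert out.equals(scores.reset_index(drop=True))

    def test_full_dropout_removes_followups(self):
        out = apply_dropout(_fake_scores(20), {"1mo": 1.0, "3mo": 1.0, "12mo": 1.0},
                            np.random.default_rng(0))
        assert set(out["timepoint"]) == {"acute"}

    def test_retention_within_binomial_bounds(self):
        out = apply_dropout(_fake_scores(217), {"12mo": 0.55}, np.random.default_rng(7))
        retained = out.loc[out["timepoint"] == "12mo", "patient_id"].nunique()
        # Binomial(217, 0.45): mean 97.65, sd 7.33; 99% interval +/- 2.576 sd
        assert 78 <= retained <= 117

    def test_retention_independent_of_severity(self):
        """Acute severity of retained vs dropped patients matches in
        distribution (here: identical generative scores, so only the
        mechanism is checked — dropout never reads values)."""
        scores = _fake_scores(50)
        scores.loc[scores["timepoint"] == "acute", "value"] = np.tile(
            np.linspace(0, 10, 50), 1).repeat(1)
        out = apply_dropout(scores, {"12mo": 0.5}, np.random.default_rng(1))
        kept = set(out.loc[out["timepoint"] == "12mo", "patient_id"])
        acute = scores[scores["timepoint"] == "acute"]
        kept_mean = acute[acute["patient_id"].isin(kept)]["value"].mean()
        dropped_mean = acute[~acute["patient_id"].isin(kept)]["value"].mean()
        assert abs(kept_mean - dropped_mean) < 2.0


class TestGenerateCohort:
    def test_smoke_roundtrip_and_determinism(self, tmp_path):
        cfg = mlsm.SimConfig(n_patients=8, grid_dims=(28, 28, 28), margin=4, n_rois=8,
                             lesion_mean_cm3=10.0, lesion_sd_cm3=8.0,
                             lesion_max_cm3=40.0, seed=33)
        out1 = mlsm.generate_cohort(cfg, tmp_path / "a")
        out2 = mlsm.generate_cohort(cfg, tmp_path / "b")
        for name in ("covariates.tsv", "scores.tsv", "atlas_rois.tsv", "true_scores.tsv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
        cohort = mlsm.load_cohort(out1)
        assert cohort.n_patients == 8
        direct, _, _ = mlsm.simulate_cohort(cfg)
        np.testing.assert_allclose(cohort.llv.to_numpy(), direct.llv.to_numpy(),
                                   atol=1e-6)
        # loaded cohort drives the full pipeline with no special-casing
        cv = mlsm.loocv_predict(cohort, "overall", "acute", "llv")
        assert len(cv) == 8
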