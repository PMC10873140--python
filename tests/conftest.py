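"""Shared fixtures: small synthetic atlases and cohorts.

Everything is generated programmatically and seeded; no stored data.
Small-grid cohorts must keep the lesion size distribution inside the 80%
growth cap of their labeled volume, hence the reduced size parameters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mlsm
from mlsm.features import TIMEPOINTS
from mlsm.synthetic import simulate_covariates, simulate_scores


@pytest.fixture(scope="session")
def small_atlas():
    """6-parcel atlas on a 24³ grid (2 mm voxels, 3-voxel background rim)."""
    return mlsm.make_synthetic_atlas((24, 24, 24), n_rois=6, seed=7, margin=3)


@pytest.fixture(scope="session")
def tiny_cohort():
    """20-patient location-driven cohort with no follow-up dropout."""
    cfg = mlsm.SimConfig(
        n_patients=20, grid_dims=(32, 32, 32), margin=4, n_rois=12,
        lesion_mean_cm3=15.0, lesion_sd_cm3=12.0, lesion_max_cm3=60.0,
        n_informative=3, dropout={"1mo": 0.0, "3mo": 0.0, "12mo": 0.0}, seed=5)
    cohort, truth, _ = mlsm.simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def medium_cohort():
    """40-patient location-driven cohort, no dropout (for grid-level checks)."""
    cfg = mlsm.SimConfig(
        n_patients=40, grid_dims=(32, 32, 32), margin=4, n_rois=12,
        lesion_mean_cm3=15.0, lesion_sd_cm3=12.0, lesion_max_cm3=60.0,
        n_informative=3, dropout={"1mo": 0.0, "3mo": 0.0, "12mo": 0.0}, seed=21)
    cohort, truth, _ = mlsm.simulate_cohort(cfg)
    return cohort, truth


def make_table_cohort(atlas, n=16, seed=3, untestable_threshold=-100.0,
                      untestable_prob=0.0, noise_sd=0.5):
    """Cohort built from synthetic tables alone (no lesion volumes).

    LLVs are drawn directly, so score-convention tests run in milliseconds.
    The two first ROIs carry strong negative weights.
    """
    rng = np.random.default_rng(seed)
    cov = simulate_covariates(n, rng)
    ids = list(cov["patient_id"])
    labels = atlas.roi_labels
    llv = pd.DataFrame(rng.uniform(0, 1, (n, len(labels))) ** 2,
                       index=pd.Index(ids, name="patient_id"),
                       columns=[f"llv_{lab}" for lab in labels])
    weights = np.zeros(len(labels))
    weights[:2] = (-6.0, -5.0)
    extents = pd.Series(rng.uniform(1, 120, n), index=ids)
    truth_params = {
        "roi_weights": weights, "informative_rois": np.array([0, 1]),
        "size_coefficient": 0.0, "baseline": 9.5,
        "noise_sd": {tp: noise_sd for tp in TIMEPOINTS}, "subscore_sd": 0.8,
        "recovery_fractions": {"1mo": 0.25, "3mo": 0.35, "12mo": 0.5},
        "untestable_threshold": untestable_threshold, "untestable_prob": untestable_prob,
    }
    scores, true_scores = simulate_scores(llv, extents, truth_params, rng)
    cov = cov.set_index("patient_id")
    cov["lesion_extent_cm3"] = extents
    cohort = mlsm.Cohort(atlas=atlas, llv=llv, covariates=cov, scores=scores)
    return cohort, true_scores


@pytest.fixture(scope="session")
def untestable_cohort(small_atlas):
    """Table-only cohort containing both untestable and testable acute patients."""
    cohort, true_scores = make_table_cohort(small_atlas, n=24, seed=11,
                                            untestable_threshold=7.0,
                                            untestable_prob=1.0)
    n_untestable = int(true_scores.loc[true_scores["timepoint"] == "acute",
                                       "untestable"].sum())
    assert 1 <= n_untestable <= 23, "fixture must mix untestable and testable patients"
    return cohort, true_scores
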