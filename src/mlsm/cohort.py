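"""Cohort container: atlas + per-patient lesion features + clinical tables.

A cohort directory (as written by the synthetic generator, and matching
what a real study export would look like) holds::

    cohort/
      atlas.nii.gz        labeled parcellation volume
      atlas_rois.tsv      label / name / tissue_class table
      lesions/<id>.nii.gz binary lesion mask per patient
      covariates.tsv      one row per patient
      scores.tsv          long table: patient_id, timepoint, outcome, value

Scores may be missing either as empty fields or as absent rows; both mean
the same thing. Building a :class:`Cohort` smooths every lesion mask and
precomputes lesion load vectors and lesion extents, so downstream feature
assembly never touches voxel data again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FeaturizationError
from .features import DEMOGRAPHIC_COLUMNS, OUTCOMES, TIMEPOINTS, compute_llv, lesion_extent_cm3
from .imaging import AtlasDefinition, LesionVolume, gaussian_smooth, load_atlas, load_volume

logger = logging.getLogger("mlsm")

DEFAULT_FWHM_MM = 8.0


@dataclass
class Cohort:
    """Featurized cohort ready for model fitting.

    ``llv`` is indexed by patient_id with one column per atlas ROI (in
    roi_table order); ``covariates`` is indexed by patient_id and includes
    ``lesion_extent_cm3``; ``scores`` is the long score table with NaN for
    missing values.
    """

    atlas: AtlasDefinition
    llv: pd.DataFrame
    covariates: pd.DataFrame
    scores: pd.DataFrame
    fwhm_mm: float = DEFAULT_FWHM_MM
    _score_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"patient_id", "timepoint", "outcome", "value"}
        if not required.issubset(self.scores.columns):
            raise FeaturizationError(f"scores table must have columns {sorted(required)}")
        bad_tp = set(self.scores["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise FeaturizationError(f"unknown timepoints in scores table: {sorted(bad_tp)}")
        bad_out = set(self.scores["outcome"]) - set(OUTCOMES)
        if bad_out:
            raise FeaturizationError(f"unknown outcomes in scores table: {sorted(bad_out)}")
        vals = self.scores["value"].dropna()
        if len(vals) and (vals.min() < 0 or vals.max() > 10):
            raise FeaturizationError("scores must lie in [0,10]")

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.covariates.index)

    @property
    def n_patients(self) -> int:
        return len(self.covariates)

    def scores_for(self, outcome: str, timepoint: str) -> pd.Series:
        """Scores for one outcome × timepoint, indexed by patient_id (NaN = missing)."""
        key = (outcome, timepoint)
        if key not in self._score_cache:
            sub = self.scores[(self.scores["outcome"] == outcome)
                              & (self.scores["timepoint"] == timepoint)]
            series = sub.set_index("patient_id")["value"].astype(float)
            self._score_cache[key] = series.reindex(self.patient_ids)
        return self._score_cache[key]

    def case_count(self, outcome: str, timepoint: str) -> int:
        return int(self.scores_for(outcome, timepoint).notna().sum())


def build_cohort(atlas: AtlasDefinition, lesions: dict[str, LesionVolume],
                 covariates: pd.DataFrame, scores: pd.DataFrame,
                 fwhm_mm: float = DEFAULT_FWHM_MM) -> Cohort:
    """Smooth binary lesions, compute LLVs and extents, assemble a Cohort.

    ``lesions`` maps patient_id to the *binary pre-smoothing* mask. Lesion
    extent is taken from the binary mask; LLVs from the smoothed mask.
    """
    records = {}
    extents = {}
    for pid in sorted(lesions):
        mask = lesions[pid]
        extents[pid] = lesion_extent_cm3(mask)
        smoothed = gaussian_smooth(mask, fwhm_mm=fwhm_mm)
        records[pid] = compute_llv(smoothed, atlas)
    llv = pd.DataFrame.from_dict(records, orient="index",
                                 columns=[f"llv_{lab}" for lab in atlas.roi_labels])
    llv.index.name = "patient_id"
    cov = covariates.copy()
    if cov.index.name != "patient_id":
        cov = cov.set_index("patient_id")
    cov["lesion_extent_cm3"] = pd.Series(extents).reindex(cov.index)
    missing_lesions = sorted(set(cov.index) - set(llv.index))
    if missing_lesions:
        raise FeaturizationError(f"patients without lesion masks: {missing_lesions}")
    return Cohort(atlas=atlas, llv=llv, covariates=cov, scores=scores.reset_index(drop=True),
                  fwhm_mm=fwhm_mm)


def load_cohort(path: str | Path, fwhm_mm: float = DEFAULT_FWHM_MM) -> Cohort:
    """Load a cohort directory from disk and featurize it."""
    path = Path(path)
    atlas = load_atlas(path / "atlas.nii.gz", path / "atlas_rois.tsv")
    covariates = pd.read_csv(path / "covariates.tsv", sep="\t", dtype={"patient_id": str})
    missing_cols = set(("patient_id",) + DEMOGRAPHIC_COLUMNS) - set(covariates.columns)
    if missing_cols:
        raise FeaturizationError(f"covariates.tsv missing columns {sorted(missing_cols)}")
    scores = pd.read_csv(path / "scores.tsv", sep="\t", dtype={"patient_id": str})
    lesion_dir = path / "lesions"
    lesions: dict[str, LesionVolume] = {}
    for pid in covariates["patient_id"]:
        lesion_path = lesion_dir / f"{pid}.nii.gz"
        if not lesion_path.exists():
            lesion_path = lesion_dir / f"{pid}.nii"
        lesions[pid] = load_volume(lesion_path, expect_binary=True, patient_id=pid)
    logger.info("loaded cohort of %d patients from %s", len(lesions), path)
    return build_cohort(atlas, lesions, covariates, scores, fwhm_mm=fwhm_mm)
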