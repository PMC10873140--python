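"""Predictor construction: lesion load vectors, covariates, model families.

A lesion load vector (LLV) summarises one patient's (smoothed) lesion as
the lesioned proportion of each atlas ROI — one value in [0,1] per ROI, in
fixed roi_table order. Model families combine LLVs with lesion extent,
demographic/stroke covariates and, optionally, initial presentation (the
acute overall language score):

================================  ====  =======  ===========  ==
family                            LLVs  extent   demographic  IP
================================  ====  =======  ===========  ==
llv                               yes   yes      yes          no
llv_ip                            yes   yes      yes          yes
reduced_no_llv                    no    yes      yes          no
reduced_no_llv_ip                 no    yes      yes          yes
reduced_no_llv_no_extent          no    no       yes          no
reduced_no_llv_no_extent_ip       no    no       yes          yes
================================  ====  =======  ===========  ==

Covariates other than the LLVs are min–max scaled; scaling parameters are
always learned on the training cases only and applied (with clipping) to
held-out cases, so cross-validation stays leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, FeaturizationError, GridMismatchError
from .imaging import AtlasDefinition, LesionVolume, check_same_grid

OUTCOMES = (
    "overall",
    "word_comprehension",
    "sentence_comprehension",
    "word_finding",
    "grammatical_construction",
    "speech_motor_programming",
    "speech_motor_execution",
    "repetition",
    "reading",
)
SUBSCORES = OUTCOMES[1:]
TIMEPOINTS = ("acute", "1mo", "3mo", "12mo")
FOLLOWUP_TIMEPOINTS = TIMEPOINTS[1:]

DEMOGRAPHIC_COLUMNS = ("age", "sex", "handedness", "education", "stroke_type")

#: Single-column numeric codes for the categorical covariates. Handedness is
#: treated as ordinal (right / ambidextrous / left) so each covariate stays
#: one predictor column.
SEX_CODES = {"M": 0.0, "F": 1.0}
STROKE_TYPE_CODES = {"ischaemic": 0.0, "haemorrhagic": 1.0}
HANDEDNESS_CODES = {"R": 1.0, "A": 0.5, "L": 0.0}


@dataclass(frozen=True)
class ModelFamily:
    """Which predictor blocks a model family includes."""

    name: str
    llv: bool
    extent: bool
    ip: bool


FAMILIES: dict[str, ModelFamily] = {
    f.name: f
    for f in (
        ModelFamily("llv", llv=True, extent=True, ip=False),
        ModelFamily("llv_ip", llv=True, extent=True, ip=True),
        ModelFamily("reduced_no_llv", llv=False, extent=True, ip=False),
        ModelFamily("reduced_no_llv_ip", llv=False, extent=True, ip=True),
        ModelFamily("reduced_no_llv_no_extent", llv=False, extent=False, ip=False),
        ModelFamily("reduced_no_llv_no_extent_ip", llv=False, extent=False, ip=True),
    )
}

#: For the location-information comparison, each LLV-bearing family is read
#: against the reduction that drops only the LLVs.
REDUCTION_OF = {"llv": "reduced_no_llv", "llv_ip": "reduced_no_llv_ip"}


def get_family(family: str | ModelFamily) -> ModelFamily:
    if isinstance(family, ModelFamily):
        return family
    try:
        return FAMILIES[family]
    except KeyError:
        raise FeaturizationError(
            f"unknown model family {family!r}; valid families: {sorted(FAMILIES)}") from None


def compute_llv(lesion: LesionVolume, atlas: AtlasDefinition) -> np.ndarray:
    """Lesioned proportion of each atlas ROI for one (smoothed) lesion.

    For ROI r the load is sum(lesion values over voxels labeled r) divided
    by the ROI's voxel count, clipped to [0,1]. Returns one value per ROI
    in roi_table order.
    """
    if not check_same_grid(lesion, atlas):
        raise GridMismatchError(
            f"lesion {lesion.patient_id!r} and atlas are not on the same voxel grid")
    flat_labels = atlas.labels.ravel()
    minlength = int(atlas.roi_labels.max()) + 1
    sums = np.bincount(flat_labels, weights=lesion.values.ravel(), minlength=minlength)
    counts = np.bincount(flat_labels, minlength=minlength)
    loads = sums[atlas.roi_labels] / counts[atlas.roi_labels]
    return np.clip(loads, 0.0, 1.0)


def lesion_extent_cm3(lesion: LesionVolume) -> float:
    """Total lesion volume in cm³ from the binary, pre-smoothing mask."""
    if not lesion.is_binary:
        raise ContractError("lesion extent is defined on the binary pre-smoothing mask")
    return lesion.n_lesioned_voxels * lesion.grid.voxel_volume_mm3 / 1000.0


def encode_covariates(rows: pd.DataFrame) -> pd.DataFrame:
    """Map categorical covariates to their fixed numeric codes.

    Expects columns age, sex, handedness, education, stroke_type (plus any
    numeric extras such as lesion_extent_cm3, passed through unchanged).
    """
    out = rows.copy()
    for col, codes in (("sex", SEX_CODES), ("handedness", HANDEDNESS_CODES),
                       ("stroke_type", STROKE_TYPE_CODES)):
        if col not in out.columns:
            continue
        if out[col].dtype == object or isinstance(out[col].dtype, pd.CategoricalDtype):
            unknown = set(out[col].dropna()) - set(codes)
            if unknown:
                raise FeaturizationError(f"unknown {col} categories {sorted(unknown)}")
            out[col] = out[col].map(codes)
    return out.astype(float)


def minmax_scale_train_apply(train: np.ndarray, apply: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise min–max scaling learned on ``train``, applied to both.

    Held-out values outside the training range are clipped to [0,1];
    constant training columns map to 0 everywhere.
    """
    train = np.asarray(train, dtype=float)
    apply = np.asarray(apply, dtype=float)
    lo = train.min(axis=0)
    span = train.max(axis=0) - lo
    constant = span == 0
    span = np.where(constant, 1.0, span)
    t = (train - lo) / span
    a = np.clip((apply - lo) / span, 0.0, 1.0)
    t[:, constant] = 0.0
    if a.size:
        a[:, constant] = 0.0
    return t, a


def encode_and_scale_covariates(train_rows: pd.DataFrame,
                                apply_rows: pd.DataFrame | None = None,
                                columns: tuple[str, ...] | None = None,
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Encode categoricals and min–max scale, training-set parameters only.

    Missing values in a used column raise :class:`FeaturizationError` — the
    caller must exclude those cases, never impute them silently.
    """
    if apply_rows is None:
        apply_rows = train_rows.iloc[:0]
    if columns is None:
        columns = tuple(train_rows.columns)
    if len(train_rows) == 0:
        raise FeaturizationError("training covariate rows are empty")
    train_enc = encode_covariates(train_rows[list(columns)])
    apply_enc = encode_covariates(apply_rows[list(columns)])
    for name, frame in (("train", train_enc), ("apply", apply_enc)):
        if frame.isna().any().any():
            bad = sorted(frame.columns[frame.isna().any()])
            raise FeaturizationError(
                f"missing covariate values in {name} rows (columns {bad}); "
                "exclude these cases rather than imputing")
    t, a = minmax_scale_train_apply(train_enc.to_numpy(), apply_enc.to_numpy())
    return (pd.DataFrame(t, index=train_enc.index, columns=columns),
            pd.DataFrame(a, index=apply_enc.index, columns=columns))


@dataclass
class FeatureMatrix:
    """Per-patient predictor rows and response for one model cell.

    ``X`` holds *raw* (encoded but unscaled) values; ``scale_mask`` marks
    the columns that must be min–max scaled at fit time, on the training
    cases of each fold. LLV columns are natively in [0,1] and never scaled.
    """

    family: ModelFamily
    outcome: str
    timepoint: str
    patient_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    scale_mask: np.ndarray
    llv_labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_excluded_missing_covariates: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape != (len(self.patient_ids), len(self.column_names)):
            raise FeaturizationError("feature matrix shape mismatch")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise FeaturizationError("feature matrix must not contain missing entries")

    @property
    def n_cases(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.column_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=pd.Index(self.patient_ids, name="patient_id"),
                          columns=self.column_names)
        df["__response__"] = self.y
        return df


def assemble_features(cohort, outcome: str, timepoint: str,
                      family: str | ModelFamily) -> FeatureMatrix:
    """Build the predictor matrix for one outcome × timepoint × family cell.

    Cases are restricted to patients with a non-missing response at the
    requested timepoint (and a non-missing acute overall score for IP
    families); rows are sorted by patient id so assembly is deterministic.
    """
    fam = get_family(family)
    if outcome not in OUTCOMES:
        raise FeaturizationError(f"unknown outcome {outcome!r}; valid: {list(OUTCOMES)}")
    if timepoint not in TIMEPOINTS:
        raise FeaturizationError(f"unknown timepoint {timepoint!r}; valid: {list(TIMEPOINTS)}")
    if fam.ip and timepoint == "acute":
        raise FeaturizationError(
            "IP families use the acute overall score as a predictor and are "
            "only defined for the 1mo, 3mo and 12mo timepoints")

    response = cohort.scores_for(outcome, timepoint).dropna()
    ids = sorted(response.index)
    if fam.ip:
        acute_overall = cohort.scores_for("overall", "acute").dropna()
        ids = [i for i in ids if i in acute_overall.index]

    cov_cols = (("lesion_extent_cm3",) if fam.extent else ()) + DEMOGRAPHIC_COLUMNS + \
        (("acute_overall",) if fam.ip else ())
    cov = cohort.covariates.reindex(ids).copy()
    if fam.ip:
        cov["acute_overall"] = cohort.scores_for("overall", "acute").reindex(ids)
    cov = encode_covariates(cov[list(cov_cols)])
    complete = ~cov.isna().any(axis=1)
    n_excluded = int((~complete).sum())
    ids = [i for i, ok in zip(ids, complete) if ok]
    if not ids:
        raise FeaturizationError(
            f"no eligible cases for outcome={outcome!r}, timepoint={timepoint!r}, "
            f"family={fam.name!r}")
    cov = cov.loc[ids]

    blocks: list[np.ndarray] = []
    names: list[str] = []
    scale: list[bool] = []
    llv_labels = np.array([], dtype=int)
    if fam.llv:
        llv_labels = cohort.atlas.roi_labels
        llv_block = cohort.llv.reindex(ids).to_numpy()
        if np.isnan(llv_block).any():
            missing = sorted(set(ids) - set(cohort.llv.index))
            raise FeaturizationError(f"patients without lesion data: {missing}")
        blocks.append(llv_block)
        names.extend(f"llv_{lab}" for lab in llv_labels)
        scale.extend([False] * len(llv_labels))
    blocks.append(cov.to_numpy())
    names.extend(cov_cols)
    scale.extend([True] * len(cov_cols))

    return FeatureMatrix(
        family=fam, outcome=outcome, timepoint=timepoint, patient_ids=list(ids),
        X=np.hstack(blocks), y=response.reindex(ids).to_numpy(),
        column_names=names, scale_mask=np.asarray(scale, dtype=bool),
        llv_labels=llv_labels, n_excluded_missing_covariates=n_excluded)
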