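"""Linear epsilon-insensitive SVR with leave-one-out cross-validation.

The estimator mirrors the default linear support vector regression used in
lesion-symptom mapping studies: box constraint C = 1 and epsilon set to
IQR(response)/13.49, a robust estimate of 0.1 sigma for Gaussian data.
Predictions are capped to the score range [0, 10].

Cross-validation is strictly leakage-free: for every held-out patient the
min–max scaling parameters, the epsilon value and the SVR weights are all
recomputed on the remaining patients only.

The public surface follows the model/results convention: build a
:class:`LesionSymptomSVR` from a cohort or a feature matrix, call
``fit()`` for a full-sample fit or ``fit_loocv()`` for out-of-sample
predictions; both return an :class:`SvrResults` with weights, diagnostics
and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .errors import ContractError, EvaluationError
from .features import FeatureMatrix, assemble_features, get_family

logger = logging.getLogger("mlsm")

SCORE_RANGE = (0.0, 10.0)
#: IQR divisor: 13.49 ≈ 2 × 1.349 × 5, i.e. epsilon targets one tenth of a
#: robust sigma estimate (IQR/1.349) scaled by the default heuristic.
EPSILON_IQR_DIVISOR = 13.49


@dataclass(frozen=True)
class SvrHyperparams:
    """Hyperparameters of the linear epsilon-insensitive SVR.

    ``epsilon`` of None means "use the IQR(response)/13.49 rule on the
    training responses of each fit". ``gamma`` is carried for fidelity to
    the default parameterization but has no effect with a linear kernel.
    """

    box_constraint: float = 1.0
    epsilon: float | None = None
    kernel: str = "linear"
    gamma: float = 1.0
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.box_constraint <= 0:
            raise ContractError("box_constraint must be positive")
        if self.epsilon is not None and self.epsilon < 0:
            raise ContractError("epsilon must be nonnegative")
        if self.kernel != "linear":
            raise ContractError("only the linear kernel is supported")


def compute_epsilon(response: np.ndarray,
                    divisor: float = EPSILON_IQR_DIVISOR) -> float:
    """Epsilon-insensitivity width: IQR(response)/13.49.

    Quartiles use linear interpolation between order statistics. A constant
    response yields epsilon 0 with a warning logged.
    """
    response = np.asarray(response, dtype=float)
    if response.size < 2:
        raise ContractError("epsilon rule needs at least 2 response values")
    q1, q3 = np.percentile(response, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        logger.warning("constant response: epsilon set to 0")
    return float(iqr / divisor)


def predict_capped(weights: np.ndarray, intercept: float, rows: np.ndarray,
                   score_range: tuple[float, float] = SCORE_RANGE) -> np.ndarray:
    """Raw linear prediction clamped to the score range."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != len(weights):
        raise ContractError(
            f"row width {rows.shape[1]} does not match model width {len(weights)}")
    raw = rows @ np.asarray(weights, dtype=float) + intercept
    return np.clip(raw, *score_range)


def _fit_scaled_svr(X_scaled: np.ndarray, y: np.ndarray,
                    hyper: SvrHyperparams) -> tuple[np.ndarray, float, float]:
    """Fit the SVR on already-scaled features; return (weights, intercept, epsilon)."""
    eps = hyper.epsilon if hyper.epsilon is not None else compute_epsilon(y)
    if hyper.gamma != 1.0:
        logger.debug("gamma=%s recorded but has no effect under a linear kernel", hyper.gamma)
    svr = SVR(kernel="linear", C=hyper.box_constraint, epsilon=eps, tol=hyper.tol,
              cache_size=200, max_iter=-1)
    svr.fit(X_scaled, y)
    return svr.coef_.ravel().astype(float), float(svr.intercept_[0]), float(eps)


@dataclass
class _ScalingParams:
    lo: np.ndarray
    span: np.ndarray
    constant: np.ndarray
    scale_mask: np.ndarray

    @classmethod
    def fit(cls, X_train: np.ndarray, scale_mask: np.ndarray) -> "_ScalingParams":
        cols = X_train[:, scale_mask]
        lo = cols.min(axis=0) if cols.size else np.array([])
        hi = cols.max(axis=0) if cols.size else np.array([])
        span = hi - lo
        constant = span == 0
        return cls(lo=lo, span=np.where(constant, 1.0, span), constant=constant,
                   scale_mask=scale_mask)

    def transform(self, X: np.ndarray, clip: bool) -> np.ndarray:
        X = np.array(X, dtype=float, copy=True)
        if not self.scale_mask.any():
            return X
        cols = (X[:, self.scale_mask] - self.lo) / self.span
        if clip:
            cols = np.clip(cols, 0.0, 1.0)
        cols[:, self.constant] = 0.0
        X[:, self.scale_mask] = cols
        return X


@dataclass
class CvPredictionSet:
    """Paired observed / out-of-sample predicted scores for one model cell."""

    patient_ids: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    outcome: str
    timepoint: str
    family: str

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if len(self.observed) != len(self.predicted) or len(self.observed) != len(self.patient_ids):
            raise ContractError("observed/predicted/patient_ids must have equal length")
        if self.predicted.size and (self.predicted.min() < SCORE_RANGE[0]
                                    or self.predicted.max() > SCORE_RANGE[1]):
            raise ContractError("predictions must be capped to the score range")

    def __len__(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.patient_ids,
            "observed": self.observed,
            "predicted": self.predicted,
            "outcome": self.outcome,
            "timepoint": self.timepoint,
            "family": self.family,
        })


class LesionSymptomSVR:
    """Linear SVR lesion-symptom model for one outcome × timepoint × family.

    Parameters
    ----------
    features : FeatureMatrix
        Raw (unscaled) predictor rows plus response, as produced by
        :func:`mlsm.features.assemble_features`.
    hyperparams : SvrHyperparams, optional
        Box constraint / epsilon rule; defaults match the standard linear
        SVR parameterization (C=1, epsilon=IQR/13.49).

    Examples
    --------
    >>> model = LesionSymptomSVR.from_cohort(cohort, "overall", "12mo", "llv")
    >>> res = model.fit_loocv()
    >>> res.prediction_r2, res.rmse  # doctest: +SKIP
    """

    def __init__(self, features: FeatureMatrix,
                 hyperparams: SvrHyperparams | None = None) -> None:
        if features.n_cases < 2:
            raise ContractError("model fitting needs at least 2 cases")
        self.features = features
        self.hyperparams = hyperparams or SvrHyperparams()

    @classmethod
    def from_cohort(cls, cohort, outcome: str, timepoint: str, family: str,
                    hyperparams: SvrHyperparams | None = None) -> "LesionSymptomSVR":
        fm = assemble_features(cohort, outcome, timepoint, get_family(family))
        return cls(fm, hyperparams=hyperparams)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "SvrResults":
        """Full-sample fit (used for feature-weight extraction, not evaluation)."""
        fm = self.features
        scaling = _ScalingParams.fit(fm.X, fm.scale_mask)
        Xs = scaling.transform(fm.X, clip=False)
        w, b, eps = _fit_scaled_svr(Xs, fm.y, self.hyperparams)
        return SvrResults(model=self, weights=w, intercept=b, epsilon=eps,
                          scaling=scaling, cv=None)

    def fit_loocv(self) -> "SvrResults":
        """Leave-one-out cross-validated predictions plus a full-sample fit.

        For each held-out case the scaling parameters, epsilon and SVR
        weights are recomputed from the remaining cases only; the held-out
        row is scaled with training parameters (clipped to [0,1]) and its
        prediction capped to the score range.
        """
        fm = self.features
        n = fm.n_cases
        if n < 3:
            raise EvaluationError(f"leave-one-out evaluation needs >= 3 cases, got {n}")
        preds = np.empty(n)
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            X_train, y_train = fm.X[keep], fm.y[keep]
            scaling = _ScalingParams.fit(X_train, fm.scale_mask)
            w, b, _ = _fit_scaled_svr(scaling.transform(X_train, clip=False),
                                      y_train, self.hyperparams)
            row = scaling.transform(fm.X[i:i + 1], clip=True)
            preds[i] = predict_capped(w, b, row)[0]
        cv = CvPredictionSet(patient_ids=list(fm.patient_ids), observed=fm.y.copy(),
                             predicted=preds, outcome=fm.outcome, timepoint=fm.timepoint,
                             family=fm.family.name)
        full = self.fit()
        return replace(full, cv=cv)


@dataclass
class SvrResults:
    """Fitted weights plus (optionally) cross-validated predictions.

    ``weights`` act on *scaled* features; use :meth:`predict` on raw rows.
    """

    model: LesionSymptomSVR
    weights: np.ndarray
    intercept: float
    epsilon: float
    scaling: _ScalingParams
    cv: CvPredictionSet | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def column_names(self) -> list[str]:
        return self.model.features.column_names

    def predict(self, rows: np.ndarray) -> np.ndarray:
        """Capped predictions for raw (unscaled) feature rows."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return predict_capped(self.weights, self.intercept,
                              self.scaling.transform(rows, clip=True))

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.features.X)

    @property
    def prediction_r2(self) -> float:
        from .evaluation import prediction_r2
        if self.cv is None:
            raise EvaluationError("prediction_r2 requires fit_loocv() results")
        return prediction_r2(self.cv.observed, self.cv.predicted)

    @property
    def rmse(self) -> float:
        from .evaluation import rmse
        if self.cv is None:
            raise EvaluationError("rmse requires fit_loocv() results")
        return rmse(self.cv.observed, self.cv.predicted)

    def weight_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.column_names, name="weight")

    def summary(self) -> str:
        """Plain-text summary table in the style of statistical model results."""
        fm = self.model.features
        lines = [
            "Lesion-symptom SVR results",
            "=" * 58,
            f"outcome:    {fm.outcome:<24} timepoint: {fm.timepoint}",
            f"family:     {fm.family.name:<24} n cases:   {fm.n_cases}",
            f"features:   {fm.n_features:<24} epsilon:   {self.epsilon:.4f}",
            f"C:          {self.model.hyperparams.box_constraint:<24} kernel:    linear",
        ]
        if self.cv is not None:
            lines.append(f"LOOCV prediction r2: {self.prediction_r2:.4f}    "
                         f"RMSE: {self.rmse:.4f}")
        lines.append("-" * 58)
        ws = self.weight_series()
        top = ws.reindex(ws.abs().sort_values(ascending=False).index)[:10]
        lines.append("largest |weights|:")
        for name, w in top.items():
            lines.append(f"  {name:<32} {w:+.4f}")
        lines.append(f"  intercept{'':<23} {self.intercept:+.4f}")
        return "\n".join(lines)


def fit_svr(features: FeatureMatrix,
            hyperparams: SvrHyperparams | None = None) -> SvrResults:
    """Functional wrapper: full-sample fit of the linear SVR."""
    return LesionSymptomSVR(features, hyperparams=hyperparams).fit()


def loocv_predict(cohort, outcome: str, timepoint: str, family: str,
                  hyperparams: SvrHyperparams | None = None) -> CvPredictionSet:
    """Leave-one-out cross-validated predictions for one model cell."""
    model = LesionSymptomSVR.from_cohort(cohort, outcome, timepoint, family,
                                         hyperparams=hyperparams)
    res = model.fit_loocv()
    assert res.cv is not None
    return res.cv
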