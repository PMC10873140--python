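"""Out-of-sample accuracy metrics and the family × outcome × timepoint grid.

Prediction r² compares squared prediction error against the variance of
the observed scores around their own mean in the evaluated set:

    r² = 1 − Σ(obs − pred)² / Σ(obs − mean(obs))²

Unlike a squared correlation it is negative whenever the model predicts
worse than the mean — which epsilon-insensitive SVR can do when the
predictors carry no information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EvaluationError, FeaturizationError, MlsmError
from .features import OUTCOMES, REDUCTION_OF, TIMEPOINTS, get_family
from .modeling import CvPredictionSet, SvrHyperparams, loocv_predict

logger = logging.getLogger("mlsm")

LOW_N_THRESHOLD = 10


def prediction_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """1 − SSE/SST with SST around the evaluated-set mean of the observations."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise EvaluationError("observed and predicted must have equal length")
    if observed.size < 2:
        raise EvaluationError("prediction r2 needs at least 2 cases")
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        raise EvaluationError(
            "observed scores are constant: prediction r2 denominator undefined")
    sse = float(np.sum((observed - predicted) ** 2))
    return 1.0 - sse / sst


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean squared prediction error."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise EvaluationError("observed and predicted must have equal length")
    if observed.size == 0:
        raise EvaluationError("rmse needs at least 1 case")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


@dataclass
class EvaluationResult:
    """Cross-validated performance of one outcome × timepoint × family cell."""

    outcome: str
    timepoint: str
    family: str
    n: int
    prediction_r2: float
    rmse: float
    low_n: bool = False

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome, "timepoint": self.timepoint, "family": self.family,
            "n": self.n, "prediction_r2": self.prediction_r2, "rmse": self.rmse,
            "low_n": self.low_n,
        }


@dataclass
class ComparisonGrid:
    """Evaluation results over all requested cells, plus skips and predictions."""

    results: list[EvaluationResult]
    skipped: list[dict] = field(default_factory=list)
    prediction_sets: dict[tuple[str, str, str], CvPredictionSet] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.results]
        for s in self.skipped:
            rows.append({**{k: s[k] for k in ("outcome", "timepoint", "family")},
                         "n": 0, "prediction_r2": np.nan, "rmse": np.nan, "low_n": False,
                         "skip_reason": s["reason"]})
        df = pd.DataFrame(rows)
        if "skip_reason" not in df.columns:
            df["skip_reason"] = ""
        df["skip_reason"] = df["skip_reason"].fillna("")
        return df.sort_values(["outcome", "timepoint", "family"]).reset_index(drop=True)

    def lookup(self, outcome: str, timepoint: str, family: str) -> EvaluationResult | None:
        for r in self.results:
            if (r.outcome, r.timepoint, r.family) == (outcome, timepoint, family):
                return r
        return None

    def improvement_count(self) -> tuple[int, int]:
        """(cells where the LLV family beats its no-LLV reduction, comparable cells)."""
        better = total = 0
        for full_name, reduced_name in REDUCTION_OF.items():
            for r in self.results:
                if r.family != full_name:
                    continue
                red = self.lookup(r.outcome, r.timepoint, reduced_name)
                if red is None:
                    continue
                total += 1
                if r.prediction_r2 > red.prediction_r2:
                    better += 1
        return better, total


def evaluate_cell(cohort, outcome: str, timepoint: str, family: str,
                  hyperparams: SvrHyperparams | None = None,
                  ) -> tuple[EvaluationResult, CvPredictionSet]:
    """Fresh LOOCV run for one cell, scored with prediction r² and RMSE."""
    cv = loocv_predict(cohort, outcome, timepoint, family, hyperparams=hyperparams)
    n = len(cv)
    result = EvaluationResult(
        outcome=outcome, timepoint=timepoint, family=get_family(family).name, n=n,
        prediction_r2=prediction_r2(cv.observed, cv.predicted),
        rmse=rmse(cv.observed, cv.predicted), low_n=n < LOW_N_THRESHOLD)
    return result, cv


def build_comparison_grid(cohort, families=("llv", "reduced_no_llv"),
                          outcomes=OUTCOMES, timepoints=TIMEPOINTS,
                          hyperparams: SvrHyperparams | None = None) -> ComparisonGrid:
    """Evaluate every requested outcome × timepoint × family cell.

    IP families at the acute timepoint are skipped with a machine-readable
    reason (the acute score is among their predictors); per-cell failures
    (e.g. empty case sets) are recorded without aborting the grid.
    """
    grid = ComparisonGrid(results=[])
    for outcome in outcomes:
        for timepoint in timepoints:
            for family in families:
                fam = get_family(family)
                cell = dict(outcome=outcome, timepoint=timepoint, family=fam.name)
                if fam.ip and timepoint == "acute":
                    grid.skipped.append({**cell, "reason": "IP undefined at acute"})
                    continue
                try:
                    result, cv = evaluate_cell(cohort, outcome, timepoint, fam.name,
                                               hyperparams=hyperparams)
                except (FeaturizationError, EvaluationError, MlsmError) as exc:
                    logger.warning("cell %s skipped: %s", cell, exc)
                    grid.skipped.append({**cell, "reason": str(exc)})
                    continue
                logger.info("cell %s/%s/%s: n=%d r2=%.3f rmse=%.3f", outcome, timepoint,
                            fam.name, result.n, result.prediction_r2, result.rmse)
                grid.results.append(result)
                grid.prediction_sets[(outcome, timepoint, fam.name)] = cv
    better, total = grid.improvement_count()
    if total:
        logger.info("LLV families improved on their reductions in %d of %d cells",
                    better, total)
    return grid
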