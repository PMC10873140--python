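"""Topographic mapping of SVR feature weights back into brain space.

LLV feature weights from a full-sample refit are thresholded — keeping
negative weights more than one standard deviation below the mean of the
LLV weight population — and the surviving ROIs are painted into a volume,
each filled with the absolute weight magnitude. The map is descriptive:
no significance is attached to SVR coefficients.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from dataclasses import dataclass, field

from .errors import ContractError, MappingError
from .imaging import AtlasDefinition, VoxelGrid
from .modeling import SvrResults

logger = logging.getLogger("mlsm")


@dataclass
class WeightMapVolume:
    """Thresholded weight magnitudes painted into atlas space.

    Nonzero only inside selected ROIs; each selected ROI holds one constant
    value (the absolute SVR weight). ``metadata`` records provenance, in
    particular that weights come from a full-sample refit.
    """

    grid: VoxelGrid
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.dims):
            raise MappingError("weight map shape does not match grid dims")


def extract_weights(results: SvrResults, atlas: AtlasDefinition) -> pd.DataFrame:
    """Tabulate every model coefficient with its ROI linkage.

    Returns a WeightTable with columns column_name, weight, is_llv,
    roi_label (NaN for non-LLV predictors). The model must come from a
    full-sample refit on a feature matrix whose LLV columns match the
    atlas roi_table 1:1 and in order.
    """
    fm = results.model.features
    if fm.family.llv:
        if len(fm.llv_labels) != atlas.n_rois or \
                not np.array_equal(fm.llv_labels, atlas.roi_labels):
            raise MappingError("model LLV columns do not match the atlas roi_table")
    n_llv = len(fm.llv_labels)
    roi_label = np.full(len(results.weights), np.nan)
    roi_label[:n_llv] = fm.llv_labels
    table = pd.DataFrame({
        "column_name": results.column_names,
        "weight": results.weights,
        "is_llv": [i < n_llv for i in range(len(results.weights))],
        "roi_label": roi_label,
    })
    table.attrs["source"] = "full-sample refit on all eligible cases"
    table.attrs["outcome"] = fm.outcome
    table.attrs["timepoint"] = fm.timepoint
    table.attrs["family"] = fm.family.name
    return table


def threshold_negative_weights(table: pd.DataFrame, llv_only: bool = True,
                               ) -> pd.DataFrame:
    """Select weights more than 1 SD below the mean *and* negative.

    The mean and (population) SD are computed over the LLV weights by
    default — the map is spatial, so demographic coefficients are kept out
    of the reference population. A degenerate SD of 0 yields an empty
    selection with a warning.
    """
    pop = table[table["is_llv"]] if llv_only else table
    if len(pop) < 2:
        raise ContractError("thresholding needs at least 2 LLV weights")
    weights = pop["weight"].to_numpy(dtype=float)
    mu = float(weights.mean())
    sigma = float(weights.std(ddof=0))
    if sigma == 0:
        warnings.warn("weight population SD is 0: empty selection", stacklevel=2)
        logger.warning("weight population SD is 0: empty selection")
        empty = table.iloc[0:0].copy()
        empty.attrs.update(table.attrs)
        return empty
    selected = table[table["is_llv"] & (table["weight"] < mu - sigma)
                     & (table["weight"] < 0)].copy()
    selected.attrs.update(table.attrs)
    logger.info("threshold mu-sigma=%.4f selects %d of %d LLV weights",
                mu - sigma, len(selected), len(pop))
    return selected


def project_to_volume(selected: pd.DataFrame, atlas: AtlasDefinition) -> WeightMapVolume:
    """Paint |weight| of each selected ROI into atlas space.

    Voxels of each selected ROI take the ROI's absolute weight magnitude;
    everything else is 0.
    """
    if len(selected) and not selected["is_llv"].all():
        raise MappingError("only LLV weights can be projected to brain space")
    unknown = set(selected["roi_label"].astype(int)) - set(atlas.roi_labels.tolist())
    if unknown:
        raise MappingError(f"unknown roi labels {sorted(unknown)}")
    values = np.zeros(atlas.grid.dims, dtype=float)
    for _, row in selected.iterrows():
        values[atlas.labels == int(row["roi_label"])] = abs(float(row["weight"]))
    meta = {k: selected.attrs.get(k) for k in ("source", "outcome", "timepoint", "family")
            if k in selected.attrs}
    return WeightMapVolume(grid=atlas.grid, values=values, metadata=meta)


def weight_map(results: SvrResults, atlas: AtlasDefinition,
               llv_only: bool = True) -> tuple[WeightMapVolume, pd.DataFrame, pd.DataFrame]:
    """Convenience path: extract → threshold → project.

    Returns (volume, full weight table, selected subset).
    """
    table = extract_weights(results, atlas)
    selected = threshold_negative_weights(table, llv_only=llv_only)
    return project_to_volume(selected, atlas), table, selected
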