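"""Figures: prediction-r² bar grids and observed-vs-predicted scatters.

All plots are regenerable from the serialized tables alone; nothing here
holds analysis state.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .features import TIMEPOINTS  # noqa: E402

#: Bar styling mirrors the usual tiering: demographic-only models unfilled,
#: +lesion-extent hatched, +lesion-location solid.
_FAMILY_STYLE = {
    "reduced_no_llv_no_extent": dict(facecolor="white", edgecolor="black"),
    "reduced_no_llv_no_extent_ip": dict(facecolor="white", edgecolor="black"),
    "reduced_no_llv": dict(facecolor="lightgrey", edgecolor="black", hatch="//"),
    "reduced_no_llv_ip": dict(facecolor="lightgrey", edgecolor="black", hatch="//"),
    "llv": dict(facecolor="tab:blue", edgecolor="black"),
    "llv_ip": dict(facecolor="tab:blue", edgecolor="black"),
}


def plot_comparison_grid(grid_df: pd.DataFrame, path: str | Path) -> Path:
    """Grouped prediction-r² bars: one panel per outcome, bars per family."""
    df = grid_df[grid_df["prediction_r2"].notna()]
    outcomes = list(dict.fromkeys(df["outcome"]))
    families = list(dict.fromkeys(df["family"]))
    timepoints = [t for t in TIMEPOINTS if t in set(df["timepoint"])]
    ncol = min(3, max(1, len(outcomes)))
    nrow = int(np.ceil(len(outcomes) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4.2 * ncol, 2.8 * nrow),
                             squeeze=False, sharey=True)
    width = 0.8 / max(1, len(families))
    for k, outcome in enumerate(outcomes):
        ax = axes[k // ncol][k % ncol]
        sub = df[df["outcome"] == outcome]
        x = np.arange(len(timepoints))
        for j, fam in enumerate(families):
            vals = [sub[(sub["timepoint"] == tp) & (sub["family"] == fam)]
                    ["prediction_r2"].mean() for tp in timepoints]
            ax.bar(x + j * width, vals, width=width, label=fam,
                   **_FAMILY_STYLE.get(fam, {}))
        ax.axhline(0, color="black", lw=0.8)
        ax.set_xticks(x + width * (len(families) - 1) / 2)
        ax.set_xticklabels(timepoints)
        ax.set_title(outcome, fontsize=9)
        if k % ncol == 0:
            ax.set_ylabel("prediction $r^2$")
    for k in range(len(outcomes), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    axes[0][0].legend(fontsize=6, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_observed_vs_predicted(cv, path: str | Path) -> Path:
    """Scatter of observed against out-of-sample predicted scores."""
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.plot([0, 10], [0, 10], color="grey", lw=0.8, zorder=0)
    ax.scatter(cv.predicted, cv.observed, s=12, alpha=0.6)
    ax.set_xlim(-0.3, 10.3)
    ax.set_ylim(-0.3, 10.3)
    ax.set_xlabel("predicted")
    ax.set_ylabel("observed")
    ax.set_title(f"{cv.outcome} / {cv.timepoint} / {cv.family} (n={len(cv)})", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_weight_map(volume, path: str | Path, n_slices: int = 6) -> Path:
    """Axial montage of a back-projected weight map."""
    data = volume.values
    nz = data.shape[2]
    picks = np.linspace(nz // 6, nz - nz // 6 - 1, n_slices).astype(int)
    fig, axes = plt.subplots(1, n_slices, figsize=(2.0 * n_slices, 2.2))
    vmax = data.max() or 1.0
    for ax, z in zip(np.atleast_1d(axes), picks):
        ax.imshow(data[:, :, z].T, origin="lower", cmap="hot", vmin=0, vmax=vmax)
        ax.set_title(f"z={z}", fontsize=7)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
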