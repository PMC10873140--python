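"""End-to-end orchestration from a single declarative YAML config.

A run is: obtain a cohort (simulate or load) → featurize → fit/evaluate
the comparison grid with LOOCV → map the feature weights of a designated
cell back to brain space → write tables, volumes, figures and a manifest.
Reruns with the same config and seed are value-identical.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import load_cohort
from .errors import ConfigError, MlsmError
from .evaluation import build_comparison_grid
from .features import FAMILIES, OUTCOMES, TIMEPOINTS, get_family
from .imaging import write_volume
from .modeling import LesionSymptomSVR, SvrHyperparams
from .synthetic import SimConfig, simulate_cohort
from .weight_mapping import weight_map

logger = logging.getLogger("mlsm")

_TOP_LEVEL_KEYS = {
    "cohort_dir", "simulate", "families", "outcomes", "timepoints", "fwhm_mm",
    "box_constraint", "outdir", "seed", "log_level", "map_weights", "figures",
}
_MAP_WEIGHTS_KEYS = {"outcome", "timepoint", "family"}
_SIMULATE_KEYS = {
    "n_patients", "grid_dims", "voxel_size_mm", "margin", "n_rois",
    "lesion_mean_cm3", "lesion_sd_cm3", "lesion_min_cm3", "lesion_max_cm3",
    "effect", "n_informative", "weight_range", "size_coefficient", "baseline",
    "noise_sd", "subscore_sd", "recovery_fractions", "dropout",
    "untestable_threshold", "untestable_prob", "fwhm_mm", "seed",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults filled in."""

    outdir: Path
    seed: int = 0
    cohort_dir: Path | None = None
    sim: SimConfig | None = None
    families: tuple[str, ...] = ("llv", "reduced_no_llv", "reduced_no_llv_no_extent")
    outcomes: tuple[str, ...] = OUTCOMES
    timepoints: tuple[str, ...] = TIMEPOINTS
    fwhm_mm: float = 8.0
    box_constraint: float = 1.0
    log_level: str = "INFO"
    map_weights_cell: dict = field(
        default_factory=lambda: {"outcome": "overall", "timepoint": "12mo", "family": "llv"})
    figures: bool = True


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown {where} keys {sorted(unknown)}; "
                          f"valid keys: {sorted(allowed)}")


def validate_config(raw: str | dict, base_dir: str | Path = ".") -> RunConfig:
    """Parse and validate a raw YAML config (text or mapping).

    Unknown keys are rejected; vocabulary values (families, outcomes,
    timepoints) are checked against the closed lists; referenced paths
    must exist; defaults (FWHM 8 mm, C = 1, epsilon rule IQR/13.49) fill
    any gaps.
    """
    if isinstance(raw, str):
        try:
            raw = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _reject_unknown(raw, _TOP_LEVEL_KEYS, "config")
    if ("cohort_dir" in raw) == ("simulate" in raw):
        raise ConfigError("config must set exactly one of 'cohort_dir' or 'simulate'")

    seed = int(raw.get("seed", 0))
    base_dir = Path(base_dir)

    cohort_dir = None
    sim = None
    if "cohort_dir" in raw:
        cohort_dir = Path(raw["cohort_dir"])
        if not cohort_dir.is_absolute():
            cohort_dir = base_dir / cohort_dir
        if not cohort_dir.is_dir():
            raise ConfigError(f"cohort_dir {cohort_dir} does not exist")
    else:
        sim_raw = raw["simulate"] or {}
        _reject_unknown(sim_raw, _SIMULATE_KEYS, "simulate")
        sim_raw = dict(sim_raw)
        for key in ("grid_dims", "weight_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        sim_raw.setdefault("seed", seed)
        if "fwhm_mm" in raw:
            sim_raw.setdefault("fwhm_mm", float(raw["fwhm_mm"]))
        try:
            sim = SimConfig(**sim_raw)
        except (TypeError, MlsmError) as exc:
            raise ConfigError(f"invalid simulate block: {exc}") from exc

    families = tuple(raw.get("families",
                             ("llv", "reduced_no_llv", "reduced_no_llv_no_extent")))
    bad = [f for f in families if f not in FAMILIES]
    if bad:
        raise ConfigError(f"unknown families {bad}; valid families: {sorted(FAMILIES)}")
    outcomes = tuple(raw.get("outcomes", OUTCOMES))
    bad = [o for o in outcomes if o not in OUTCOMES]
    if bad:
        raise ConfigError(f"unknown outcomes {bad}; valid outcomes: {list(OUTCOMES)}")
    timepoints = tuple(raw.get("timepoints", TIMEPOINTS))
    bad = [t for t in timepoints if t not in TIMEPOINTS]
    if bad:
        raise ConfigError(f"unknown timepoints {bad}; valid timepoints: {list(TIMEPOINTS)}")
    for fname in families:
        if get_family(fname).ip and all(t == "acute" for t in timepoints):
            raise ConfigError(
                f"family {fname!r} uses the acute score as a predictor and is "
                "undefined when only the acute timepoint is requested")

    mw = dict(raw.get("map_weights",
                      {"outcome": "overall", "timepoint": "12mo", "family": "llv"}))
    _reject_unknown(mw, _MAP_WEIGHTS_KEYS, "map_weights")
    mw.setdefault("outcome", "overall")
    mw.setdefault("timepoint", "12mo")
    mw.setdefault("family", "llv")
    if mw["outcome"] not in OUTCOMES or mw["timepoint"] not in TIMEPOINTS \
            or mw["family"] not in FAMILIES:
        raise ConfigError(f"invalid map_weights cell {mw}")

    outdir = Path(raw.get("outdir", "mlsm_run"))
    if not outdir.is_absolute():
        outdir = base_dir / outdir
    return RunConfig(
        outdir=outdir, seed=seed, cohort_dir=cohort_dir, sim=sim, families=families,
        outcomes=outcomes, timepoints=timepoints, fwhm_mm=float(raw.get("fwhm_mm", 8.0)),
        box_constraint=float(raw.get("box_constraint", 1.0)),
        log_level=str(raw.get("log_level", "INFO")).upper(),
        map_weights_cell=mw, figures=bool(raw.get("figures", True)))


def _versions() -> dict:
    import matplotlib
    import nibabel
    import pandas
    import scipy
    import sklearn

    from . import __version__
    return {
        "mlsm": __version__, "python": platform.python_version(),
        "numpy": np.__version__, "scipy": scipy.__version__,
        "pandas": pandas.__version__, "scikit-learn": sklearn.__version__,
        "nibabel": nibabel.__version__, "matplotlib": matplotlib.__version__,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run; returns the populated output directory.

    Outputs: ``grid.tsv`` (comparison grid), ``predictions/*.tsv`` (one
    per evaluated cell), ``weights.tsv`` / ``weights_selected.tsv`` /
    ``weight_map.nii.gz`` for the designated cell, optional figures, and
    ``manifest.json`` (config echo, seed, versions, timings, cell counts).
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {"seed": config.seed, "versions": _versions()}

    t0 = time.perf_counter()
    if config.sim is not None:
        cohort, truth, _raw = simulate_cohort(config.sim)
        manifest["cohort"] = {"source": "simulated", "n_patients": cohort.n_patients,
                              "effect": config.sim.effect}
    else:
        cohort = load_cohort(config.cohort_dir, fwhm_mm=config.fwhm_mm)
        manifest["cohort"] = {"source": str(config.cohort_dir),
                              "n_patients": cohort.n_patients}
    timings["cohort"] = time.perf_counter() - t0
    manifest["case_counts"] = {tp: cohort.case_count("overall", tp)
                               for tp in config.timepoints}

    t0 = time.perf_counter()
    hyper = SvrHyperparams(box_constraint=config.box_constraint)
    grid = build_comparison_grid(cohort, families=config.families,
                                 outcomes=config.outcomes, timepoints=config.timepoints,
                                 hyperparams=hyper)
    timings["fit_eval"] = time.perf_counter() - t0
    grid_df = grid.to_frame()
    grid_df.to_csv(outdir / "grid.tsv", sep="\t", index=False)
    pred_dir = outdir / "predictions"
    pred_dir.mkdir(exist_ok=True)
    for (outcome, timepoint, family), cv in grid.prediction_sets.items():
        cv.to_frame().to_csv(pred_dir / f"{outcome}__{timepoint}__{family}.tsv",
                             sep="\t", index=False)
    better, total = grid.improvement_count()
    manifest["llv_improvement"] = {"better": better, "comparable_cells": total}

    t0 = time.perf_counter()
    mw = config.map_weights_cell
    try:
        model = LesionSymptomSVR.from_cohort(cohort, mw["outcome"], mw["timepoint"],
                                             mw["family"], hyperparams=hyper)
        res = model.fit()
        volume, table, selected = weight_map(res, cohort.atlas)
        table.to_csv(outdir / "weights.tsv", sep="\t", index=False)
        selected.to_csv(outdir / "weights_selected.tsv", sep="\t", index=False)
        write_volume(volume, outdir / "weight_map.nii.gz")
        manifest["weight_map"] = {**mw, "n_selected": len(selected),
                                  "weights_from": "full-sample refit on all eligible cases"}
    except MlsmError as exc:
        logger.warning("weight mapping skipped: %s", exc)
        manifest["weight_map"] = {**mw, "skipped": str(exc)}
    timings["map_weights"] = time.perf_counter() - t0

    if config.figures:
        t0 = time.perf_counter()
        from . import plotting
        figdir = outdir / "figures"
        figdir.mkdir(exist_ok=True)
        plotting.plot_comparison_grid(grid_df, figdir / "prediction_r2_bars.png")
        for (outcome, timepoint, family), cv in grid.prediction_sets.items():
            if outcome == "overall":
                plotting.plot_observed_vs_predicted(
                    cv, figdir / f"scatter_{outcome}__{timepoint}__{family}.png")
        timings["figures"] = time.perf_counter() - t0

    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    manifest["config"] = _echo_config(config)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %s", outdir)
    return outdir


def _echo_config(config: RunConfig) -> dict:
    from dataclasses import asdict
    echo = {
        "outdir": str(config.outdir), "seed": config.seed,
        "families": list(config.families), "outcomes": list(config.outcomes),
        "timepoints": list(config.timepoints), "fwhm_mm": config.fwhm_mm,
        "box_constraint": config.box_constraint, "log_level": config.log_level,
        "map_weights": config.map_weights_cell, "figures": config.figures,
    }
    if config.cohort_dir is not None:
        echo["cohort_dir"] = str(config.cohort_dir)
    if config.sim is not None:
        echo["simulate"] = {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in asdict(config.sim).items()}
    return echo
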