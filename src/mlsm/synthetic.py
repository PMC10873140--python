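"""Synthetic stroke-cohort generator with known ground truth.

Emulates the statistical structure the lesion-symptom analysis assumes:

* a contiguous parcellation (multi-source region growth from seeded
  voxels) standing in for a left-hemisphere grey/white-matter atlas;
* contiguous lesions grown by random frontier expansion, with a
  heavy-tailed (log-normal) size distribution matched to a cohort mean of
  ~54 cm³ and range ~0.6–376 cm³;
* bounded 0–10 language scores driven either by a sparse ROI weight map
  ("location" ground truth) or by total lesion volume alone ("size"
  ground truth), plus Gaussian noise and clipping;
* longitudinal recovery toward the score ceiling, with nondecreasing
  per-timepoint recovery fractions;
* untestable acute patients (overall score 0, subscores missing) and
  independent follow-up dropout shrinking the cohort from 217 toward ~100
  at one/three months and ~74 at one year.

Everything is reproducible from a single seed, and the noiseless signal
behind every score is kept in a ground-truth sidecar so that parameter-
and ceiling-recovery can be tested without any external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, build_cohort
from .errors import GenerationError
from .features import SUBSCORES, TIMEPOINTS
from .imaging import AtlasDefinition, LesionVolume, VoxelGrid, write_atlas, write_volume

logger = logging.getLogger("mlsm")


@dataclass
class GroundTruth:
    """Generative parameters plus the noiseless signal behind every score.

    ``roi_weights`` is sparse (mostly zero, a few strongly negative
    entries) for location-driven cohorts and all-zero for size-driven
    ones, where ``size_coefficient`` carries the effect instead.
    ``true_scores`` stores per patient × timepoint the noiseless signal
    and the noisy pre-clip latent, enabling noise-ceiling estimation.
    """

    roi_weights: np.ndarray
    size_coefficient: float
    baseline: float
    noise_sd: dict[str, float]
    recovery_fractions: dict[str, float]
    informative_rois: np.ndarray
    true_scores: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        fr = [self.recovery_fractions[t] for t in TIMEPOINTS[1:]]
        if any(b < a for a, b in zip(fr, fr[1:])):
            raise GenerationError("recovery fractions must be nondecreasing over time")
        if any(v <= 0 for v in self.noise_sd.values()):
            raise GenerationError("noise SDs must be positive")

    def signal_for(self, timepoint: str) -> pd.Series:
        sub = self.true_scores[self.true_scores["timepoint"] == timepoint]
        return sub.set_index("patient_id")["signal"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the cohort scale of the target study population:
    217 acute patients, log-normal lesion sizes with mean 53.6 / SD 60.4
    cm³ clipped to [0.6, 376.4], follow-up dropout leaving roughly 102, 98
    and 74 patients at one, three and twelve months, and ~8% of patients
    untestable acutely.
    """

    n_patients: int = 217
    grid_dims: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    margin: int = 6
    n_rois: int = 150
    lesion_mean_cm3: float = 53.6
    lesion_sd_cm3: float = 60.4
    lesion_min_cm3: float = 0.6
    lesion_max_cm3: float = 376.4
    effect: str = "location"  # "location" | "size"
    n_informative: int = 5
    weight_range: tuple[float, float] = (-8.0, -4.0)
    # Size-only ground truth keeps the deficit proportional to lesion volume
    # on the 0-10 scale: the largest lesion (~376 cm³) maps to complete
    # impairment, so clipping never breaks the proportionality.
    size_coefficient: float = 0.025  # score points lost per cm³ (size effect)
    baseline: float = 9.5
    noise_sd: float = 0.8
    subscore_sd: float = 1.0
    recovery_fractions: dict = field(
        default_factory=lambda: {"1mo": 0.25, "3mo": 0.35, "12mo": 0.5})
    dropout: dict = field(default_factory=lambda: {"1mo": 0.53, "3mo": 0.55, "12mo": 0.66})
    untestable_threshold: float = 1.5
    untestable_prob: float = 0.6
    fwhm_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise GenerationError("a seed is mandatory for cohort generation")
        for t, p in self.dropout.items():
            if not 0.0 <= p <= 1.0:
                raise GenerationError(f"dropout probability for {t} must be in [0,1]")
        if not 0.0 <= self.untestable_prob <= 1.0:
            raise GenerationError("untestable_prob must be in [0,1]")
        if self.effect not in ("location", "size"):
            raise GenerationError("effect must be 'location' or 'size'")


# ---------------------------------------------------------------------------
# atlas


def make_synthetic_atlas(grid_dims=(64, 64, 64), n_rois=150, seed=0,
                         voxel_size_mm=2.0, margin=6, min_voxels=8,
                         max_tries=10) -> AtlasDefinition:
    """Partition the grid interior into contiguous parcels by seeded growth.

    ROI seed voxels are drawn uniformly from the interior box (a
    ``margin``-voxel background rim is kept on every face, standing in for
    non-brain space); parcels then grow by multi-source breadth-first
    expansion, which assigns every interior voxel to the graph-nearest
    seed and guarantees face-connected parcels. Seeds are redrawn up to
    ``max_tries`` times if any parcel ends up with fewer than
    ``min_voxels`` voxels.

    Tissue classes are assigned in the proportions of a combined
    grey/white/commissural parcellation (82% / 14% / 4%).
    """
    from collections import deque

    if n_rois < 2:
        raise GenerationError("n_rois must be >= 2")
    margin = max(1, int(margin))
    dims = tuple(int(d) for d in grid_dims)
    interior = [np.arange(margin, d - margin) for d in dims]
    if any(len(ax) <= 0 for ax in interior):
        raise GenerationError(f"grid {dims} too small for margin {margin}")
    n_interior = int(np.prod([len(ax) for ax in interior]))
    if n_rois * min_voxels > n_interior:
        raise GenerationError(
            f"cannot fit {n_rois} parcels of >= {min_voxels} voxels into "
            f"{n_interior} interior voxels")
    coords = np.stack(np.meshgrid(*interior, indexing="ij"), axis=-1).reshape(-1, 3)
    flat_coords = np.ravel_multi_index(tuple(coords.T), dims)
    interior_mask = np.zeros(int(np.prod(dims)), dtype=bool)
    interior_mask[flat_coords] = True
    offsets = _flat_neighbor_offsets(dims)
    rng = np.random.default_rng(seed)
    for attempt in range(max_tries):
        seeds = flat_coords[rng.choice(len(flat_coords), size=n_rois, replace=False)]
        flat_labels = np.zeros(interior_mask.size, dtype=np.int32)
        queue = deque()
        for i, s in enumerate(seeds):
            flat_labels[s] = i + 1
            queue.append(int(s))
        while queue:
            idx = queue.popleft()
            lab = flat_labels[idx]
            for off in offsets:
                nb = idx + off
                if 0 <= nb < interior_mask.size and interior_mask[nb] \
                        and flat_labels[nb] == 0:
                    flat_labels[nb] = lab
                    queue.append(nb)
        counts = np.bincount(flat_labels, minlength=n_rois + 1)[1:]
        if counts.min() >= min_voxels:
            break
    else:
        raise GenerationError(
            f"could not draw {n_rois} parcels of >= {min_voxels} voxels in "
            f"{max_tries} tries")
    labels = flat_labels.reshape(dims)
    n_grey = int(round(0.82 * n_rois))
    n_white = int(round(0.14 * n_rois))
    classes = (["grey"] * n_grey + ["white"] * n_white
               + ["commissural"] * (n_rois - n_grey - n_white))
    roi_table = pd.DataFrame({
        "label": np.arange(1, n_rois + 1),
        "name": [f"{cls}_roi_{i + 1:03d}" for i, cls in enumerate(classes)],
        "tissue_class": classes,
    })
    grid = VoxelGrid.isotropic(dims, voxel_size_mm)
    return AtlasDefinition(grid=grid, labels=labels, roi_table=roi_table)


# ---------------------------------------------------------------------------
# lesions


def _flat_neighbor_offsets(dims) -> np.ndarray:
    nx, ny, nz = dims
    return np.array([1, -1, nz, -nz, ny * nz, -ny * nz])


def simulate_lesion(atlas: AtlasDefinition, size_cm3: float,
                    rng: np.random.Generator, patient_id: str = "") -> LesionVolume:
    """Grow a contiguous binary lesion of (almost exactly) the target volume.

    Growth is uniform-random frontier expansion from a random labeled seed
    voxel, restricted to labeled (brain) voxels; the achieved voxel count
    equals the rounded target exactly unless the connected component is
    exhausted first.
    """
    voxvol = atlas.grid.voxel_volume_mm3
    target = max(1, int(round(size_cm3 * 1000.0 / voxvol)))
    brain = (atlas.labels > 0).ravel()
    n_brain = int(brain.sum())
    if target > 0.8 * n_brain:
        raise GenerationError(
            f"target {size_cm3:.1f} cm3 exceeds 80% of the labeled volume")
    offsets = _flat_neighbor_offsets(atlas.grid.dims)
    n_flat = brain.size
    brain_idx = np.flatnonzero(brain)
    seed_idx = int(brain_idx[rng.integers(len(brain_idx))])
    in_lesion = np.zeros(n_flat, dtype=bool)
    queued = np.zeros(n_flat, dtype=bool)
    frontier = [seed_idx]
    queued[seed_idx] = True
    count = 0
    while count < target and frontier:
        j = int(rng.integers(len(frontier)))
        idx = frontier[j]
        frontier[j] = frontier[-1]
        frontier.pop()
        in_lesion[idx] = True
        count += 1
        for off in offsets:
            nb = idx + off
            if 0 <= nb < n_flat and brain[nb] and not queued[nb]:
                queued[nb] = True
                frontier.append(int(nb))
    if count < target:
        raise GenerationError(
            f"connected component exhausted at {count} of {target} voxels")
    values = in_lesion.reshape(atlas.grid.dims).astype(np.float64)
    return LesionVolume(grid=atlas.grid, values=values, patient_id=patient_id,
                        is_binary=True)


def sample_lesion_sizes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-normal lesion sizes (cm³) matched to the configured mean/SD, clipped."""
    m, s = config.lesion_mean_cm3, config.lesion_sd_cm3
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    sizes = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=config.n_patients)
    return np.clip(sizes, config.lesion_min_cm3, config.lesion_max_cm3)


# ---------------------------------------------------------------------------
# covariates and scores


#: Covariate marginals for the emulated acute cohort (age years, education
#: years, category frequencies) — chosen to match the demographic profile
#: of a representative acute left-hemisphere stroke cohort.
COVARIATE_MARGINALS = {
    "age": (62.5, 13.6, 21.0, 90.0),
    "education": (12.9, 3.2, 0.0, 20.0),
    "sex": (("M", "F"), (117, 100)),
    "handedness": (("R", "L", "A"), (193, 19, 5)),
    "stroke_type": (("ischaemic", "haemorrhagic"), (174, 43)),
}


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Demographic/clinical covariates drawn from the configured marginals."""
    def cat(spec):
        values, freq = spec
        p = np.asarray(freq, dtype=float)
        return rng.choice(values, size=n, p=p / p.sum())

    mean, sd, lo, hi = COVARIATE_MARGINALS["age"]
    age = np.clip(rng.normal(mean, sd, size=n), lo, hi)
    mean, sd, lo, hi = COVARIATE_MARGINALS["education"]
    education = np.clip(np.round(rng.normal(mean, sd, size=n)), lo, hi)
    return pd.DataFrame({
        "patient_id": [f"p{i + 1:04d}" for i in range(n)],
        "age": np.round(age, 1),
        "sex": cat(COVARIATE_MARGINALS["sex"]),
        "handedness": cat(COVARIATE_MARGINALS["handedness"]),
        "education": education,
        "stroke_type": cat(COVARIATE_MARGINALS["stroke_type"]),
    })


def _clip_score(x: np.ndarray | float) -> np.ndarray | float:
    return np.clip(x, 0.0, 10.0)


def simulate_scores(llv: pd.DataFrame, extents: pd.Series, truth_params: dict,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the longitudinal score table plus the noiseless sidecar.

    The acute latent is ``baseline + roi_weights · llv − c · extent +
    noise``; follow-up latents move toward the ceiling of 10 by the
    timepoint's recovery fraction, with fresh noise. All observed scores
    are clipped to [0, 10]. Patients whose acute latent falls below the
    untestable threshold are, with the configured probability, recorded as
    untestable: overall 0, all acute subscores missing. Subscores are
    correlated perturbations of the overall latent.
    """
    w = np.asarray(truth_params["roi_weights"], dtype=float)
    if llv.shape[1] != len(w):
        raise GenerationError(
            f"llv has {llv.shape[1]} ROIs but ground truth has {len(w)} weights")
    baseline = truth_params["baseline"]
    c_size = truth_params["size_coefficient"]
    noise_sd = truth_params["noise_sd"]
    sub_sd = truth_params["subscore_sd"]
    recovery = truth_params["recovery_fractions"]
    ut_thresh = truth_params["untestable_threshold"]
    ut_prob = truth_params["untestable_prob"]

    ids = list(llv.index)
    signal_acute = baseline + llv.to_numpy() @ w - c_size * extents.reindex(ids).to_numpy()
    rows, truth_rows = [], []
    for i, pid in enumerate(ids):
        lat_acute = signal_acute[i] + rng.normal(0.0, noise_sd["acute"])
        untestable = bool(lat_acute < ut_thresh and rng.random() < ut_prob)
        truth_rows.append({"patient_id": pid, "timepoint": "acute",
                           "signal": signal_acute[i], "latent": lat_acute,
                           "untestable": untestable})
        overall_acute = 0.0 if untestable else float(_clip_score(lat_acute))
        rows.append({"patient_id": pid, "timepoint": "acute", "outcome": "overall",
                     "value": overall_acute})
        for sub in SUBSCORES:
            value = (np.nan if untestable
                     else float(_clip_score(lat_acute + rng.normal(0.0, sub_sd))))
            rows.append({"patient_id": pid, "timepoint": "acute", "outcome": sub,
                         "value": value})
        for tp in TIMEPOINTS[1:]:
            r = recovery[tp]
            signal_tp = signal_acute[i] + r * (10.0 - signal_acute[i])
            lat_tp = lat_acute + r * (10.0 - lat_acute) + rng.normal(0.0, noise_sd[tp])
            truth_rows.append({"patient_id": pid, "timepoint": tp,
                               "signal": signal_tp, "latent": lat_tp,
                               "untestable": False})
            rows.append({"patient_id": pid, "timepoint": tp, "outcome": "overall",
                         "value": float(_clip_score(lat_tp))})
            for sub in SUBSCORES:
                rows.append({"patient_id": pid, "timepoint": tp, "outcome": sub,
                             "value": float(_clip_score(lat_tp + rng.normal(0.0, sub_sd)))})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def apply_dropout(scores: pd.DataFrame, dropout: dict[str, float],
                  rng: np.random.Generator) -> pd.DataFrame:
    """Remove follow-up rows patient-wise, independently of severity.

    Each patient is retained at each follow-up timepoint with probability
    1 − dropout[t]; retention never looks at scores, so severity
    distributions of retained and dropped patients match in expectation.
    """
    out = scores
    for tp, p in dropout.items():
        if p == 0:
            continue
        ids = sorted(out.loc[out["timepoint"] == tp, "patient_id"].unique())
        dropped = {pid for pid in ids if rng.random() < p}
        out = out[~((out["timepoint"] == tp) & (out["patient_id"].isin(dropped)))]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort assembly


def _draw_ground_truth_params(config: SimConfig, rng: np.random.Generator) -> dict:
    weights = np.zeros(config.n_rois)
    informative = np.array([], dtype=int)
    size_coeff = 0.0
    if config.effect == "location":
        informative = np.sort(rng.choice(config.n_rois, size=config.n_informative,
                                         replace=False))
        lo, hi = config.weight_range
        weights[informative] = rng.uniform(lo, hi, size=config.n_informative)
    else:
        size_coeff = config.size_coefficient
    return {
        "roi_weights": weights,
        "informative_rois": informative,
        "size_coefficient": size_coeff,
        "baseline": config.baseline,
        "noise_sd": {tp: config.noise_sd for tp in TIMEPOINTS},
        "subscore_sd": config.subscore_sd,
        "recovery_fractions": dict(config.recovery_fractions),
        "untestable_threshold": config.untestable_threshold,
        "untestable_prob": config.untestable_prob,
    }


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth, dict]:
    """Generate a complete in-memory cohort plus its ground truth.

    Returns (cohort, ground_truth, raw) where raw holds the binary lesion
    volumes and atlas needed for on-disk serialization.
    """
    root = np.random.SeedSequence(config.seed)
    s_atlas, s_lesion, s_cov, s_truth, s_scores, s_drop = root.spawn(6)
    atlas = make_synthetic_atlas(config.grid_dims, config.n_rois,
                                 seed=s_atlas, voxel_size_mm=config.voxel_size_mm,
                                 margin=config.margin)
    cov = simulate_covariates(config.n_patients, np.random.default_rng(s_cov))
    sizes = sample_lesion_sizes(config, np.random.default_rng(s_lesion))
    lesion_rngs = [np.random.default_rng(s) for s in s_lesion.spawn(config.n_patients)]
    lesions: dict[str, LesionVolume] = {}
    for pid, size, prng in zip(cov["patient_id"], sizes, lesion_rngs):
        lesions[pid] = simulate_lesion(atlas, size, prng, patient_id=pid)
    truth_params = _draw_ground_truth_params(config, np.random.default_rng(s_truth))

    # featurize once so the score generator sees exactly the LLVs the
    # analysis will see
    cohort_stub = build_cohort(atlas, lesions, cov, pd.DataFrame(
        {"patient_id": [], "timepoint": [], "outcome": [], "value": []}),
        fwhm_mm=config.fwhm_mm)
    scores, true_scores = simulate_scores(
        cohort_stub.llv, cohort_stub.covariates["lesion_extent_cm3"], truth_params,
        np.random.default_rng(s_scores))
    scores = apply_dropout(scores, config.dropout, np.random.default_rng(s_drop))

    cohort = Cohort(atlas=atlas, llv=cohort_stub.llv, covariates=cohort_stub.covariates,
                    scores=scores, fwhm_mm=config.fwhm_mm)
    truth = GroundTruth(
        roi_weights=truth_params["roi_weights"],
        size_coefficient=truth_params["size_coefficient"],
        baseline=truth_params["baseline"],
        noise_sd=truth_params["noise_sd"],
        recovery_fractions=truth_params["recovery_fractions"],
        informative_rois=truth_params["informative_rois"],
        true_scores=true_scores)
    logger.info("simulated cohort: n=%d, effect=%s, %d untestable, timepoint n = %s",
                config.n_patients, config.effect,
                int(true_scores.loc[true_scores["timepoint"] == "acute", "untestable"].sum()),
                {tp: cohort.case_count("overall", tp) for tp in TIMEPOINTS})
    return cohort, truth, {"lesions": lesions, "atlas": atlas}


def generate_cohort(config: SimConfig, outdir: str | Path) -> Path:
    """Generate a cohort and write the on-disk dataset layout.

    Layout: ``atlas.nii.gz``, ``atlas_rois.tsv``, ``lesions/<id>.nii.gz``,
    ``covariates.tsv``, ``scores.tsv``, ``ground_truth.json`` and
    ``true_scores.tsv``. Fully reproducible from the config seed and
    loadable by :func:`mlsm.cohort.load_cohort` with no special-casing.
    """
    outdir = Path(outdir)
    (outdir / "lesions").mkdir(parents=True, exist_ok=True)
    cohort, truth, raw = simulate_cohort(config)
    write_atlas(raw["atlas"], outdir / "atlas.nii.gz", outdir / "atlas_rois.tsv")
    for pid, lesion in raw["lesions"].items():
        write_volume(lesion, outdir / "lesions" / f"{pid}.nii.gz")
    cov = cohort.covariates.reset_index()
    cov.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    cohort.scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
    truth.true_scores.to_csv(outdir / "true_scores.tsv", sep="\t", index=False)
    sidecar = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "roi_weights": truth.roi_weights.tolist(),
        "informative_rois": truth.informative_rois.tolist(),
        "size_coefficient": truth.size_coefficient,
        "baseline": truth.baseline,
        "noise_sd": truth.noise_sd,
        "recovery_fractions": truth.recovery_fractions,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    logger.info("cohort written to %s", outdir)
    return outdir


def noise_ceiling(cohort: Cohort, truth: GroundTruth, outcome: str = "overall",
                  timepoint: str = "acute") -> float:
    """Prediction r² of the generator's own noiseless (clipped) signal.

    This is the analytic ceiling a feature-based model can reach: it
    predicts each evaluated case with clip(signal), so only observation
    noise (and clipping) separates it from the observations.
    """
    from .evaluation import prediction_r2
    observed = cohort.scores_for(outcome, timepoint).dropna()
    signal = truth.signal_for(timepoint).reindex(observed.index)
    return prediction_r2(observed.to_numpy(), _clip_score(signal.to_numpy()))
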