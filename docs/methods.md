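# Methods

This note documents the models and procedures implemented in `mlsm`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data tests do and do not establish about real data.

## Lesion featurization

**Smoothing.** Binary lesion masks are smoothed per axis with a Gaussian
kernel parameterised by its full width at half maximum (default 8 mm);
sigma in voxels is `fwhm_mm / (voxel_size_mm · 2√(2 ln 2))`. Boundary
handling is constant-zero padding: space outside the volume is treated as
non-brain, so lesions touching the volume edge lose a little mass. The
smoothed output is clipped to [0, 1] so lesion loads stay interpretable
as proportions. Masks are binarised at load time with a 0.5 threshold
(with a warning for non-integral inputs) before any smoothing.

**Lesion load vectors.** For each atlas region the load is the sum of
smoothed lesion values over the region's voxels divided by the region's
voxel count, clipped to [0, 1]. The atlas ROI-table row order is frozen
and defines the LLV column order everywhere. Lesion extent (cm³) is
computed from the *binary pre-smoothing* mask (voxel count × voxel
volume); loads come from the smoothed mask — smoothing precedes overlap
calculation in the pipeline's order of operations.

**Covariate encoding.** The paper-style predictor list is kept at one
column per covariate: sex M=0/F=1, stroke type ischaemic=0/haemorrhagic=1,
handedness ordinal R=1/ambidextrous=0.5/L=0. All non-LLV columns
(including lesion extent and, for IP families, the acute overall score)
are min–max scaled; LLV columns are natively in [0, 1] and never rescaled.
Scaling parameters are always learned on the training cases of the current
fit and applied to held-out cases with clipping to [0, 1]; constant
training columns map to 0. Missing covariates exclude the case — there is
no imputation.

## The SVR model

Each outcome × timepoint × family cell is a linear ε-insensitive support
vector regression with box constraint C = 1 and
ε = IQR(response)/13.49, the default parameterisation for linear SVR in
common statistical environments (13.49 ≈ 2 × 6.745 targets a tenth of a
robust sigma estimate). Quartiles use linear interpolation between order
statistics; a constant response yields ε = 0 with a warning. A `gamma`
field is carried on the hyperparameter object for fidelity to that
default parameterisation but has no effect under a linear kernel (a debug
note is logged). The solver is libsvm (scikit-learn `SVR`) at tolerance
1e-8, which is deterministic and row-order invariant to well below the
1e-6 level asserted in tests. Predictions are capped to the score range
[0, 10]; capping can only reduce squared error against scores known to
lie in that range.

**Cross-validation.** Evaluation is leave-one-out: for each held-out
patient, min–max scaling, ε and the SVR fit are recomputed on the
remaining patients only, so no statistic of the held-out case touches its
own model. Whether scaling/ε estimation should be nested inside the loop
is a genuine design choice; nesting was chosen because it is the only
arrangement that keeps training and testing data fully independent, which
is the stated design principle of the modelling approach. Accuracy is
prediction r² (1 − SSE/SST with SST around the evaluated-set mean — the
standard out-of-sample convention) plus RMSE as a variance-independent
companion. Prediction r² is negative when predictions underperform the
mean, which ε-insensitive SVR can produce on uninformative predictors.
Grid cells with n < 10 are flagged `low_n`; cells that cannot be built
(e.g. IP families at the acute timepoint, or empty case sets) are recorded
as skipped with a machine-readable reason rather than aborting the grid.

**Missingness conventions.** Patients untestable at the acute evaluation
carry an overall score of 0 with all acute subscores missing; they
therefore enter acute overall models (response 0) and no acute subscore
model. Case filtering is per cell: a patient contributes wherever their
response (and, for IP families, their acute overall score) is present.

## Weight mapping

For topographic interpretation the model is refit on *all* eligible cases
(not a cross-validation fold — the map should reflect the full sample; the
refit provenance is recorded in output metadata). LLV coefficients are
thresholded keeping weights that are both negative and more than one
standard deviation below the mean; mean and **population** SD are computed
over the LLV weights only, since the map is spatial and demographic
coefficients belong to a different scale (the population/sample SD
difference is negligible at 150 features). Selected regions are painted
into atlas space with their absolute weight magnitude; the selection is
invariant to positive rescaling of the weights.

**Identifiability caveat.** With 150 mutually correlated lesion-load
columns and C = 1, the fit is deliberately regularised: true effects are
shrunk and every load column absorbs part of the overall lesion-size
signal. A 1-SD threshold on a roughly unimodal weight population then
selects on the order of 15 % of regions, so the selected set is a
*diffuse superset* of the truly causal regions (sign recovery of the true
regions is reliable; exact support recovery is not — the Jaccard overlap
with a 5-region ground truth is ≈ 0.25 at 150 ROIs but 0.6–1.0 at 50
ROIs, where the effect is identifiable). This mirrors the general caution
that SVR beta weights have no agreed significance calibration and should
be read as descriptive.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with defaults matched to an acute left-hemisphere stroke cohort of 217
patients:

* **Grid/atlas** — 64³ voxels at 2 mm with a 6-voxel background rim
  (~1125 cm³ labeled volume, left-hemisphere scale, and large enough that
  the biggest lesions stay under the 80 % growth cap). The parcellation
  grows 150 contiguous parcels (multi-source breadth-first expansion from
  random seed voxels; parcels are face-connected by construction, ≥ 8
  voxels each), tissue-classed 82 % grey / 14 % white / 4 % commissural.
* **Lesions** — contiguous masks grown by uniform-random frontier
  expansion inside the labeled volume, sizes log-normal matched to mean
  53.6 / SD 60.4 cm³ and clipped to [0.6, 376.4] cm³. Vascular-territory
  realism is out of scope.
* **Covariates** — age 62.5 ± 13.6 (21–90), education 12.9 ± 3.2 years,
  sex 117 M:100 F, handedness 193 R:19 L:5 A, stroke type 174 I:43 H per
  217 patients.
* **Scores** — acute latent = baseline (9.5) + Σ roi_weights·LLV −
  c·extent + N(0, 0.8). Location-driven truth uses 5 informative regions
  with weights drawn in [−8, −4]; size-driven truth uses c = 0.025 per cm³
  (≈ 10/376, so the largest lesion maps to complete impairment and the
  deficit stays proportional on-scale — a larger coefficient would put
  most of the range below the floor and break the intended linearity).
  Follow-up latents move toward the ceiling of 10 by nondecreasing
  recovery fractions (0.25 / 0.35 / 0.5 at 1 / 3 / 12 months) with fresh
  noise; all observed scores are clipped to [0, 10]. Subscores are the
  overall latent plus independent N(0, 1) perturbations — a stand-in for
  testability, not a model of subdomain structure. Patients with acute
  latent below 1.5 become untestable with probability 0.6 (overall 0,
  subscores missing), yielding roughly the observed ~8 % untestable rate
  with large lesions.
* **Dropout** — independent per patient and timepoint (probabilities
  0.53 / 0.55 / 0.66), shrinking 217 → ~102 / ~98 / ~74 and, by
  construction, independent of severity. Proportional recovery as an
  empirical law is contested; the recovery fractions are exposed
  per-config so non-proportional scenarios can be generated.
* **Ground truth sidecar** — the noiseless signal behind every score is
  stored per patient × timepoint. The analytic noise ceiling of a cohort
  is the prediction r² of the clipped noiseless signal against the
  observed scores; a well-specified model can approach but not exceed it.

**What passing tests show.** On these cohorts the pipeline reaches the
generator's noise ceiling to within 0.1, separates location- from
size-driven deficits by Δr², and recovers the sign of informative-region
weights — i.e. the machinery is correct and leakage-free under the
linear-with-noise structure it assumes. Real lesion–behaviour data
violate that structure in ways the generator does not emulate (non-linear
and interactive lesion effects, vascular lesion topology, measurement
properties of clinical batteries, informative dropout), so passing tests
do not certify real-data accuracy levels.

## Numerical and procedural choices

* Problem sizes: unit tests run on 24–32³ grids with 6–12 parcels and
  20–40 patients; the scientific acceptance checks use n = 300 cohorts at
  the full 150-ROI resolution, and the reproduction script uses the
  default n = 217 conditions. These sizes were chosen as the smallest at
  which the studied effects are stable.
* Determinism: every stochastic step descends from one seed through
  spawned generators (atlas, lesions, covariates, truth, scores, dropout),
  so cohorts, grids and weight maps are value-identical across reruns;
  LOOCV processes cases in sorted patient-id order and results are
  row-order invariant.
* Degenerate inputs: constant responses give ε = 0 (warned); constant
  covariate columns scale to 0; a zero-SD weight population yields an
  empty map selection (warned); grids with < 3 eligible cases refuse
  LOOCV; constant observed vectors make prediction r² undefined and raise
  rather than returning 0.
* Tolerances: LLV extraction agrees with per-voxel accumulation to 1e-12;
  smoothing agrees with direct convolution to ~1e-7 with < 1e-3 relative
  mass loss away from boundaries; LOOCV equals a per-fold refit oracle to
  1e-10.

## Known limitations

* Lesions and atlas must already share one voxel grid; coregistration,
  normalization and delineation are upstream of this package.
* Weight maps are descriptive; no significance or stability inference is
  attached (see identifiability caveat above).
* The subscore generator is intentionally simplistic; subscore-level
  results on synthetic data only exercise the missingness plumbing.
* Modified recomputation of overall scores from partial subscores is not
  implemented; scores are taken as provided.
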