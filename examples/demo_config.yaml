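# Small end-to-end demonstration run: a simulated 30-patient cohort on a
# 32^3 grid with 30 ROIs, three model-family tiers, and weight mapping for
# the overall score at the 1-year timepoint. Lesion sizes are scaled down
# so the size distribution fits the small demonstration grid.
simulate:
  n_patients: 30
  grid_dims: [32, 32, 32]
  margin: 4
  n_rois: 30
  lesion_mean_cm3: 15.0
  lesion_sd_cm3: 12.0
  lesion_max_cm3: 60.0
outcomes: [overall, word_finding]
families: [llv, reduced_no_llv, reduced_no_llv_no_extent]
map_weights:
  outcome: overall
  timepoint: 12mo
  family: llv
seed: 7
outdir: demo_run
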