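# Full pipeline on a simulated cohort at the default study conditions.
# Replace `simulate` with an `inputs` block to run on real tables:
#   inputs:
#     abundance: path/to/abundance.tsv
#     manifest:  path/to/manifest.tsv
#     snv:       path/to/snv.tsv        # optional; strain stage skipped if absent
#     clinical:  path/to/clinical.tsv   # optional; correlation stage skipped if absent
seed: 1
simulate:
  species:
    n_pairs: 15
    n_taxa: 200
    species_engraftment: 0.3
    env_gain: 0.05
    timepoints: [3, 7, 30]
  snv:
    n_species: 50
    positions_per_species: 100
  clinical: {}
detection_threshold: 0.001
transform:
  x0: 1.0e-6
  variant: shifted_log
strain:
  cov_min: 5
  present_min: 0.2
  absent_max: 0.1
  min_positions: 20
  hi: 0.8
  lo: 0.2
prediction:
  n_trees: 300
  mtry_cv_trees: 25
  auc_min: 0.9
  top_k: 40
correlation:
  t1: 0
  t2: 3
  q_max: 0.05
  min_n: 4
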