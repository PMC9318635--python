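# Full pipeline on a synthetic cohort (no external data needed).
input_mode: synthetic
synthetic:
  n_per_class: 10
  n_days: 13
  separation: 1.0
  subject_sd: 0.15
  dispersion: 1.5
  class_amplitude: {control: 320, depression: 220, schizophrenia: 130}
  night_floor: {control: 4, depression: 12, schizophrenia: 25}
  zero_inflation_night: {control: 0.60, depression: 0.35, schizophrenia: 0.20}
standardize: per-class        # per-class | global | per-subject
stages: [night, morning, afternoon, evening]
train_fraction: 0.7
split_level: segment          # segment | subject
forest:
  n_trees: 900
  min_samples_to_split_node: 3
  min_samples_at_leaf: 6
  max_leaf_nodes_per_tree: 90
  bootstrap: false
selection_folds: 5
selection_step: 1
rfe_n_trees: 100              # lighter forest inside the elimination loop
cv_folds: 5
seed: 1
outdir: runs/synthetic
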