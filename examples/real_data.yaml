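# Full pipeline on downloaded study data: per-subject CSV files with a
# timestamp,date,activity header, grouped into one directory per class.
# Control files shared between the two source datasets are de-duplicated
# by file basename.
input_mode: csv-dirs
control_dir: data/control
depression_dir: data/condition_depression
schizophrenia_dir: data/condition_schizophrenia
standardize: per-class
stages: [night, morning, afternoon, evening]
train_fraction: 0.7
split_level: segment
forest:
  n_trees: 900
  min_samples_to_split_node: 3
  min_samples_at_leaf: 6
  max_leaf_nodes_per_tree: 90
  bootstrap: false
selection_folds: 5
selection_step: 1
rfe_n_trees: 100
cv_folds: 5
seed: 1
outdir: runs/real
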