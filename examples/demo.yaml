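# Small end-to-end demonstration: simulate a 200-subject cohort, extract
# features, rank the three candidate ensembles, GA-select features, train
# on a stratified 90/10 split and evaluate with exact 95% intervals.
seed: 7
out_dir: fhp_demo_run
cohort:
  n_subjects: 200
ga:
  population_size: 12
  generations: 4
  inner_cv_folds: 3
cv_folds: 5
models:
  - {family: extremely_randomized_trees, name: ETC, hyperparams: {n_estimators: 30}}
  - {family: gradient_boosting, name: GBC, hyperparams: {n_estimators: 20}}
  - {family: extreme_gradient_boosting, name: XGB, hyperparams: {n_estimators: 20}}
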