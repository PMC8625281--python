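# Desk-scale end-to-end demo: simulate a planted-effect cohort, segment,
# build features, compare hemispheres, and fit two models.
out_dir: demo_run
sim:
  planted_effects: {n_effect: 5, beta: 2.0}
  n_patients: 150
  seed: 1
segmentation:
  adc_threshold: 615.0
  min_component_voxels: 5
  connectivity: 6
models:
  - {learner: svm_rbf, feature_set: p3}
  - learner: svm_rbf
    feature_set: p4
    selector: fscore_rank
    svm_c_grid: [1.0]
    svm_gamma_grid: [scale]
    inner_folds: 3
    max_curve_features: 25
folds: 10
repeats: 20
seed: 1
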