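# Scaled-down configuration for a quick end-to-end comparison run.
synthetic:
  n_case: 80
  n_control: 80
  n_female_per_group: 31
  modality_dims: {sMRI: 12, DTI: 12, rsfMRI: 12}
  n_informative: {sMRI: 4, DTI: 4, rsfMRI: 4}
  effect_size: 0.5
  n_batches: 2
harmonize: true
selection:
  ensemble_size: 35
  max_iterations: 20
train:
  weight_stride: 0.2
  c_grid: [0.001, 0.1, 10.0]
cv:
  outer_folds: 10
  inner_folds: 5
  repeats: 1
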