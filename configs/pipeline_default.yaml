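cluster:
  hom_threshold: 0.4
  n_over: 25
  reagg_threshold: 0.4
filter_trials:
  eye_radius_mm: 1.65
  threshold_deg: 2.0
model:
  spec_yaml: null
output_dir: run_out
preprocess:
  neuropil_weight: 0.7
  smooth_window: 0.19
  tau: 2.0
seed: 0
stages:
- synth
- preprocess
- filter_trials
- cluster
- stats
- model
stats:
  alpha: 0.01
  mask_pct: 1.0
  response_window:
  - 0.2
  - 1.0
synth:
  contexts:
  - dark
  n_neurons: 120
  n_repetitions: 20
  noise_sd: 0.03
  saccade_rate: 0.0
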