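cohort:
  n_weeks: 11
  groups:
  - HCD
  - HCD+HVK
  - HCD+LVK
  - HCD+NN
  n_mice:
  - 6
  - 6
  - 6
  - 3
  sigma_obs: 0.3
  sigma_state: 30.0
  seed: 2024
  image_shape: null
  scale_min: 337
  scale_max: 1020
  max_redraws: 1000
prior:
  sigma_obs_scale: 1.0
  sigma_state_scale: 1.0
  data_rescale: 100.0
model:
  share_sigma_state: true
sampler:
  n_chains: 4
  n_draws: 5000
  n_warmup: 1000
  seed: 7
summary:
  weeks:
  - 5
  - 8
  - 10
  control: HCD
  ci_level: 0.89
  interval: eti
rhat_max: 1.05
ess_min: 400.0
data_csv: null
render_images: false
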