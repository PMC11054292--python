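# Desk-scale configuration: tiny backbone, 256-px scenes, short z range.
seed: 5
optical:
  z_min_um: -2.0
  z_max_um: 2.0
  z_step_um: 0.5
  seed: 5
compose:
  image_size_min_px: 256
  image_size_max_px: 256
  n_particles_min: 3
  n_particles_max: 5
net:
  backbone: tiny
  input_size_px: 256
  score_threshold: 0.35
train:
  epochs: 40
  batch_size: 2
  lr: 0.002
  eval_every: 10
  seed: 5
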