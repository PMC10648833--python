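# Strong appearance drift over 10 ticks, 5 identities.
scenario:
  duration: 10
  morph_rate: 2.0
  env_events: []
  population_events: []

world:
  n_identities: 5
  frames_per_session: 3
  sessions_per_tick: 5
  noise_sigma: 0.02

train:
  margin: 0.2
  gor_weight: 1.0
  learning_rate: 0.001
  patience: 5
  max_epochs: 8
  input_size: 32
  seed: 0

policy:
  period: 1
  per_identity_trigger: 6
  capacity: 40
  finetune_trigger: 12
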