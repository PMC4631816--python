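# Scaled-down cohort: 32-channel helmet (24 retained after frontal
# exclusion), 200-vertex source shell, 10 repetitions per image (140
# trials/subject), 250 Hz sampling. Runs end to end in a few minutes.
# The full study design uses n_channels: 160, n_vertices: 4004,
# repetitions: 40, sfreq: 1000 — substitute those for a study-scale run.
simulation:
  n_channels: 32
  n_vertices: 200
  repetitions: 10
  sfreq: 250.0
  amplitude_nam: 2.0
  n_background: 10
preprocessing:
  bandpass: [1.0, 30.0]
  baseline: [-500.0, -100.0]
  notch_hz: 60.0
inverse:
  lam: 0.1
  f_window_ms: [180.0, 200.0]
decoding:
  k_folds: 10
  n_random_partitions: 3
n_subjects: 3
seed: 7
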