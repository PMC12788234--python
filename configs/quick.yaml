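# Five-class quick profile: 1 subject x 10 trials x 20 s, Plabel 100 ms.
seed: 0
dataset:
  n_subjects: 1
  trials_per_subject: 10
  classes: [1, 2, 3, 5, 14]
  trial_duration_s: 20.0
windowing:
  window_ms: 1200
  step_ms: 200
  plabel_ms: 100
training:
  epochs: 30
  early_stop_patience: 5
  scheduler_patience: 2
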