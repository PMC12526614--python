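# Reference pipeline configuration (all keys optional; defaults shown for
# the blocks most often tuned). Run with:
#   squatstab run --config examples/config.yaml --out out --seed 1
seed: 1
out_dir: out
synth:
  n_subjects: 28
  squats_per_subject: 130
  camera_rate: 60.0       # Hz
  plate_rate: 50.0        # Hz
  start_offset_max: 3.0   # s, device start-time mismatch
  instability_prevalence: 0.065
  osc_freq_range: [1.0, 4.0]     # Hz, must stay below the filter cutoff
  osc_amp_unstable: [0.004, 0.010]  # m
filter:
  cutoff: 5.0   # Hz
  order: 4
  zero_phase: true
segmentation:
  min_depth: 0.15   # m, spurious-detection rejection
  dur_min: 1.0      # s
  dur_max: 10.0     # s
features:
  ks_mode: magnitude     # or 'signed'
  label_threshold: 0.03  # m/s
  label_stat: max        # or 'mean'
  n_samples: 20
  scope: per_subject     # min-max scope; or 'global'
train:
  hidden: 32
  epochs: 100
  batch_size: 32
  learning_rate: 0.001
  split_fraction: 0.8
sets: ["1,2,3,4,5", "1,2,3", "1,3,5", "4,5", "2,4"]
models: ["lstm", "svm"]
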