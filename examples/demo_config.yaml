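# Full-size demo configuration for `lfpbands run-all --config examples/demo_config.yaml`
# 2 groups x 10 subjects, 5 regions, two 5-minute states at 1000 Hz,
# with the bundled movement/lesion oscillation pattern injected.
mode: synthetic
seed: 0
out_dir: lfpbands_out
filter_low: 0.5
filter_high: 80.0
artifact_method: amplitude_sd
artifact_k: 6.0
segment_s: 10.0
epoch_length_s: 1.0
sphericity_alpha: 0.05
synthetic:
  n_per_group: 10
  fs: 1000
  state_duration_s: 300
  noise_exponent: 1.0
  noise_scale: 20.0
  subject_sd: 0.2
  band_effects: demo
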