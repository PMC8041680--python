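# Full end-to-end run configuration for `visearch run-all --config run.yaml`
seed: 1
n_per_group: [29, 23, 15, 18]    # TD, ADHD, ASD-, ASD+
sampling_rate: 120               # Hz; 60 also supported
n_trials: 30
min_trials: 10                   # valid-trial floor for participant inclusion
min_line_length: 2               # RQA determinism/laminarity line length

detector:
  min_duration_ms: 60
  max_dispersion_deg: 2.0
  dispersion_metric: sum         # x-range + y-range (I-DT); or 'max'
  gap_bridge_ms: 75

rules:
  cue_window_ms: [1700, 3300]    # first cue fixation onset, closed interval
  max_prescan_fixations: 1
  max_prescan_duration_ms: 300

multimatch:
  amp_threshold: 0.10            # fraction of screen diagonal
  dir_threshold_deg: 45
  dur_threshold_ms: 300
  aggregate: median

# per-variable within-group outlier removal (3 SD rule), applied selectively
outlier_k_sd:
  sd_search_fix_count: 3.0

out_dir: visearch_out
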