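# visearch

Analysis pipeline for eye movements in a cued visual-search task, built
to study *performance* (per-trial means) and *intra-subject variability*
(ISV: per-trial SDs) of oculomotor behaviour in typically developing
children and children with ADHD, ASD, or both.

The task it models: each trial shows a fixation cross on the left for
2 s, then a cue word plus a 4 x 3 grid of word pairs for 7 s (30 trials,
4.5 min; 12 target cells, 6 used twice and 6 thrice). Participants find
the grid cell matching the cue and press the corresponding field on a
response pad.

The pipeline runs from raw gaze samples to group statistics:

1. **io_gaze** — TSV readers/writers for samples, fixation events, trial
   metadata and result tables, with schema validation and a
   column-dialect config for vendor exports.
2. **fixations** — dispersion-threshold (I-DT) event detection:
   a fixation is a sample window spanning >= 60 ms whose dispersion
   (x-range + y-range) stays under 2 degrees of visual angle.
3. **segmentation** — AOI labeling (cue, `cell_1..12`, outside) and the
   trial-validity rules: only correct/corrected trials; first cue
   fixation must start 1700-3300 ms from trial onset; at most one grid
   fixation of <= 300 ms before it. Valid trials split into
   *Encoding-and-Initiation* (first cue fixation -> first grid fixation)
   and *Search* (-> last target fixation before the correct press).
4. **metrics** — per-trial variables (entry to cue/grid, cue fixation
   count/duration, search fixation count/duration, RT) and
   per-participant mean (performance) and SD (ISV) summaries, including
   RTSD.
5. **rqa** — categorical recurrence quantification of the search
   scanpath over AOIs: Recurrence `100*2R/(N(N-1))`, Determinism
   (recurrent points on diagonal lines >= L), Laminarity
   (horizontal/vertical lines), and CORM
   `100*sum((j-i)*r_ij)/((N-1)*R)`; plus the same-target-cell
   subtracted variant as an ISV measure.
6. **multimatch** — MultiMatch scanpath similarity (vector, length,
   direction, position, duration dimensions in [0,1]) between trial
   pairs sharing a target cell; low similarity = high ISV.
7. **group_stats** — one-way ANOVA over GROUP with eta-squared,
   Tukey-Kramer post hoc (studentized range) with Cohen's d, one-way
   ANCOVA with an IQ-style covariate, and a 3-SD within-group outlier
   rule.
8. **simulate** — a synthetic gaze-trial generator with full ground
   truth (fixations, segment boundaries, per-trial variable values),
   used to validate every downstream stage end to end.

## Worked example

```python
from visearch import (RunConfig, TaskLayout, default_profiles,
                      simulate_participant, detect_fixations,
                      AOILayout, label_fixations, segment_trial,
                      trial_features, split_fixations_by_trial)

layout = TaskLayout()                      # 2 s cross + 7 s stimulus, 30 trials
profile = default_profiles()["TD"]
stream, metas, truth = simulate_participant(profile, layout, seed=1)

fixations = detect_fixations(stream)       # I-DT, 60 ms / 2 deg
per_trial = split_fixations_by_trial(fixations, layout.n_trials,
                                     layout.trial_duration)
aois = AOILayout.from_task_layout(layout)
seg = segment_trial(label_fixations(per_trial[0], aois), metas[0])
f = trial_features(seg, metas[0])
print(seg.status, round(f.entry_to_cue), round(f.entry_to_grid), f.search_fix_count)
```

prints

```
valid 2600 3400 9
```

i.e. the first trial is valid; the eye entered the cue area 2600 ms
after trial onset (600 ms after the cue appeared), entered the grid at
3400 ms, and made 9 search fixations before settling on the target.

An end-to-end study (four groups, sizes 29/23/15/18) runs from the
shell and writes `trial_features.tsv`, `participant_summary.tsv`,
`rqa_trials.tsv`, `rqa_isv.tsv`, `multimatch_isv.tsv`,
`group_stats.tsv`, `group_posthoc.tsv` and a reproducibility
`manifest.json`:

```bash
visearch run-all --seed 1 --out-dir out/
```

Per-stage subcommands (`visearch simulate|detect|segment|metrics|rqa|
multimatch|stats`) expose the same steps over TSV files; see
`examples/run.yaml` for a full configuration.

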