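# Methods

## Scope and model of the task

The package analyses eye movements in a cued visual-search task with a
fixed trial structure: a fixation cross on the left of a 1920 x 1080
screen for 2000 ms, then a cue word plus a 4 x 3 grid of word-pair
cells for 7000 ms. A block has 30 trials (4.5 min); targets occupy 12
grid cells, 6 cells twice and 6 thrice. All times are milliseconds from
trial onset (the cross); subtracting the 2000 ms cross duration converts
entry times to a cue-onset baseline — the two conventions differ by
exactly that constant.

Coordinates are 0-based screen pixels, origin top-left, y downward.
Degrees of visual angle convert to pixels with the small-angle formula
from the physical screen width (default 47.4 cm) and viewing distance
(default 70 cm), giving ~49.5 px/deg; both are configuration, never
hard-coded, because recordings from other set-ups will differ.

## Fixation detection (I-DT)

A fixation is a maximal window of consecutive valid samples whose
dispersion stays within `max_dispersion` (default 2 deg) for at least
`min_duration` (default 60 ms). Dispersion is the sum of the x-range
and the y-range of the window (the classic I-DT convention); a
max-of-ranges alternative is selectable as `dispersion_metric: max`.
The centroid is the mean of member samples. Candidate windows break at
track-loss gaps longer than `gap_bridge_ms` (default 75 ms); shorter
gaps are bridged. The bridge sits above the inter-sample interval but
below the minimum duration, so bridging alone can never assemble a
valid fixation out of two sub-threshold snippets. Whether a commercial
event detector's proprietary dispersion definition matches this
convention exactly cannot be established from vendor documentation;
the config records the choice so either variant can be selected.

## Trial segmentation

Validity rules run in a fixed order, and a trial failing rule *k* is
never tested on rule *k+1*, so the rejection reason is deterministic:

1. outcome filter — only correct or corrected (wrong press later
   corrected) trials continue;
2. cue-window rule — the first cue fixation's onset must lie in
   [1700, 3300] ms (closed on both ends; a fixation straddling 3300
   qualifies by onset);
3. pre-scan rule — before that cue fixation at most one grid fixation,
   lasting at most 300 ms;
4. encoding end — onset of the first grid fixation after the cue
   fixation;
5. search end — onset of the last fixation on the target cell before
   the final correct press; trials with presses at or before search
   onset fail here (`no_search_end`).

Intervals are half-open `[start, end)`: a fixation starting exactly at
a boundary belongs to the later segment. "Grid fixation" means a
fixation inside any of the 12 cell AOIs; gaps between cells count as
`outside` (an open reading of the rule — the alternative, the grid
bounding box, would also capture inter-cell gaps).

Validity bookkeeping reports four buckets — valid, incorrect, missing,
rejected-other — because the first three alone cannot partition 30
trials once window/pre-scan rejections exist.

## Per-trial variables and ISV

For each valid trial: entry to cue (= encoding start), total duration
and count of cue fixations within encoding, entry to grid (= encoding
end), search fixation count and per-fixation mean duration over the
search segment, and RT (final correct press minus stimulus onset).
Cue fixation duration defaults to the per-trial total (consistent with
summary magnitudes of roughly count x single-fixation duration); a
`mean` switch exists. Search fixation duration is the within-trial
mean, so the participant-level mean is a mean of trial means.

Participant summaries take the mean (performance) and the sample SD
with n-1 denominator (intra-subject variability, ISV) over valid
trials; RTSD is the raw SD of RTs, not a CV. A single-trial SD is
reported missing, never 0. Participants need `min_trials` (default 10)
valid trials to enter group statistics; the floor is explicit config
because "poor data quality" is otherwise an unquantified judgement.

## Scanpath structure: RQA

Recurrence quantification runs on the search-segment scanpath, with
each grid cell and the cue as categorical AOIs. Two fixations recur if
they share an AOI; `outside` fixations stay in the sequence with unique
labels (dropping them would distort the lag structure that CORM
measures) but never recur. With N fixations and R recurrent pairs in
the upper triangle:

* REC = 100 * 2R / (N(N-1))
* DET = 100 * |D_L| / R, D_L = recurrent points on diagonal lines of
  length >= L (default L = 2) — repeated sub-scanpaths
* LAM = 100 * (|H_L| + |V_L|) / (2R) over horizontal/vertical lines —
  prolonged dwelling
* CORM = 100 * sum over i<j of (j-i) r_ij / ((N-1) R) — low values mean
  revisits occur close in time

With R = 0, REC is 0 and the structure measures are missing. Note a
boundary effect of the line definitions: in a saturated matrix the
lag-(N-1) corner point lies on a length-1 diagonal, so DET and LAM peak
at 100(R-1)/R rather than 100 under L = 2; under L = 1, DET is exactly
100 whenever R > 0, which doubles as a configuration sanity check.

The ISV variant recomputes the measures per target cell: for each cell
with >= 2 valid trials, all pairwise absolute differences of each
measure are averaged over pairs. "Subtraction" leaves sign and
aggregation open; the symmetric choice (absolute mean) is used and
recorded in config. Both this variant and the plain per-participant
mean/SD of the trial measures are reported.

## Scanpath similarity: MultiMatch

Each search-segment scanpath is reduced to saccade vectors, simplified
by iteratively merging consecutive saccades that are either both small
(amplitude < 10% of the screen diagonal, intervening fixation < 300 ms)
or near-collinear (direction difference < 45 deg); merged vectors are
vector sums, and simplification is idempotent. The two vector
sequences are aligned by the cheapest monotone path (right/down/
diagonal moves) through the matrix of vector-difference norms —
computed by dynamic programming, which is exact on this DAG. Five
normalized difference dimensions are scored over the aligned pairs
(vector by 2x diagonal, length and position by the diagonal, direction
by pi, duration by the longer fixation) and aggregated by the median
(mean available), giving similarities in [0,1]. Position and duration
compare the source fixation of each aligned vector. Per participant,
all within-target-cell trial pairs are compared, unweighted, and
averaged; lower similarity means higher ISV.

## Group statistics

One-way between-subjects ANOVA per variable (single factor, so SS types
coincide under unbalance), eta^2 = SS_between/SS_total. Tukey-Kramer
post hoc for all pairs regardless of omnibus significance, with
q = t sqrt(2), p from the studentized-range distribution at the omnibus
error df, and t from the pooled MS_error. Cohen's d defaults to
`2t/sqrt(df_error)` — the convention consistent with the reported
effect sizes this layer models (pooled-pairwise d reproduces none of
them; it is available as `d_convention="pooled_pairwise"`). A summary
interface (`oneway_anova_from_summary`, `tukey_from_summary`) performs
the algebraically identical analysis from per-group (n, mean, SD)
triples so published tables can be re-analysed. Outlier removal is a
single within-group pass dropping values beyond k SD (default 3),
applied selectively per variable via config, before the ANOVA; the
post hoc df reflects the post-removal N. ANCOVA fits the
covariate-plus-group linear model (homogeneous slopes) and tests the
group factor by extra sum of squares; rows with missing covariates are
dropped and counted.

## Synthetic data generator

The generator exists to make every stage testable without clinical
recordings; its defaults encode the study conditions being emulated.
Each base variable (entry to cue, cue fixation duration/count, entry to
grid, search fixation duration, motor delay) follows a two-level
normal law: subject mean ~ N(population mean, between-subject SD),
trial value ~ N(subject mean, within-subject SD). The within-subject
SD is the generative ISV that downstream SD summaries recover. The four
default profiles carry the published per-group means and SDs (e.g. TD
entry-to-cue 2493.01 / 82.81 / 128.57 ms; ASD+ 2662.29 / 120.31 /
169.07 ms); miss, error (never-corrected), corrected and late-entry
probabilities are set from the published valid/inaccurate/missing trial
counts (TD: 0.6 missing, 0.2 inaccurate, ~2.3 other rejections of 30).

Within a trial the simulated eye fixates the cross, enters the cue at
the drawn entry time (late-entry trials draw beyond the 3300 ms window
so segmentation rejection paths are exercised), makes the drawn number
of cue fixations, enters the grid, and scans cells under a first-order
Markov policy: with probability `revisit_probability` the next fixation
goes to an already-visited cell, else to an unvisited one, until the
target is fixated; a button press follows after the motor delay.
Revisit defaults (0.54-0.58) put recurrence near the reported 21-25%
range. Under time pressure (when less than ~2.5 fixations plus a motor
response would fit before stimulus offset) the scan steers to the
target, so missing-trial rates stay at their configured values rather
than inflating with policy tail events.

Rendering places fixation boundaries on the sampling grid (120 Hz
default, 60 Hz supported), draws within-fixation Gaussian jitter
(default 0.1 deg, clipped at 2.5 SD) strictly below the dispersion
threshold, and keeps consecutive fixation centres >= 150 px apart so a
2 deg detector can never merge neighbours. Saccades occupy exactly one
inter-sample interval — no mid-saccade samples are rendered at the
default gap — which is what makes detector recovery exact: counts match
and boundaries agree to within one inter-sample interval. The stretch
from a trial's last fixation to the next trial's first fixation is
marked as track loss (blink-like), as real recordings have no stimulus
to anchor gaze there.

What the generator does *not* emulate: biophysical saccade kinematics
(no mid-flight samples), pupil/blink dynamics beyond the inter-trial
track loss, word identity within cells (cells are opaque AOIs; the
word-to-cell mapping of the original stimuli is not modelled),
subject-level heterogeneity of ISV itself (within-subject SD is a
group constant, so between-subject spread of recovered SDs reflects
sampling error only, and group F statistics on SD variables run larger
than in heterogeneous real samples), and the long right tail of real
RT distributions (searches are kept short enough that responses fall
inside the stimulus window, compressing RT-level summaries relative to
the modelled study). Passing tests therefore demonstrate correctness
of the pipeline's computations and calibrated recovery of configured
parameters — not that real clinical data would reproduce any particular
group effect.

## Numerical and reproducibility choices

* Sample SD uses the n-1 denominator throughout; recovery tests compare
  against the c4-corrected expectation E[s] = c4(n) sigma.
* The recurrence matrix is exact integer counting; measures are exact
  rational arithmetic in floating point (no tolerance issues below
  N ~ 10^3).
* Alignment ties in the MultiMatch backtrack prefer the diagonal,
  yielding the shortest optimal alignment.
* Studies spawn one RNG stream per participant from the study seed
  (`SeedSequence.spawn`), so participant data are independent of group
  order and bit-reproducible; identical configs re-run to byte-identical
  output tables. Test and demo problem sizes (e.g. 200 replicate
  studies for power checks, 10,000 replicates for type-I calibration)
  are the package's choices for tight Monte-Carlo error at interactive
  runtimes.
* Degenerate inputs: empty/all-invalid streams detect to empty event
  lists; single-fixation scanpaths have no RQA/MultiMatch result
  (missing, never zero); zero-variance groups remove no outliers.
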