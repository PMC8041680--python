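"""Synthetic participants, trials and gaze streams for the visual-search task.

The task structure being emulated: each trial shows a fixation cross on
the left for 2 s, then a cue word plus a 12-cell word grid for 7 s; the
main block has 30 trials, with 6 target cells used twice and 6 used
three times.  A participant fixates the cross, enters the cue AOI
(entry-to-cue), encodes the cue over one or more cue fixations, enters
the grid (entry-to-grid), scans cells under a first-order Markov policy
with a revisit parameter until the target cell is fixated, and presses
the matching response-pad field after a motor delay.

Each base variable follows a two-level normal law: a subject-level mean
drawn from N(population mean, between-subject SD) and trial-level values
drawn from N(subject mean, within-subject SD).  The within-subject SD is
the generative intra-subject variability (ISV) that the downstream
per-participant SD summaries are meant to recover.  Default group
profiles are anchored to the four study groups' reported summary
statistics (TD, ADHD, ASD without ADHD, ASD with ADHD).

Ground truth records every generated fixation, the segment boundaries
and the per-trial variable values, so detection, segmentation and
metrics can all be checked against it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import CUE, OUTSIDE, Fixation, Rect, Scanpath, cell_label
from .io_gaze import Outcome, SampleStream, ScreenGeometry, TrialMeta


class ConfigurationError(ValueError):
    """A simulation profile or layout cannot produce feasible trials."""


# ---------------------------------------------------------------------------
# Task layout


def default_grid(screen: ScreenGeometry = ScreenGeometry(),
                 n_cols: int = 4, n_rows: int = 3,
                 left_fraction: float = 0.25) -> list[Rect]:
    """Equal rectangular grid cells tiling the right part of the screen."""
    x_start = screen.width_px * left_fraction
    cw = (screen.width_px - x_start) / n_cols
    ch = screen.height_px / n_rows
    cells = []
    for r in range(n_rows):
        for c in range(n_cols):
            cells.append(Rect(x_start + c * cw, r * ch,
                              x_start + (c + 1) * cw, (r + 1) * ch))
    return cells


def target_schedule(n_trials: int = 30, n_cells: int = 12,
                    rng: np.random.Generator | None = None) -> list[int]:
    """Per-trial target cells: for 30 trials, 6 cells twice + 6 cells thrice.

    For other trial counts the cells are cycled as evenly as possible.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if n_trials == 30 and n_cells == 12:
        cells = rng.permutation(np.arange(1, 13))
        twice, thrice = cells[:6], cells[6:]
        sched = list(np.repeat(twice, 2)) + list(np.repeat(thrice, 3))
    else:
        reps = int(math.ceil(n_trials / n_cells))
        sched = list(np.tile(np.arange(1, n_cells + 1), reps))[:n_trials]
    sched = [int(c) for c in sched]
    rng.shuffle(sched)
    return sched


@dataclass
class TaskLayout:
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    cue_aoi: Rect = Rect(40, 390, 440, 690)
    grid_aois: list[Rect] = field(default_factory=default_grid)
    fixation_cross_pos: tuple[float, float] = (240.0, 860.0)
    cross_duration: float = 2000.0
    stimulus_duration: float = 7000.0
    n_trials: int = 30
    target_schedule: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.target_schedule:
            self.target_schedule = target_schedule(
                self.n_trials, len(self.grid_aois), np.random.default_rng(0))
        if len(self.target_schedule) != self.n_trials:
            raise ConfigurationError("target_schedule length must equal n_trials")
        rects = [self.cue_aoi] + list(self.grid_aois)
        for i, a in enumerate(rects):
            for b in rects[i + 1:]:
                if a.x0 < b.x1 and b.x0 < a.x1 and a.y0 < b.y1 and b.y0 < a.y1:
                    raise ConfigurationError("AOIs must be pairwise disjoint")
        cx, cy = self.fixation_cross_pos
        if self.cue_aoi.contains(cx, cy) or any(r.contains(cx, cy) for r in self.grid_aois):
            raise ConfigurationError("fixation cross must lie outside all AOIs")

    @property
    def trial_duration(self) -> float:
        return self.cross_duration + self.stimulus_duration

    @property
    def block_duration_minutes(self) -> float:
        return self.n_trials * self.trial_duration / 60000.0


# ---------------------------------------------------------------------------
# Group profiles


@dataclass(frozen=True)
class VariableLaw:
    """Two-level normal law: subject mean ~ N(mean, between_sd); trial value
    ~ N(subject mean, within_sd).  ``within_sd`` is the generative ISV."""

    mean: float
    between_sd: float
    within_sd: float

    def __post_init__(self) -> None:
        if self.between_sd < 0 or self.within_sd < 0:
            raise ConfigurationError("SDs must be non-negative")


@dataclass(frozen=True)
class GroupProfile:
    group_label: str
    entry_to_cue: VariableLaw
    cue_fix_duration: VariableLaw
    cue_fix_count: VariableLaw
    entry_to_grid: VariableLaw
    search_fix_duration: VariableLaw
    motor_delay: VariableLaw
    revisit_probability: float = 0.40
    miss_probability: float = 0.02
    error_probability: float = 0.007
    corrected_probability: float = 0.03
    late_entry_probability: float = 0.07

    def __post_init__(self) -> None:
        for p in (self.revisit_probability, self.miss_probability,
                  self.error_probability, self.corrected_probability,
                  self.late_entry_probability):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")


def default_profiles() -> dict[str, GroupProfile]:
    """Generative analogues of the four study groups.

    Population means and between/within SDs for the base variables follow
    the study's per-group descriptive statistics; miss / error / late-entry
    rates are set so that expected per-participant valid-trial counts match
    the reported values (e.g. TD: 0.6 missing, 0.2 inaccurate and ~2.3
    segmentation-rejected trials out of 30).
    """
    return {
        "TD": GroupProfile(
            "TD",
            entry_to_cue=VariableLaw(2493.01, 82.81, 128.57),
            cue_fix_duration=VariableLaw(604.29, 219.72, 158.06),
            cue_fix_count=VariableLaw(1.42, 0.25, 0.47),
            entry_to_grid=VariableLaw(2921.30, 227.87, 182.14),
            search_fix_duration=VariableLaw(248.60, 30.68, 59.92),
            motor_delay=VariableLaw(500.0, 100.0, 150.0),
            revisit_probability=0.55,
            miss_probability=0.020, error_probability=0.007,
            corrected_probability=0.03, late_entry_probability=0.077,
        ),
        "ADHD": GroupProfile(
            "ADHD",
            entry_to_cue=VariableLaw(2540.47, 110.56, 162.58),
            cue_fix_duration=VariableLaw(655.08, 168.87, 219.63),
            cue_fix_count=VariableLaw(1.50, 0.24, 0.54),
            entry_to_grid=VariableLaw(3045.00, 220.74, 245.62),
            search_fix_duration=VariableLaw(263.96, 36.48, 69.82),
            motor_delay=VariableLaw(520.0, 100.0, 170.0),
            revisit_probability=0.55,
            miss_probability=0.046, error_probability=0.011,
            corrected_probability=0.03, late_entry_probability=0.123,
        ),
        "ASDminus": GroupProfile(
            "ASDminus",
            entry_to_cue=VariableLaw(2508.11, 98.86, 126.89),
            cue_fix_duration=VariableLaw(600.59, 144.55, 161.45),
            cue_fix_count=VariableLaw(1.52, 0.22, 0.51),
            entry_to_grid=VariableLaw(2957.09, 166.65, 191.90),
            search_fix_duration=VariableLaw(241.98, 37.12, 61.78),
            motor_delay=VariableLaw(510.0, 100.0, 160.0),
            revisit_probability=0.58,
            miss_probability=0.044, error_probability=0.015,
            corrected_probability=0.03, late_entry_probability=0.067,
        ),
        "ASDplus": GroupProfile(
            "ASDplus",
            entry_to_cue=VariableLaw(2662.29, 120.31, 169.07),
            cue_fix_duration=VariableLaw(716.89, 220.02, 246.45),
            cue_fix_count=VariableLaw(1.51, 0.30, 0.59),
            entry_to_grid=VariableLaw(3208.27, 260.43, 295.48),
            search_fix_duration=VariableLaw(276.50, 38.01, 66.92),
            motor_delay=VariableLaw(540.0, 100.0, 180.0),
            revisit_probability=0.54,
            miss_probability=0.096, error_probability=0.007,
            corrected_probability=0.03, late_entry_probability=0.128,
        ),
    }


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass
class TrialGroundTruth:
    trial_id: int
    outcome: Outcome
    target_cell: int
    scanpath: Scanpath                 # trial-relative, AOI-labeled
    encoding_start: float | None       # = entry to cue
    encoding_end: float | None         # = entry to grid
    search_end: float | None           # onset of last target fixation
    responses: list[tuple[float, int]]  # trial-relative
    expected_status: str               # 'valid' or 'rejected'
    expected_reason: str | None
    features: dict | None              # per-trial variable values (valid only)


@dataclass
class GroundTruth:
    participant_id: str
    group_label: str
    subject_means: dict
    trials: list[TrialGroundTruth]


# ---------------------------------------------------------------------------
# Participant simulation

_MIN_FIX_MS = 80.0
# consecutive fixation centres are kept at least this far apart so that a
# 2 deg dispersion detector can never merge neighbouring fixations
_MIN_SEPARATION_PX = 150.0


def _point_in_rect(rect: Rect, rng: np.random.Generator,
                   margin: float = 60.0,
                   away_from: tuple[float, float] | None = None) -> tuple[float, float]:
    """Random point inside ``rect`` (inset by ``margin``), at least
    ``_MIN_SEPARATION_PX`` from ``away_from`` when that is feasible."""
    for _ in range(40):
        x = rng.uniform(rect.x0 + margin, rect.x1 - margin)
        y = rng.uniform(rect.y0 + margin, rect.y1 - margin)
        if away_from is None or math.hypot(x - away_from[0], y - away_from[1]) >= _MIN_SEPARATION_PX:
            return x, y
    # fall back to the inset corner farthest from away_from
    corners = [(rect.x0 + margin, rect.y0 + margin), (rect.x1 - margin, rect.y0 + margin),
               (rect.x0 + margin, rect.y1 - margin), (rect.x1 - margin, rect.y1 - margin)]
    return max(corners, key=lambda c: math.hypot(c[0] - away_from[0], c[1] - away_from[1]))


def _simulate_trial(trial_id: int, target: int, profile: GroupProfile,
                    layout: TaskLayout, subj: dict,
                    rng: np.random.Generator, dt: float) -> TrialGroundTruth:
    stim_onset = layout.cross_duration
    trial_end = layout.trial_duration
    fixations: list[Fixation] = []
    labels: list[str] = []

    def snap(v: float) -> float:
        # fixation boundaries live on the sample grid, so that rendering and
        # re-detection can agree exactly; saccades occupy exactly one
        # inter-sample interval (no mid-saccade samples are rendered)
        return round(v / dt) * dt

    # --- entry to cue ---------------------------------------------------
    if rng.uniform() < profile.late_entry_probability:
        # delayed first cue fixation -> fails the cue-window rule downstream
        e1 = rng.uniform(stim_onset + 1350, stim_onset + 2600)
    else:
        e1 = float(np.clip(rng.normal(subj["entry_to_cue"], profile.entry_to_cue.within_sd),
                           stim_onset - 300.0, trial_end - 2500.0))
    e1 = snap(e1)

    # fixation on the cross until one saccade before cue entry
    cross_start = snap(rng.uniform(80.0, 150.0))
    cx, cy = layout.fixation_cross_pos
    fixations.append(Fixation(cross_start, e1 - dt, cx, cy))
    labels.append(OUTSIDE)

    # --- cue fixations --------------------------------------------------
    n_cue = max(1, int(round(rng.normal(subj["cue_fix_count"],
                                        profile.cue_fix_count.within_sd))))
    total_cue = float(np.clip(rng.normal(subj["cue_fix_duration"],
                                         profile.cue_fix_duration.within_sd),
                              _MIN_FIX_MS * n_cue + 10.0, 2500.0))
    prev_pos = (cx, cy)
    t = e1
    for k in range(n_cue):
        dur = max(snap(total_cue / n_cue), snap(_MIN_FIX_MS))
        pos = _point_in_rect(layout.cue_aoi, rng, margin=50.0, away_from=prev_pos)
        fixations.append(Fixation(t, t + dur, pos[0], pos[1]))
        labels.append(CUE)
        prev_pos = pos
        t = t + dur + dt
    cue_phase_end = fixations[-1].end

    # --- entry to grid --------------------------------------------------
    e2 = snap(float(np.clip(rng.normal(subj["entry_to_grid"], profile.entry_to_grid.within_sd),
                            cue_phase_end + dt, trial_end - 1200.0)))
    e2 = max(e2, cue_phase_end + dt)

    # --- grid search (first-order Markov over cells) ---------------------
    miss_trial = rng.uniform() < profile.miss_probability
    n_cells = len(layout.grid_aois)
    trial_dur_mean = max(120.0, rng.normal(subj["search_fix_duration"],
                                           profile.search_fix_duration.within_sd))
    t = e2
    visited: list[int] = []
    scan: list[tuple[int, Fixation]] = []
    choices = [c for c in range(1, n_cells + 1) if not (miss_trial and c == target)]
    current = int(rng.choice(choices))
    found = False
    while True:
        dur = snap(max(_MIN_FIX_MS, rng.normal(trial_dur_mean, 40.0)))
        if t + dur > trial_end - 120.0:
            break
        rect = layout.grid_aois[current - 1]
        pos = _point_in_rect(rect, rng, margin=60.0, away_from=prev_pos)
        scan.append((current, Fixation(t, t + dur, pos[0], pos[1])))
        prev_pos = pos
        visited.append(current)
        if current == target and not miss_trial:
            found = True
            break
        t = t + dur + dt
        # leave room for the final target fixation plus the motor response
        remaining = (trial_end - 120.0) - t
        if not miss_trial and remaining < 2.5 * trial_dur_mean + 1000.0:
            # time pressure: searchers almost always find the target before
            # the stimulus disappears, so steer the last saccade to it
            current = target
        elif visited and rng.uniform() < profile.revisit_probability:
            current = int(rng.choice(visited))
        else:
            unvisited = [c for c in choices if c not in visited]
            current = int(rng.choice(unvisited if unvisited else choices))

    for cell, fx in scan:
        fixations.append(fx)
        labels.append(cell_label(cell))

    scanpath = Scanpath(fixations, labels)
    responses: list[tuple[float, int]] = []

    # --- response -------------------------------------------------------
    outcome = Outcome.MISSING
    search_end = None
    if found:
        last_fix = scan[-1][1]
        md = max(80.0, rng.normal(subj["motor_delay"], profile.motor_delay.within_sd))
        resp_t = last_fix.end + md
        if resp_t <= trial_end - 20.0:
            u = rng.uniform()
            wrong = int(rng.choice([c for c in range(1, n_cells + 1) if c != target]))
            if u < profile.error_probability:
                responses = [(resp_t, wrong)]
                outcome = Outcome.INCORRECT
            elif u < profile.error_probability + profile.corrected_probability and \
                    resp_t + 500.0 <= trial_end:
                responses = [(resp_t, wrong), (resp_t + rng.uniform(250.0, 450.0), target)]
                outcome = Outcome.CORRECTED
            else:
                responses = [(resp_t, target)]
                outcome = Outcome.CORRECT
            search_end = last_fix.start

    # --- expected segmentation status ------------------------------------
    window_lo, window_hi = stim_onset - 300.0, stim_onset + 1300.0
    if outcome is Outcome.MISSING:
        status, reason = "rejected", "missing_response"
    elif outcome is Outcome.INCORRECT:
        status, reason = "rejected", "incorrect_response"
    elif not window_lo <= e1 <= window_hi:
        status, reason = "rejected", "no_cue_fixation_in_window"
    else:
        status, reason = "valid", None

    features = None
    if status == "valid":
        search_fixs = [fx for _, fx in scan]
        rt = responses[-1][0] - stim_onset if outcome is Outcome.CORRECTED \
            else responses[0][0] - stim_onset
        features = {
            "entry_to_cue": e1,
            "cue_fix_duration": float(sum(f.duration for f, lab in zip(fixations, labels)
                                          if lab == CUE)),
            "cue_fix_count": n_cue,
            "entry_to_grid": e2,
            "search_fix_count": len(search_fixs),
            "search_fix_duration": float(np.mean([f.duration for f in search_fixs])),
            "rt": rt,
        }

    return TrialGroundTruth(
        trial_id=trial_id, outcome=outcome, target_cell=target,
        scanpath=scanpath, encoding_start=e1, encoding_end=e2,
        search_end=search_end, responses=responses,
        expected_status=status, expected_reason=reason, features=features,
    )


def render_stream(truth: GroundTruth, layout: TaskLayout,
                  sampling_rate: float, rng: np.random.Generator,
                  jitter_deg: float = 0.1,
                  track_loss_probability: float = 0.0) -> SampleStream:
    """Render ground-truth fixations to raw samples.

    Within fixations: Gaussian jitter around the centre, clipped at 2.5 SD
    so the dispersion stays strictly below the 2 degree detection
    threshold.  Between fixations: linear saccadic sweeps.  The stretch
    from a trial's last fixation to the next trial's first fixation is
    marked as track loss (blink/inter-trial gap).
    """
    dt = 1000.0 / sampling_rate
    session_end = layout.n_trials * layout.trial_duration
    n = int(round(session_end / dt))
    t = np.arange(n) * dt
    sigma = jitter_deg * layout.screen.px_per_degree

    x = np.zeros(n)
    y = np.zeros(n)
    # valid only while the eye is on a fixation or an intra-trial saccade;
    # everything between a trial's last fixation and the next trial's first
    # fixation is track loss (blink / inter-trial gap)
    valid = np.zeros(n, dtype=bool)
    for i, tr in enumerate(truth.trials):
        onset = i * layout.trial_duration
        for fx in tr.scanpath:
            i0 = int(round((onset + fx.start) / dt))
            i1 = int(round((onset + fx.end) / dt))
            i1 = min(i1, n - 1)
            m = i1 - i0 + 1
            x[i0:i1 + 1] = fx.x + np.clip(rng.normal(0.0, sigma, m),
                                          -2.5 * sigma, 2.5 * sigma)
            y[i0:i1 + 1] = fx.y + np.clip(rng.normal(0.0, sigma, m),
                                          -2.5 * sigma, 2.5 * sigma)
            valid[i0:i1 + 1] = True
    # fill invalid stretches with a linear drift between neighbouring
    # fixation centres (what a tracker would report around blinks)
    anchors = np.nonzero(valid)[0]
    if len(anchors):
        x[~valid] = np.interp(t[~valid], t[anchors], x[anchors])
        y[~valid] = np.interp(t[~valid], t[anchors], y[anchors])
    if track_loss_probability > 0.0:
        valid &= rng.uniform(size=n) >= track_loss_probability

    x = np.clip(x, 0.0, layout.screen.width_px - 1.0)
    y = np.clip(y, 0.0, layout.screen.height_px - 1.0)
    return SampleStream(truth.participant_id, sampling_rate, t, x, y, valid)


def simulate_participant(
    profile: GroupProfile,
    layout: TaskLayout | None = None,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
    render: bool = True,
    sampling_rate: float = 120.0,
    jitter_deg: float = 0.1,
) -> tuple[SampleStream | None, list[TrialMeta], GroundTruth]:
    """Simulate one participant's session.

    Returns the rendered sample stream (None when ``render`` is False),
    recording-relative trial metadata, and the full ground truth.
    """
    layout = layout if layout is not None else TaskLayout()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if profile.entry_to_cue.mean > layout.trial_duration - 2500.0:
        raise ConfigurationError(
            "entry_to_cue mean leaves no room for search within the stimulus window")

    subj = {
        "entry_to_cue": rng.normal(profile.entry_to_cue.mean, profile.entry_to_cue.between_sd),
        "cue_fix_duration": rng.normal(profile.cue_fix_duration.mean,
                                       profile.cue_fix_duration.between_sd),
        "cue_fix_count": rng.normal(profile.cue_fix_count.mean,
                                    profile.cue_fix_count.between_sd),
        "entry_to_grid": rng.normal(profile.entry_to_grid.mean,
                                    profile.entry_to_grid.between_sd),
        "search_fix_duration": rng.normal(profile.search_fix_duration.mean,
                                          profile.search_fix_duration.between_sd),
        "motor_delay": rng.normal(profile.motor_delay.mean, profile.motor_delay.between_sd),
    }
    # keep subject-level means physically sensible
    subj["entry_to_cue"] = float(np.clip(subj["entry_to_cue"], 1750.0, 3250.0))
    subj["entry_to_grid"] = float(max(subj["entry_to_grid"], subj["entry_to_cue"] + 200.0))
    subj["cue_fix_duration"] = float(max(subj["cue_fix_duration"], 150.0))
    subj["search_fix_duration"] = float(max(subj["search_fix_duration"], 140.0))

    trials = []
    metas = []
    dt = 1000.0 / sampling_rate
    for i in range(layout.n_trials):
        target = layout.target_schedule[i]
        tr = _simulate_trial(i + 1, target, profile, layout, subj, rng, dt)
        trials.append(tr)
        onset = i * layout.trial_duration
        metas.append(TrialMeta(
            trial_id=i + 1,
            trial_onset=onset,
            cue_onset=onset + layout.cross_duration,
            target_cell=target,
            responses=[(onset + t, c) for t, c in tr.responses],
            outcome=tr.outcome,
        ))

    truth = GroundTruth(participant_id, profile.group_label, subj, trials)
    stream = render_stream(truth, layout, sampling_rate, rng, jitter_deg) if render else None
    return stream, metas, truth


@dataclass
class StudyParticipant:
    participant_id: str
    group_label: str
    stream: SampleStream | None
    metas: list[TrialMeta]
    truth: GroundTruth


@dataclass
class StudyBundle:
    layout: TaskLayout
    participants: list[StudyParticipant]


def simulate_group_study(
    profiles: dict[str, GroupProfile] | Sequence[GroupProfile] | None = None,
    n_per_group: Sequence[int] = (29, 23, 15, 18),
    layout: TaskLayout | None = None,
    seed: int = 0,
    render: bool = True,
    sampling_rate: float = 120.0,
) -> StudyBundle:
    """Simulate a four-group study; deterministic given ``seed``.

    Each participant gets an independent RNG stream spawned from the
    study seed, so results are reproducible and order-independent.
    """
    if profiles is None:
        profiles = default_profiles()
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    if len(profiles) != len(n_per_group):
        raise ConfigurationError("need one group size per profile")
    for n in n_per_group:
        if n < 2:
            raise ConfigurationError("each group needs at least 2 participants")
    layout = layout if layout is not None else TaskLayout()

    total = int(sum(n_per_group))
    children = np.random.SeedSequence(seed).spawn(total)
    participants = []
    k = 0
    for profile, n in zip(profiles, n_per_group):
        for j in range(n):
            pid = f"{profile.group_label}_{j + 1:02d}"
            rng = np.random.default_rng(children[k])
            stream, metas, truth = simulate_participant(
                profile, layout, rng, participant_id=pid,
                render=render, sampling_rate=sampling_rate)
            participants.append(StudyParticipant(pid, profile.group_label,
                                                 stream, metas, truth))
            k += 1
    return StudyBundle(layout, participants)
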