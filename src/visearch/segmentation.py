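"""AOI labeling, trial-validity rules and two-segment trial splitting.

Every valid trial is split into two adjacent segments:

* *Encoding and initiation of search*: from the onset of the first cue
  fixation (which must fall in a window around cue onset, by default
  1700-3300 ms from trial onset) to the onset of the first grid fixation
  after it.
* *Search*: from that grid fixation to the onset of the last fixation on
  the target cell preceding the (final, correct) button press.

Validity rules are applied in a fixed order, so each rejected trial
carries exactly one, deterministic rejection reason.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import CUE, OUTSIDE, Fixation, Rect, Scanpath, cell_label
from .io_gaze import Outcome, TrialMeta


@dataclass
class AOILayout:
    """Cue and grid-cell rectangles plus the per-trial target mapping."""

    cue: Rect
    grid_cells: list[Rect]
    target_cell_of_trial: Mapping[int, int] = field(default_factory=dict)

    def label_point(self, x: float, y: float) -> str:
        if self.cue.contains(x, y):
            return CUE
        for i, r in enumerate(self.grid_cells):
            if r.contains(x, y):
                return cell_label(i + 1)
        return OUTSIDE

    @classmethod
    def from_task_layout(cls, layout) -> "AOILayout":
        return cls(
            cue=layout.cue_aoi,
            grid_cells=list(layout.grid_aois),
            target_cell_of_trial={i + 1: c for i, c in enumerate(layout.target_schedule)},
        )


class RejectionReason(str, enum.Enum):
    NO_CUE_FIXATION_IN_WINDOW = "no_cue_fixation_in_window"
    PREMATURE_GRID_SCANNING = "premature_grid_scanning"
    INCORRECT_RESPONSE = "incorrect_response"
    MISSING_RESPONSE = "missing_response"
    NO_SEARCH_END = "no_search_end"


@dataclass(frozen=True)
class SegmentationRules:
    """The trial-validity rule set; window bounds are closed on both ends."""

    cue_window_ms: tuple[float, float] = (1700.0, 3300.0)
    max_prescan_fixations: int = 1
    max_prescan_duration_ms: float = 300.0


@dataclass
class SegmentedTrial:
    trial_id: int
    status: str                       # 'valid' | 'rejected'
    rejection_reason: RejectionReason | None
    encoding_start: float | None      # onset of first cue fixation
    encoding_end: float | None        # onset of first grid fixation after it
    search_end: float | None          # onset of last target fixation pre-press
    scanpath: Scanpath                # trial-relative, AOI-labeled

    @property
    def valid(self) -> bool:
        return self.status == "valid"


def label_fixations(fixations: Sequence[Fixation], layout: AOILayout) -> Scanpath:
    """Label each fixation by the AOI containing its centroid."""
    fixations = list(fixations)
    labels = [layout.label_point(f.x, f.y) for f in fixations]
    return Scanpath(fixations, labels)


def _is_grid(label: str) -> bool:
    return label.startswith("cell_")


def segment_trial(scanpath: Scanpath, meta: TrialMeta,
                  rules: SegmentationRules = SegmentationRules()) -> SegmentedTrial:
    """Apply the validity rules, in order, and split a trial into segments.

    ``scanpath`` must be AOI-labeled with trial-relative times (trial
    onset = 0); response times in ``meta`` are recording-relative and
    converted internally.
    """
    if scanpath.labels is None:
        raise ValueError("scanpath must be AOI-labeled (call label_fixations first)")
    starts = [f.start for f in scanpath]
    if starts != sorted(starts):
        raise ValueError("fixations must be time-sorted")

    def rejected(reason: RejectionReason,
                 enc_start=None, enc_end=None) -> SegmentedTrial:
        return SegmentedTrial(meta.trial_id, "rejected", reason,
                              enc_start, enc_end, None, scanpath)

    # (1) outcome filter
    if meta.outcome is Outcome.MISSING:
        return rejected(RejectionReason.MISSING_RESPONSE)
    if meta.outcome is Outcome.INCORRECT:
        return rejected(RejectionReason.INCORRECT_RESPONSE)

    # (2) cue-window rule: onset of the first cue fixation in [lo, hi]
    lo, hi = rules.cue_window_ms
    cue_idx = next((i for i, lab in enumerate(scanpath.labels) if lab == CUE), None)
    if cue_idx is None or not lo <= scanpath[cue_idx].start <= hi:
        return rejected(RejectionReason.NO_CUE_FIXATION_IN_WINDOW)
    enc_start = scanpath[cue_idx].start

    # (3) pre-scan rule: before that cue fixation, at most
    #     max_prescan_fixations grid fixations, each within the duration cap
    prescan = [scanpath[i] for i in range(cue_idx) if _is_grid(scanpath.labels[i])]
    if len(prescan) > rules.max_prescan_fixations or \
            any(f.duration > rules.max_prescan_duration_ms for f in prescan):
        return rejected(RejectionReason.PREMATURE_GRID_SCANNING)

    # (4) encoding end: onset of first grid fixation after the cue fixation
    grid_idx = next((i for i in range(cue_idx + 1, len(scanpath))
                     if _is_grid(scanpath.labels[i])), None)
    if grid_idx is None:
        return rejected(RejectionReason.NO_SEARCH_END, enc_start)
    enc_end = scanpath[grid_idx].start

    # (5) search end: onset of last target fixation before the final correct press
    press = meta.final_correct_response_time
    press_rel = press - meta.trial_onset
    if press_rel <= enc_end:
        return rejected(RejectionReason.NO_SEARCH_END, enc_start, enc_end)
    target_label = cell_label(meta.target_cell)
    search_end = None
    for i in range(grid_idx, len(scanpath)):
        f = scanpath[i]
        if scanpath.labels[i] == target_label and enc_end <= f.start < press_rel:
            search_end = f.start
    if search_end is None:
        return rejected(RejectionReason.NO_SEARCH_END, enc_start, enc_end)

    return SegmentedTrial(meta.trial_id, "valid", None,
                          enc_start, enc_end, search_end, scanpath)


@dataclass(frozen=True)
class ValidityCounts:
    """Per-participant trial bookkeeping; the four buckets partition the
    trial list (``rejected_other`` collects segmentation rejections that
    are neither incorrect nor missing)."""

    valid: int
    incorrect: int
    missing: int
    rejected_other: int

    @property
    def total(self) -> int:
        return self.valid + self.incorrect + self.missing + self.rejected_other


def tabulate_validity(trials: Sequence[SegmentedTrial]) -> ValidityCounts:
    valid = sum(1 for t in trials if t.valid)
    incorrect = sum(1 for t in trials
                    if t.rejection_reason is RejectionReason.INCORRECT_RESPONSE)
    missing = sum(1 for t in trials
                  if t.rejection_reason is RejectionReason.MISSING_RESPONSE)
    return ValidityCounts(valid, incorrect, missing,
                          len(trials) - valid - incorrect - missing)
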