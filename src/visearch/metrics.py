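"""Per-trial dependent variables and per-participant mean/SD summaries.

Means over valid trials index performance; sample SDs over valid trials
(denominator n-1) index intra-subject variability (ISV).  Reaction-time
summaries (rt_mean, rtsd) are computed the same way; RTSD is the raw SD
of reaction times, not a coefficient of variation.

Times are trial-relative (trial onset = 0), so entry times can be
re-expressed relative to cue onset by subtracting the cross duration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CUE
from .io_gaze import TrialMeta
from .segmentation import SegmentedTrial

FEATURE_NAMES = (
    "entry_to_cue", "cue_fix_duration", "cue_fix_count",
    "entry_to_grid", "search_fix_count", "search_fix_duration",
)


@dataclass(frozen=True)
class TrialFeatures:
    trial_id: int
    entry_to_cue: float        # onset of first cue fixation, ms from trial onset
    cue_fix_duration: float    # total cue-fixation duration within encoding
    cue_fix_count: int
    entry_to_grid: float       # onset of first grid fixation after cue
    search_fix_count: int
    search_fix_duration: float  # per-fixation mean within the search segment
    rt: float                  # final correct press, ms from stimulus onset


def trial_features(seg: SegmentedTrial, meta: TrialMeta,
                   cue_fix_duration_mode: str = "total") -> TrialFeatures:
    """Compute the per-trial dependent variables for a valid trial.

    ``cue_fix_duration_mode``: 'total' (sum over cue fixations in the
    encoding segment, the default) or 'mean' (per-fixation mean).
    """
    if not seg.valid:
        raise ValueError(f"trial {seg.trial_id} is rejected; features undefined")
    sp = seg.scanpath
    # cue fixations within the encoding segment [enc_start, enc_end)
    cue_durs = [f.duration for f, lab in zip(sp.fixations, sp.labels)
                if lab == CUE and seg.encoding_start <= f.start < seg.encoding_end]
    # search fixations: onsets within [search_start, search_end]
    search_durs = [f.duration for f in sp.fixations
                   if seg.encoding_end <= f.start <= seg.search_end]
    cue_total = float(sum(cue_durs))
    cue_dur = cue_total if cue_fix_duration_mode == "total" else cue_total / len(cue_durs)
    press = meta.final_correct_response_time - meta.trial_onset
    stimulus_onset = meta.cue_onset - meta.trial_onset
    return TrialFeatures(
        trial_id=seg.trial_id,
        entry_to_cue=seg.encoding_start,
        cue_fix_duration=cue_dur,
        cue_fix_count=len(cue_durs),
        entry_to_grid=seg.encoding_end,
        search_fix_count=len(search_durs),
        search_fix_duration=float(np.mean(search_durs)),
        rt=press - stimulus_onset,
    )


@dataclass
class ParticipantSummary:
    participant_id: str
    group_label: str
    n_valid: int
    means: dict[str, float]
    sds: dict[str, float]      # the ISV measure; NaN when n_valid < 2
    rt_mean: float
    rtsd: float

    def as_row(self) -> dict:
        row = {"participant_id": self.participant_id,
               "group_label": self.group_label, "n_valid": self.n_valid}
        for k in FEATURE_NAMES:
            row[f"mean_{k}"] = self.means[k]
            row[f"sd_{k}"] = self.sds[k]
        row["rt_mean"] = self.rt_mean
        row["rtsd"] = self.rtsd
        return row


def _sd(values: np.ndarray) -> float:
    # sample SD (n-1); undefined (NaN) for a single trial, never 0
    return float(np.std(values, ddof=1)) if len(values) >= 2 else math.nan


def summarize_participant(features: Sequence[TrialFeatures],
                          participant_id: str, group_label: str,
                          min_trials: int = 10) -> ParticipantSummary | None:
    """Mean and sample SD of every feature over a participant's valid trials.

    Returns None (participant excluded) when fewer than ``min_trials``
    valid trials are available.
    """
    if len(features) < min_trials:
        return None
    means, sds = {}, {}
    for name in FEATURE_NAMES:
        vals = np.array([getattr(f, name) for f in features], dtype=float)
        means[name] = float(np.mean(vals))
        sds[name] = _sd(vals)
    rts = np.array([f.rt for f in features], dtype=float)
    return ParticipantSummary(
        participant_id=participant_id, group_label=group_label,
        n_valid=len(features), means=means, sds=sds,
        rt_mean=float(np.mean(rts)), rtsd=_sd(rts),
    )
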