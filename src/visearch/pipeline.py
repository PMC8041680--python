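"""End-to-end orchestration: simulate -> detect -> segment -> metrics ->
RQA -> MultiMatch -> group stats, with a serializable run config and a
reproducibility manifest.

Every stage is a pure function of (inputs, config, seed); re-running
with the same config reproduces all output tables bit-identically.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import Scanpath
from .fixations import DetectorConfig, detect_fixations
from .io_gaze import SampleStream, ScreenGeometry, TrialMeta, write_table
from .metrics import FEATURE_NAMES, ParticipantSummary, summarize_participant, trial_features
from .multimatch import DIMENSIONS, MultiMatchConfig, multimatch_isv
from .rqa import MEASURES, rqa_isv_subtracted, rqa_trial
from .segmentation import (AOILayout, SegmentationRules, SegmentedTrial,
                           label_fixations, segment_trial, tabulate_validity)
from .simulate import (GroupProfile, TaskLayout, default_profiles,
                       simulate_group_study)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input id."""

    def __init__(self, stage: str, input_id: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed on '{input_id}': {cause}")
        self.stage = stage
        self.input_id = input_id


@dataclass
class RunConfig:
    seed: int = 0
    n_per_group: tuple[int, ...] = (29, 23, 15, 18)
    sampling_rate: float = 120.0
    n_trials: int = 30
    min_trials: int = 10
    min_line_length: int = 2
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    rules: SegmentationRules = field(default_factory=SegmentationRules)
    multimatch: MultiMatchConfig = field(default_factory=MultiMatchConfig)
    outlier_k_sd: dict = field(default_factory=dict)  # variable -> k
    out_dir: str = "visearch_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_per_group"] = list(self.n_per_group)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "detector" in kwargs:
            det = dict(kwargs["detector"])
            if "screen" in det:
                det["screen"] = ScreenGeometry(**det["screen"])
            kwargs["detector"] = DetectorConfig(**det)
        if "rules" in kwargs:
            r = dict(kwargs["rules"])
            if "cue_window_ms" in r:
                r["cue_window_ms"] = tuple(r["cue_window_ms"])
            kwargs["rules"] = SegmentationRules(**r)
        if "multimatch" in kwargs:
            mm = dict(kwargs["multimatch"])
            if "screen" in mm:
                mm["screen"] = ScreenGeometry(**mm["screen"])
            kwargs["multimatch"] = MultiMatchConfig(**mm)
        if "n_per_group" in kwargs:
            kwargs["n_per_group"] = tuple(kwargs["n_per_group"])
        return cls(**kwargs)


@dataclass
class ParticipantResult:
    participant_id: str
    group_label: str
    segmented: list[SegmentedTrial]
    features: list
    summary: ParticipantSummary | None
    rqa_by_trial: dict
    rqa_means: dict[str, float]
    rqa_sds: dict[str, float]
    rqa_isv: dict[str, float] | None
    mm_isv: dict[str, float] | None


def split_fixations_by_trial(fixations, n_trials: int, trial_duration: float):
    """Assign detected fixations (recording time) to trials by onset and
    convert them to trial-relative times."""
    from .core import Fixation
    per_trial: list[list] = [[] for _ in range(n_trials)]
    for f in fixations:
        i = int(f.start // trial_duration)
        if 0 <= i < n_trials:
            onset = i * trial_duration
            per_trial[i].append(Fixation(f.start - onset, f.end - onset, f.x, f.y))
    return per_trial


def search_scanpath(seg: SegmentedTrial) -> Scanpath:
    """The search-segment slice of a labeled trial scanpath (onsets in
    [encoding_end, search_end])."""
    idx = [i for i, f in enumerate(seg.scanpath)
           if seg.encoding_end <= f.start <= seg.search_end]
    return seg.scanpath.subpath(idx)


def process_participant(stream: SampleStream, metas: Sequence[TrialMeta],
                        layout: TaskLayout, cfg: RunConfig,
                        group_label: str = "") -> ParticipantResult:
    """Run detection, segmentation, metrics, RQA and MultiMatch for one
    participant's recording."""
    pid = stream.participant_id
    aois = AOILayout.from_task_layout(layout)
    fixations = detect_fixations(stream, cfg.detector)
    per_trial = split_fixations_by_trial(fixations, layout.n_trials,
                                         layout.trial_duration)
    segmented = []
    for meta, fixs in zip(metas, per_trial):
        sp = label_fixations(fixs, aois)
        segmented.append(segment_trial(sp, meta, cfg.rules))

    feats = [trial_features(s, m) for s, m in zip(segmented, metas) if s.valid]
    summary = summarize_participant(feats, pid, group_label, cfg.min_trials)

    targets = {m.trial_id: m.target_cell for m in metas}
    rqa_by_trial = {}
    paths = {}
    for s in segmented:
        if not s.valid:
            continue
        sp = search_scanpath(s)
        res = rqa_trial(sp, cfg.min_line_length, s.trial_id)
        if res is not None:
            rqa_by_trial[s.trial_id] = res
        if len(sp) >= 2:
            paths[s.trial_id] = sp

    rqa_means, rqa_sds = {}, {}
    for m in MEASURES:
        vals = np.array([getattr(r, m) for r in rqa_by_trial.values()], dtype=float)
        vals = vals[~np.isnan(vals)]
        rqa_means[m] = float(vals.mean()) if len(vals) else math.nan
        rqa_sds[m] = float(vals.std(ddof=1)) if len(vals) >= 2 else math.nan

    rqa_isv = rqa_isv_subtracted(rqa_by_trial, targets) if rqa_by_trial else None
    mm_isv = multimatch_isv(paths, targets, cfg.multimatch) if paths else None
    return ParticipantResult(pid, group_label, segmented, feats, summary,
                             rqa_by_trial, rqa_means, rqa_sds, rqa_isv, mm_isv)


def participant_table(results: Sequence[ParticipantResult]) -> pd.DataFrame:
    """One row per included participant: metric summaries plus RQA and
    MultiMatch per-participant values."""
    rows = []
    for r in results:
        if r.summary is None:
            continue
        row = r.summary.as_row()
        for m in MEASURES:
            row[f"mean_{m}"] = r.rqa_means[m]
            row[f"sd_{m}"] = r.rqa_sds[m]
            row[f"sub_{m}"] = r.rqa_isv[m] if r.rqa_isv else math.nan
        for d in DIMENSIONS:
            row[f"mm_{d}"] = r.mm_isv[d] if r.mm_isv else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


DEFAULT_STAT_VARIABLES = tuple(
    [f"mean_{v}" for v in FEATURE_NAMES] + [f"sd_{v}" for v in FEATURE_NAMES]
    + ["rt_mean", "rtsd"]
    + [f"mean_{m}" for m in MEASURES] + [f"sd_{m}" for m in MEASURES]
)


def group_statistics(table: pd.DataFrame,
                     variables: Sequence[str] = DEFAULT_STAT_VARIABLES,
                     outlier_k_sd: Mapping[str, float] | None = None):
    """ANOVA + Tukey for each variable of the participant table."""
    from .group_stats import compare_groups
    outlier_k_sd = outlier_k_sd or {}
    comparisons = []
    for var in variables:
        if var not in table.columns:
            continue
        by_group = {g: sub[var].to_numpy(dtype=float)
                    for g, sub in table.groupby("group_label", sort=True)}
        ids = {g: list(sub["participant_id"])
               for g, sub in table.groupby("group_label", sort=True)}
        try:
            comparisons.append(compare_groups(
                by_group, var, outlier_k_sd.get(var), ids))
        except ValueError as e:
            raise StageError("stats", var, e)
    return comparisons


def run_all(cfg: RunConfig,
            profiles: dict[str, GroupProfile] | None = None) -> Path:
    """Simulate a study under ``cfg`` and run the full analysis, writing
    all result tables plus a manifest to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = profiles or default_profiles()

    layout = TaskLayout(
        screen=cfg.detector.screen, n_trials=cfg.n_trials,
        target_schedule=[], )
    try:
        bundle = simulate_group_study(profiles, cfg.n_per_group, layout,
                                      cfg.seed, render=True,
                                      sampling_rate=cfg.sampling_rate)
    except Exception as e:  # pragma: no cover - defensive
        raise StageError("simulate", "study", e)

    results, validity_rows, feature_rows, rqa_rows = [], [], [], []
    for p in bundle.participants:
        try:
            r = process_participant(p.stream, p.metas, layout, cfg, p.group_label)
        except Exception as e:
            raise StageError("process", p.participant_id, e)
        results.append(r)
        counts = tabulate_validity(r.segmented)
        validity_rows.append({
            "participant_id": p.participant_id, "group_label": p.group_label,
            "valid": counts.valid, "incorrect": counts.incorrect,
            "missing": counts.missing, "rejected_other": counts.rejected_other,
        })
        for f in r.features:
            row = {"participant_id": p.participant_id, **f.__dict__}
            feature_rows.append(row)
        for res in r.rqa_by_trial.values():
            rqa_rows.append({"participant_id": p.participant_id, **res.__dict__})

    table = participant_table(results)
    comparisons = group_statistics(table, outlier_k_sd=cfg.outlier_k_sd)

    write_table(pd.DataFrame(feature_rows), out / "trial_features.tsv")
    write_table(pd.DataFrame(validity_rows), out / "trial_validity.tsv")
    write_table(table, out / "participant_summary.tsv")
    write_table(pd.DataFrame(rqa_rows), out / "rqa_trials.tsv")
    write_table(table[["participant_id", "group_label"]
                      + [c for c in table.columns if c.startswith("sub_")]],
                out / "rqa_isv.tsv")
    write_table(table[["participant_id", "group_label"]
                      + [c for c in table.columns if c.startswith("mm_")]],
                out / "multimatch_isv.tsv")

    stat_rows, posthoc_rows = [], []
    for c in comparisons:
        stat_rows.append({
            "variable": c.variable, "F": c.F, "df_between": c.df_between,
            "df_error": c.df_error, "p": c.p, "eta_squared": c.eta_squared,
            "outliers_removed": ";".join(c.outliers_removed),
        })
        for ph in c.posthoc:
            posthoc_rows.append({"variable": c.variable, **ph.__dict__})
    write_table(pd.DataFrame(stat_rows), out / "group_stats.tsv")
    write_table(pd.DataFrame(posthoc_rows), out / "group_posthoc.tsv")

    cfg_dict = cfg.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "visearch_version": __version__,
        "numpy_version": np.__version__,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return out
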