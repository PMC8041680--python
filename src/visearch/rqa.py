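"""Categorical recurrence quantification analysis (RQA) of scanpaths.

Two fixations recur when they land in the same AOI.  Over the binary
upper-triangular recurrence matrix of a trial's search-segment scanpath
(N fixations, R recurrent pairs) the four standard measures are:

* Recurrence   REC  = 100 * 2R / (N(N-1)) — density of recurrent pairs.
* Determinism  DET  = 100 * |D_L| / R — fraction of recurrent points on
  diagonal line structures of length >= L (repeated sub-scanpaths).
* Laminarity   LAM  = 100 * (|H_L| + |V_L|) / (2R) — fraction on
  horizontal/vertical lines (prolonged dwelling on one AOI).
* CORM = 100 * sum (j - i) r_ij / ((N-1) R) — lag-weighted centre of
  recurrence mass; lower values mean revisits happen closer in time.

Fixations outside every AOI stay in the sequence (preserving the lag
structure) but carry unique labels so they never recur.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import OUTSIDE, Scanpath

MEASURES = ("recurrence", "determinism", "laminarity", "corm")


@dataclass
class RecurrenceMatrix:
    n: int
    matrix: np.ndarray  # full symmetric 0/1 matrix, zero diagonal

    @property
    def R(self) -> int:
        return int(np.triu(self.matrix, k=1).sum())


@dataclass(frozen=True)
class RQAResult:
    trial_id: int | None
    n: int
    R: int
    recurrence: float
    determinism: float  # NaN when R == 0
    laminarity: float   # NaN when R == 0
    corm: float         # NaN when R == 0
    min_line_length: int = 2


def recurrence_matrix(labels: Sequence[str] | Scanpath) -> RecurrenceMatrix:
    """Binary recurrence matrix of an AOI label sequence (N >= 2)."""
    if isinstance(labels, Scanpath):
        if labels.labels is None:
            raise ValueError("scanpath must be AOI-labeled")
        labels = labels.labels
    labels = list(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 fixations for a recurrence matrix")
    # outside fixations get unique non-matching symbols
    keyed = [f"__out_{i}" if lab == OUTSIDE else lab for i, lab in enumerate(labels)]
    arr = np.array(keyed)
    m = (arr[:, None] == arr[None, :]).astype(np.int8)
    np.fill_diagonal(m, 0)
    return RecurrenceMatrix(n=n, matrix=m)


def _diagonal_points(m: np.ndarray, L: int) -> int:
    """Recurrent points on diagonal lines (length >= L) in the upper triangle."""
    n = m.shape[0]
    count = 0
    for d in range(1, n):
        diag = np.diagonal(m, offset=d)
        count += _run_points(diag, L)
    return count


def _run_points(seq: np.ndarray, L: int) -> int:
    count = run = 0
    for v in seq:
        if v:
            run += 1
        else:
            if run >= L:
                count += run
            run = 0
    if run >= L:
        count += run
    return count


def _hv_points(m: np.ndarray, L: int) -> tuple[int, int]:
    """Points on horizontal / vertical lines (length >= L), upper triangle."""
    n = m.shape[0]
    horiz = sum(_run_points(m[i, i + 1:], L) for i in range(n))
    vert = sum(_run_points(m[:j, j], L) for j in range(n))
    return horiz, vert


def rqa_measures(rm: RecurrenceMatrix, min_line_length: int = 2,
                 trial_id: int | None = None) -> RQAResult:
    """The four RQA measures of a recurrence matrix.

    With R = 0, recurrence is 0 and the structure measures are NaN.
    """
    n, m = rm.n, rm.matrix
    R = rm.R
    rec = 100.0 * 2.0 * R / (n * (n - 1))
    if R == 0:
        return RQAResult(trial_id, n, 0, rec, math.nan, math.nan, math.nan,
                         min_line_length)
    det = 100.0 * _diagonal_points(m, min_line_length) / R
    h, v = _hv_points(m, min_line_length)
    lam = 100.0 * (h + v) / (2.0 * R)
    i, j = np.nonzero(np.triu(m, k=1))
    corm = 100.0 * float(np.sum(j - i)) / ((n - 1) * R)
    return RQAResult(trial_id, n, R, rec, det, lam, corm, min_line_length)


def rqa_trial(scanpath: Scanpath, min_line_length: int = 2,
              trial_id: int | None = None) -> RQAResult | None:
    """RQA of one search-segment scanpath; None when N < 2."""
    if len(scanpath) < 2:
        return None
    return rqa_measures(recurrence_matrix(scanpath), min_line_length, trial_id)


def rqa_isv_subtracted(trial_results: Mapping[int, RQAResult],
                       target_cells: Mapping[int, int]) -> dict[str, float] | None:
    """Same-target-cell subtracted RQA: an ISV measure per participant.

    For each target cell with >= 2 valid trials, take all pairwise
    absolute differences of each RQA measure across that cell's trials;
    the participant value is the mean over all such pairs.  Returns None
    when no cell has a comparable pair.
    """
    by_cell: dict[int, list[RQAResult]] = {}
    for trial_id, res in trial_results.items():
        if res is None:
            continue
        cell = target_cells[trial_id]
        by_cell.setdefault(cell, []).append(res)

    diffs: dict[str, list[float]] = {m: [] for m in MEASURES}
    for results in by_cell.values():
        for a, b in itertools.combinations(results, 2):
            for m in MEASURES:
                va, vb = getattr(a, m), getattr(b, m)
                if not (math.isnan(va) or math.isnan(vb)):
                    diffs[m].append(abs(va - vb))
    if not any(diffs[m] for m in MEASURES):
        return None
    return {m: (float(np.mean(diffs[m])) if diffs[m] else math.nan)
            for m in MEASURES}
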