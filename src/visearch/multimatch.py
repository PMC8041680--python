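"""MultiMatch scanpath similarity.

Each scanpath is reduced to its sequence of saccade vectors, simplified
by merging small or near-collinear consecutive saccades, aligned to the
other path by a minimum-cost monotone matching on vector differences,
and scored on five normalized dimensions (vector/shape, length,
direction, position, duration), each in [0, 1] with 1 = identical.

Low similarity between two trials of the same participant (same target
cell) indicates high intra-subject variability.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import Fixation, Scanpath
from .io_gaze import ScreenGeometry


@dataclass(frozen=True)
class MultiMatchConfig:
    """Simplification thresholds and aggregation choice.

    ``amp_threshold`` is a fraction of the screen diagonal; ``aggregate``
    is 'median' (default) or 'mean' over the alignment's normalized
    differences.
    """

    amp_threshold: float = 0.10
    dir_threshold_deg: float = 45.0
    dur_threshold_ms: float = 300.0
    aggregate: str = "median"
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)

    def __post_init__(self) -> None:
        if self.aggregate not in ("median", "mean"):
            raise ValueError("aggregate must be 'median' or 'mean'")


@dataclass(frozen=True)
class MultiMatchResult:
    vector_similarity: float
    length_similarity: float
    direction_similarity: float
    position_similarity: float
    duration_similarity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "vector": self.vector_similarity,
            "length": self.length_similarity,
            "direction": self.direction_similarity,
            "position": self.position_similarity,
            "duration": self.duration_similarity,
        }


DIMENSIONS = ("vector", "length", "direction", "position", "duration")


def _vectors(path: Scanpath) -> np.ndarray:
    xy = np.array([(f.x, f.y) for f in path], dtype=float)
    return np.diff(xy, axis=0)


def _angle_between(v: np.ndarray, w: np.ndarray) -> float:
    """Unsigned angle between two vectors in [0, pi]; 0 if either is null."""
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0.0 or nw == 0.0:
        return 0.0
    c = float(np.dot(v, w) / (nv * nw))
    return math.acos(max(-1.0, min(1.0, c)))


def simplify_scanpath(path: Scanpath, cfg: MultiMatchConfig = MultiMatchConfig()) -> Scanpath:
    """Merge consecutive saccades until no merge applies (idempotent).

    Two consecutive saccades merge when (a) both amplitudes are below
    ``amp_threshold`` x screen diagonal and the fixation between them is
    shorter than ``dur_threshold_ms`` (amplitude merge), or (b) their
    directions differ by less than ``dir_threshold_deg`` (direction
    merge).  The merged saccade is the vector sum; the absorbed middle
    fixation's duration is added to the preceding fixation.
    """
    if len(path) < 3:
        return path
    fixs = list(path.fixations)
    amp_px = cfg.amp_threshold * cfg.screen.diagonal_px
    dir_rad = math.radians(cfg.dir_threshold_deg)

    changed = True
    while changed and len(fixs) >= 3:
        changed = False
        for k in range(len(fixs) - 2):
            a, b, c = fixs[k], fixs[k + 1], fixs[k + 2]
            v1 = np.array([b.x - a.x, b.y - a.y])
            v2 = np.array([c.x - b.x, c.y - b.y])
            amp_ok = (np.linalg.norm(v1) < amp_px and np.linalg.norm(v2) < amp_px
                      and b.duration < cfg.dur_threshold_ms)
            dir_ok = _angle_between(v1, v2) < dir_rad
            if amp_ok or dir_ok:
                # drop b; extend a's duration by b's
                fixs[k] = Fixation(a.start, a.end + b.duration, a.x, a.y)
                del fixs[k + 1]
                changed = True
                break
    # rebuild without labels: simplified paths are geometric objects
    rebuilt = []
    t = 0.0
    for f in fixs:
        rebuilt.append(Fixation(t, t + f.duration, f.x, f.y))
        t += f.duration + 1.0
    return Scanpath(rebuilt)


def align_scanpaths(p: Scanpath, q: Scanpath) -> list[tuple[int, int]]:
    """Minimum-cost monotone alignment of the two saccade-vector sequences.

    Cost of matching vectors i and j is the Euclidean norm of their
    difference; the alignment is the cheapest path from (0, 0) to
    (n-1, m-1) moving right, down, or diagonally.
    """
    V, W = _vectors(p), _vectors(q)
    n, m = len(V), len(W)
    if n == 0 or m == 0:
        raise ValueError("both scanpaths need at least one saccade vector")
    diff = V[:, None, :] - W[None, :, :]
    M = np.linalg.norm(diff, axis=2)

    # dynamic program over the DAG of right/down/diagonal moves
    D = np.full((n, m), np.inf)
    D[0, 0] = M[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, D[i - 1, j])
            if j > 0:
                best = min(best, D[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, D[i - 1, j - 1])
            D[i, j] = M[i, j] + best

    # backtrack (prefer diagonal on ties for the shortest alignment)
    pairs = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        cands = []
        if i > 0 and j > 0:
            cands.append((D[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            cands.append((D[i - 1, j], (i - 1, j)))
        if j > 0:
            cands.append((D[i, j - 1], (i, j - 1)))
        _, (i, j) = min(cands, key=lambda c: c[0])
        pairs.append((i, j))
    pairs.reverse()
    return pairs


def alignment_cost(p: Scanpath, q: Scanpath) -> float:
    """Total cost of the optimal alignment (sum of matched-vector norms)."""
    V, W = _vectors(p), _vectors(q)
    pairs = align_scanpaths(p, q)
    return float(sum(np.linalg.norm(V[i] - W[j]) for i, j in pairs))


def _aggregate(diffs: list[float], how: str) -> float:
    arr = np.array([d for d in diffs if not math.isnan(d)], dtype=float)
    if arr.size == 0:
        return math.nan
    return float(np.median(arr) if how == "median" else np.mean(arr))


def similarity_dimensions(p: Scanpath, q: Scanpath,
                          alignment: Sequence[tuple[int, int]],
                          cfg: MultiMatchConfig = MultiMatchConfig()) -> MultiMatchResult:
    """Score the five similarity dimensions over an alignment.

    Normalizations: vector difference by 2x screen diagonal, length and
    position by the diagonal, direction by pi, duration by the longer of
    the two fixation durations.  Position and duration compare the
    source fixation of each aligned saccade vector.
    """
    V, W = _vectors(p), _vectors(q)
    diag = cfg.screen.diagonal_px
    vec_d, len_d, dir_d, pos_d, dur_d = [], [], [], [], []
    for i, j in alignment:
        v, w = V[i], W[j]
        vec_d.append(float(np.linalg.norm(v - w)) / (2.0 * diag))
        len_d.append(abs(float(np.linalg.norm(v)) - float(np.linalg.norm(w))) / diag)
        dir_d.append(_angle_between(v, w) / math.pi)
        fp, fq = p[i], q[j]
        pos_d.append(math.hypot(fp.x - fq.x, fp.y - fq.y) / diag)
        dmax = max(fp.duration, fq.duration)
        dur_d.append(abs(fp.duration - fq.duration) / dmax if dmax > 0 else math.nan)
    agg = cfg.aggregate
    return MultiMatchResult(
        vector_similarity=1.0 - _aggregate(vec_d, agg),
        length_similarity=1.0 - _aggregate(len_d, agg),
        direction_similarity=1.0 - _aggregate(dir_d, agg),
        position_similarity=1.0 - _aggregate(pos_d, agg),
        duration_similarity=1.0 - _aggregate(dur_d, agg),
    )


def compare_scanpaths(p: Scanpath, q: Scanpath,
                      cfg: MultiMatchConfig = MultiMatchConfig(),
                      simplify: bool = True) -> MultiMatchResult | None:
    """Full MultiMatch comparison of two scanpaths; None when either path
    has fewer than 2 fixations after simplification."""
    if simplify:
        p, q = simplify_scanpath(p, cfg), simplify_scanpath(q, cfg)
    if len(p) < 2 or len(q) < 2:
        return None
    alignment = align_scanpaths(p, q)
    return similarity_dimensions(p, q, alignment, cfg)


def multimatch_isv(trial_paths: Mapping[int, Scanpath],
                   target_cells: Mapping[int, int],
                   cfg: MultiMatchConfig = MultiMatchConfig()) -> dict[str, float] | None:
    """Per-participant mean similarity over all same-target-cell trial pairs.

    Lower mean similarity = higher intra-subject variability.  Returns
    None when no cell has two comparable trials.
    """
    import itertools

    by_cell: dict[int, list[Scanpath]] = {}
    for trial_id, path in trial_paths.items():
        by_cell.setdefault(target_cells[trial_id], []).append(path)

    sums = {d: [] for d in DIMENSIONS}
    for paths in by_cell.values():
        for a, b in itertools.combinations(paths, 2):
            res = compare_scanpaths(a, b, cfg)
            if res is None:
                continue
            for d, v in res.as_dict().items():
                if not math.isnan(v):
                    sums[d].append(v)
    if not any(sums[d] for d in DIMENSIONS):
        return None
    return {d: (float(np.mean(sums[d])) if sums[d] else math.nan)
            for d in DIMENSIONS}
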