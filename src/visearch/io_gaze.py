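"""Reading and writing the pipeline's delimited-text formats.

Canonical on-disk format is plain UTF-8 TSV with a one-line header.  A
:class:`SampleDialect` maps vendor column names (e.g. SMI exports) onto
the canonical ``t``/``x``/``y``/``valid`` schema and carries an explicit
missing-data policy; nothing is silently dropped.
"""
from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Fixation

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A file does not have the expected columns."""


class DataError(ValueError):
    """A file has the right columns but invalid content."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry used for pixel <-> visual-angle conversion.

    ``px_per_degree`` follows the small-angle formula from the physical
    screen width and viewing distance; the defaults describe a 1920x1080
    display, 47.4 cm wide, viewed from 70 cm.
    """

    width_px: int = 1920
    height_px: int = 1080
    viewing_distance_cm: float = 70.0
    screen_width_cm: float = 47.4

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) <= 0:
            raise ValueError("screen dimensions must be positive")
        if min(self.viewing_distance_cm, self.screen_width_cm) <= 0:
            raise ValueError("physical geometry must be positive")

    @property
    def px_per_cm(self) -> float:
        return self.width_px / self.screen_width_cm

    @property
    def px_per_degree(self) -> float:
        cm_per_degree = self.viewing_distance_cm * math.tan(math.radians(1.0))
        return self.px_per_cm * cm_per_degree

    @property
    def diagonal_px(self) -> float:
        return math.hypot(self.width_px, self.height_px)


class Outcome(str, enum.Enum):
    CORRECT = "correct"
    CORRECTED = "corrected"
    INCORRECT = "incorrect"
    MISSING = "missing"


@dataclass
class TrialMeta:
    """Trial-level metadata: onsets, target cell and button responses.

    ``responses`` are (t_ms, cell_pressed) in recording time, ordered.
    A ``corrected`` outcome means the first press was wrong and a later
    press hit the target cell; such trials count as correct downstream.
    """

    trial_id: int
    trial_onset: float
    cue_onset: float
    target_cell: int
    responses: list[tuple[float, int]] = field(default_factory=list)
    outcome: Outcome = Outcome.MISSING

    def __post_init__(self) -> None:
        self.outcome = Outcome(self.outcome)
        if not 1 <= self.target_cell:
            raise ValueError("target_cell must be a positive cell index")
        if self.cue_onset < self.trial_onset:
            raise ValueError("cue_onset precedes trial_onset")
        ts = [t for t, _ in self.responses]
        if ts != sorted(ts):
            raise ValueError("responses must be ordered in time")
        if self.outcome is Outcome.CORRECT:
            if not self.responses or self.responses[0][1] != self.target_cell:
                raise ValueError("correct outcome requires first response on target")
        elif self.outcome is Outcome.CORRECTED:
            if len(self.responses) < 2 or self.responses[-1][1] != self.target_cell:
                raise ValueError(
                    "corrected outcome requires >=2 responses ending on target"
                )

    @property
    def final_correct_response_time(self) -> float | None:
        """Time of the press that decided the trial (None if missing/incorrect)."""
        if self.outcome is Outcome.CORRECT:
            return self.responses[0][0]
        if self.outcome is Outcome.CORRECTED:
            return self.responses[-1][0]
        return None


@dataclass
class SampleStream:
    """Raw gaze samples for one participant.

    Track-loss samples are kept in place with ``valid=False`` so that
    sample indices and timing stay faithful to the recording.
    """

    participant_id: str
    sampling_rate: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("sample arrays must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if n > 1:
            dt = np.diff(self.t)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                # bad[k] flags t[bad[k]+1] <= t[bad[k]]; report 1-based row
                raise DataError(
                    f"time not strictly increasing at row {int(bad[0]) + 2}"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def window(self, t0: float, t1: float) -> "SampleStream":
        """Samples with t in the half-open window [t0, t1)."""
        m = (self.t >= t0) & (self.t < t1)
        return SampleStream(
            self.participant_id, self.sampling_rate,
            self.t[m], self.x[m], self.y[m], self.valid[m],
        )


@dataclass(frozen=True)
class SampleDialect:
    """Column mapping + missing-data policy for sample files.

    ``missing_policy``: 'flag' keeps rows with missing coordinates and
    marks them invalid; 'drop' removes them (counted and logged).
    """

    time_col: str = "t"
    x_col: str = "x"
    y_col: str = "y"
    valid_col: str | None = "valid"
    delimiter: str = "\t"
    missing_policy: str = "flag"

    def __post_init__(self) -> None:
        if self.missing_policy not in ("flag", "drop"):
            raise ValueError("missing_policy must be 'flag' or 'drop'")


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column '{c}'")


def read_samples(
    path,
    dialect: SampleDialect = SampleDialect(),
    participant_id: str | None = None,
    sampling_rate: float = 120.0,
) -> SampleStream:
    """Read a delimited sample file into a validated :class:`SampleStream`."""
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter, float_precision="round_trip")
    _require_columns(df, [dialect.time_col, dialect.x_col, dialect.y_col], path)
    t = pd.to_numeric(df[dialect.time_col], errors="coerce").to_numpy(float)
    x = pd.to_numeric(df[dialect.x_col], errors="coerce").to_numpy(float)
    y = pd.to_numeric(df[dialect.y_col], errors="coerce").to_numpy(float)
    if np.isnan(t).any():
        raise DataError(f"{path}: non-numeric time at row "
                        f"{int(np.nonzero(np.isnan(t))[0][0]) + 1}")
    if dialect.valid_col is not None and dialect.valid_col in df.columns:
        valid = df[dialect.valid_col].astype(bool).to_numpy()
    else:
        valid = np.ones(len(df), dtype=bool)
    missing = np.isnan(x) | np.isnan(y)
    valid = valid & ~missing
    if dialect.missing_policy == "drop" and missing.any():
        n_drop = int(missing.sum())
        log.info("%s: dropped %d rows with missing coordinates", path, n_drop)
        keep = ~missing
        t, x, y, valid = t[keep], x[keep], y[keep], valid[keep]
    else:
        # keep rows; park missing coordinates at 0 so arrays stay numeric
        x = np.where(missing, 0.0, x)
        y = np.where(missing, 0.0, y)
    return SampleStream(
        participant_id=participant_id or path.stem,
        sampling_rate=sampling_rate,
        t=t, x=x, y=y, valid=valid,
    )


def write_samples(stream: SampleStream, path) -> None:
    df = pd.DataFrame({
        "t": stream.t, "x": stream.x, "y": stream.y,
        "valid": stream.valid.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)


def read_fixation_events(path, delimiter: str = "\t") -> list[Fixation]:
    """Read a fixation-event table (columns start, end, x, y)."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    _require_columns(df, ["start", "end", "x", "y"], path)
    fixations = [
        Fixation(float(r.start), float(r.end), float(r.x), float(r.y))
        for r in df.itertuples(index=False)
    ]
    for i, (a, b) in enumerate(zip(fixations, fixations[1:])):
        if b.start < a.end:
            raise DataError(f"{path}: overlapping events at rows {i + 1}-{i + 2}")
    return fixations


def write_fixation_events(fixations: Sequence[Fixation], path) -> None:
    df = pd.DataFrame(
        [(f.start, f.end, f.x, f.y) for f in fixations],
        columns=["start", "end", "x", "y"],
    )
    df.to_csv(path, sep="\t", index=False)


def _encode_responses(responses: Sequence[tuple[float, int]]) -> str:
    return "|".join(f"{t}:{c}" for t, c in responses)


def _decode_responses(s: str) -> list[tuple[float, int]]:
    if not s or (isinstance(s, float) and np.isnan(s)):
        return []
    out = []
    for part in str(s).split("|"):
        t, c = part.split(":")
        out.append((float(t), int(c)))
    return out


def write_trial_meta(trials: Sequence[TrialMeta], path) -> None:
    df = pd.DataFrame(
        [
            (m.trial_id, m.trial_onset, m.cue_onset, m.target_cell,
             m.outcome.value, _encode_responses(m.responses))
            for m in trials
        ],
        columns=["trial_id", "trial_onset", "cue_onset", "target_cell",
                 "outcome", "responses"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_trial_meta(path, delimiter: str = "\t") -> list[TrialMeta]:
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, keep_default_na=False,
                     float_precision="round_trip")
    _require_columns(
        df, ["trial_id", "trial_onset", "cue_onset", "target_cell", "outcome"], path
    )
    out = []
    for r in df.itertuples(index=False):
        out.append(TrialMeta(
            trial_id=int(r.trial_id),
            trial_onset=float(r.trial_onset),
            cue_onset=float(r.cue_onset),
            target_cell=int(r.target_cell),
            responses=_decode_responses(getattr(r, "responses", "")),
            outcome=Outcome(r.outcome),
        ))
    return out


def write_table(rows, path, columns: Sequence[str] | None = None) -> None:
    """Write any homogeneous result table as TSV at full precision.

    ``rows`` may be a DataFrame, a list of dicts, or a list of
    dataclass-like objects; ``columns`` is required only to write the
    header of an empty table.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        records = []
        for r in rows:
            if hasattr(r, "__dataclass_fields__"):
                records.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                records.append(dict(r))
        df = pd.DataFrame(records, columns=columns if not records else None)
        if columns is not None and records:
            df = df[list(columns)]
    df.to_csv(path, sep="\t", index=False)


def read_table(path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, float_precision="round_trip")
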