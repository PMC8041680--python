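"""Shared primitive types used across the pipeline.

Coordinate convention (used everywhere in this package): 0-based screen
pixels, origin at the top-left corner, y increasing downward.  Times are
milliseconds — recording-relative for raw streams, trial-relative (trial
onset = 0) after segmentation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple, Sequence


class Rect(NamedTuple):
    """Axis-aligned rectangle, half-open: contains (x, y) with x0 <= x < x1."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0


@dataclass(frozen=True)
class Fixation:
    """A detected (or simulated) fixation event.

    ``start``/``end`` in ms, ``x``/``y`` the centroid in screen px.
    """

    start: float
    end: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fixation end {self.end} must exceed start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Scanpath:
    """An ordered sequence of fixations, optionally AOI-labeled.

    Labels use the alphabet ``cue``, ``cell_1`` .. ``cell_12`` and
    ``outside``; ``labels`` is None until AOI assignment.
    """

    fixations: list[Fixation]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        fx = self.fixations
        for a, b in zip(fx, fx[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"fixations overlap or are out of order at t={b.start}"
                )
        if self.labels is not None and len(self.labels) != len(fx):
            raise ValueError("labels length must match fixations length")

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self) -> Iterator[Fixation]:
        return iter(self.fixations)

    def __getitem__(self, i: int) -> Fixation:
        return self.fixations[i]

    def subpath(self, indices: Sequence[int]) -> "Scanpath":
        labels = [self.labels[i] for i in indices] if self.labels is not None else None
        return Scanpath([self.fixations[i] for i in indices], labels)


OUTSIDE = "outside"
CUE = "cue"


def cell_label(cell: int) -> str:
    """Canonical AOI label for grid cell ``cell`` (1-based)."""
    return f"cell_{cell}"
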