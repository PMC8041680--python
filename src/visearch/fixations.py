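"""Dispersion-threshold (I-DT) fixation detection.

A window of consecutive valid samples is a fixation when its spatial
dispersion stays under a threshold (default 2 degrees of visual angle)
for at least a minimum duration (default 60 ms).  Dispersion is, by the
classic I-DT convention, the sum of the x-range and the y-range of the
window; the max-of-ranges alternative is selectable in the config.

Track loss is handled by breaking candidate windows at gaps longer than
``gap_bridge_ms`` between consecutive valid samples; shorter gaps are
bridged.  The default bridge (75 ms) is deliberately above the typical
inter-sample interval but below the minimum fixation duration, so two
sub-threshold snippets can never be merged into a spurious fixation by
the bridge alone.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Fixation
from .io_gaze import SampleStream, ScreenGeometry


@dataclass(frozen=True)
class DetectorConfig:
    min_duration_ms: float = 60.0
    max_dispersion_deg: float = 2.0
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    dispersion_metric: str = "sum"  # 'sum' (x-range + y-range) or 'max'
    gap_bridge_ms: float = 75.0

    def __post_init__(self) -> None:
        if self.min_duration_ms <= 0 or self.max_dispersion_deg <= 0:
            raise ValueError("min_duration_ms and max_dispersion_deg must be > 0")
        if self.dispersion_metric not in ("sum", "max"):
            raise ValueError("dispersion_metric must be 'sum' or 'max'")

    @property
    def max_dispersion_px(self) -> float:
        return self.max_dispersion_deg * self.screen.px_per_degree


def _dispersion(xmin, xmax, ymin, ymax, metric: str) -> float:
    if metric == "sum":
        return (xmax - xmin) + (ymax - ymin)
    return max(xmax - xmin, ymax - ymin)


def detect_fixations(stream: SampleStream, cfg: DetectorConfig = DetectorConfig()) -> list[Fixation]:
    """Run I-DT over a sample stream and return time-ordered fixations.

    Only valid samples participate; the stream's timing is preserved, so
    fixation boundaries are sample timestamps.  An empty (or all-invalid)
    stream yields an empty list.
    """
    m = stream.valid
    t = stream.t[m]
    x = stream.x[m]
    y = stream.y[m]
    n = len(t)
    if n == 0:
        return []

    thresh = cfg.max_dispersion_px
    out: list[Fixation] = []
    i = 0
    while i < n:
        # initialise window [i, j]
        j = i
        xmin = xmax = x[i]
        ymin = ymax = y[i]
        while j + 1 < n:
            if t[j + 1] - t[j] > cfg.gap_bridge_ms:
                break
            nxmin = min(xmin, x[j + 1]); nxmax = max(xmax, x[j + 1])
            nymin = min(ymin, y[j + 1]); nymax = max(ymax, y[j + 1])
            if _dispersion(nxmin, nxmax, nymin, nymax, cfg.dispersion_metric) > thresh:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        if t[j] - t[i] >= cfg.min_duration_ms:
            out.append(Fixation(
                start=float(t[i]),
                end=float(t[j]),
                x=float(np.mean(x[i:j + 1])),
                y=float(np.mean(y[i:j + 1])),
            ))
            i = j + 1
        else:
            i += 1
    return out
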