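"""Spatial accuracy and movement-duration measures for the drawing task.

Targets are disks; the spatial error of a trial is the sum over targets
of the closest approach of the pen path to each disk's edge (zero when
the path enters the disk).  Duration improvements are reported as
percent of the pre-test baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import TargetLayout
from .preprocess import KinematicSeries
from .segmentation import MovementSegment

__all__ = ["AccuracyResult", "spatial_error", "movement_duration", "percent_improvement"]


@dataclass(frozen=True)
class AccuracyResult:
    spatial_error: float
    per_target_distances: tuple[float, ...]
    duration: float

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.per_target_distances):
            raise ValueError("per-target distances must be >= 0")
        if abs(self.spatial_error - sum(self.per_target_distances)) > 1e-9:
            raise ValueError("spatial error must equal the sum of per-target distances")


def spatial_error(
    series: KinematicSeries,
    segment: MovementSegment,
    layout: TargetLayout,
) -> AccuracyResult:
    """Summed closest distance from the pen path to each target's edge.

    Per target: min over the segment's samples of (distance from sample
    to the target centre minus the radius), clamped at zero — a path
    passing inside a disk contributes nothing.  Distances are
    sample-to-centre (at 200 Hz the between-sample gap is negligible).
    """
    sub = series.crop(segment.onset_idx, segment.offset_idx)
    if len(sub) == 0:
        raise ValueError("empty movement segment")
    dists = []
    for _label, cx, cy, radius in layout.targets:
        d = np.hypot(sub.x - cx, sub.y - cy) - radius
        dists.append(max(0.0, float(np.min(d))))
    return AccuracyResult(
        spatial_error=float(sum(dists)),
        per_target_distances=tuple(dists),
        duration=segment.duration,
    )


def movement_duration(segment: MovementSegment) -> float:
    """Movement duration in seconds (offset minus onset)."""
    return segment.duration


def percent_improvement(value: float, baseline: float) -> tuple[float, float]:
    """Percent improvement over the pre-test baseline.

    Returns ``(improvement, signed_change)`` where improvement is
    100 x (baseline - value) / baseline — positive means faster/smaller
    — and signed_change is the raw normalized change
    100 x (value - baseline) / baseline.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0 for percent improvement")
    signed = 100.0 * (value - baseline) / baseline
    return -signed, signed
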