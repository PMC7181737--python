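"""Movement onset/offset detection and trial-level quality control.

Onset is the last time before the first significant tangential-velocity
peak at which the speed falls below 5% of the global peak speed and the
stylus pressure is positive; offset is the last time the speed exceeds
that same 5% threshold.  "Significant" peaks are those whose prominence
reaches a configurable fraction (default 5%) of the global maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal

from .io_formats import RawTrajectory, TargetLayout
from .preprocess import KinematicSeries

__all__ = [
    "MovementSegment",
    "TrialQC",
    "QCReason",
    "NoMovementError",
    "detect_bounds",
    "qc_trial",
]


class NoMovementError(ValueError):
    """Raised when a trial contains no detectable movement."""


@dataclass(frozen=True)
class MovementSegment:
    """Onset/offset of the scored movement inside a trial."""

    onset_t: float
    offset_t: float
    onset_idx: int
    offset_idx: int
    peak_vtan: float

    def __post_init__(self) -> None:
        if not self.onset_t < self.offset_t:
            raise ValueError("onset must precede offset")
        if self.peak_vtan <= 0:
            raise ValueError("peak tangential speed must be > 0")

    @property
    def duration(self) -> float:
        return self.offset_t - self.onset_t


class QCReason(str, Enum):
    OK = "ok"
    DISCONTINUOUS = "discontinuous_recording"
    WRONG_PATTERN = "wrong_pattern"
    NO_PRESSURE = "no_pressure"
    TOO_SHORT = "too_short"


@dataclass(frozen=True)
class TrialQC:
    trial_id: str
    kept: bool
    reason: QCReason

    def __post_init__(self) -> None:
        if self.kept != (self.reason is QCReason.OK):
            raise ValueError("kept flag must match reason == ok")


def _significant_peaks(v_tan: np.ndarray, prominence_fraction: float) -> np.ndarray:
    vmax = float(np.max(v_tan))
    peaks, _ = signal.find_peaks(v_tan, prominence=prominence_fraction * vmax)
    return peaks


def detect_bounds(
    series: KinematicSeries,
    threshold_fraction: float = 0.05,
    peak_prominence_fraction: float = 0.05,
    pressure_epsilon: float = 0.0,
) -> MovementSegment:
    """Locate movement onset and offset from the tangential-speed profile.

    Parameters
    ----------
    threshold_fraction
        Speed threshold as a fraction of the global tangential-speed
        peak (default 0.05, i.e. 5%).
    peak_prominence_fraction
        Minimum prominence, relative to the global maximum, for a speed
        peak to count as the "first significant peak" anchoring the
        onset search.
    pressure_epsilon
        Pressure must exceed this value at the onset sample; zero by
        default, raise it to tolerate sensor noise.
    """
    if series.v_tan is None:
        raise ValueError("series must carry v_tan (run a preprocessing recipe first)")
    v = series.v_tan
    vmax = float(np.max(v)) if v.size else 0.0
    if vmax <= 1e-12:
        raise NoMovementError("tangential speed is zero throughout the trial")
    pressure = series.pressure
    if pressure is None:
        pressure = np.ones_like(v)
    if not np.any(pressure > pressure_epsilon):
        raise NoMovementError("stylus pressure never exceeds epsilon; pen-up trial")

    peaks = _significant_peaks(v, peak_prominence_fraction)
    first_peak = int(peaks[0]) if peaks.size else int(np.argmax(v))

    thresh = threshold_fraction * vmax
    below = (v[:first_peak] < thresh) & (pressure[:first_peak] > pressure_epsilon)
    candidates = np.nonzero(below)[0]
    if candidates.size:
        onset_idx = int(candidates[-1])
    else:
        # pen touches down after the speed threshold is already exceeded:
        # onset deferred to the first pen-down sample before the peak
        down = np.nonzero(pressure[:first_peak] > pressure_epsilon)[0]
        onset_idx = int(down[0]) if down.size else 0

    above = np.nonzero(v > thresh)[0]
    offset_idx = int(above[-1]) if above.size else int(np.argmax(v))
    if offset_idx <= onset_idx:
        offset_idx = min(onset_idx + 1, len(series) - 1)

    return MovementSegment(
        onset_t=float(series.t[onset_idx]),
        offset_t=float(series.t[offset_idx]),
        onset_idx=onset_idx,
        offset_idx=offset_idx,
        peak_vtan=vmax,
    )


def qc_trial(
    raw: RawTrajectory,
    layout: TargetLayout | None = None,
    gap_limit_s: float = 0.1,
    completeness_radius_mm: float = 10.0,
    min_duration_s: float = 0.2,
    pressure_epsilon: float = 0.0,
) -> TrialQC:
    """Apply the trial-exclusion rules and return a verdict.

    Flags, in order of precedence: recordings with a timestamp gap
    larger than ``gap_limit_s`` (discontinuous recording), trials whose
    pen pressure never goes positive, trials shorter than
    ``min_duration_s``, and — when a layout is given — paths that fail
    to approach every target centre within ``completeness_radius_mm``
    (a different pattern was drawn).
    """
    if len(raw) >= 2 and float(np.max(np.diff(raw.t))) > gap_limit_s:
        return TrialQC(raw.trial_id, False, QCReason.DISCONTINUOUS)
    if not np.any(raw.pressure > pressure_epsilon):
        return TrialQC(raw.trial_id, False, QCReason.NO_PRESSURE)
    if raw.duration < min_duration_s:
        return TrialQC(raw.trial_id, False, QCReason.TOO_SHORT)
    if layout is not None:
        down = raw.pressure > pressure_epsilon
        x, y = raw.x[down], raw.y[down]
        for label, cx, cy, _r in layout.targets:
            d = np.hypot(x - cx, y - cy)
            if d.size == 0 or float(np.min(d)) > completeness_radius_mm:
                return TrialQC(raw.trial_id, False, QCReason.WRONG_PATTERN)
    return TrialQC(raw.trial_id, True, QCReason.OK)
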