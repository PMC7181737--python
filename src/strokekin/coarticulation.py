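"""Coarticulation scoring of point-to-point drawing trajectories.

A drawing trial traverses four targets and back (A>B>C>D>A).  A mover
who stops at every via-point produces four separate speed bells with
troughs at zero; a mover who blends consecutive strokes (coarticulates)
leaves the intermediate troughs high.  The coarticulation score is the
ratio of the mean of the first and third trough heights to the mean of
the four peak heights, times 100: 0 means four distinct point-to-point
movements, 100 means no dip at all at the scored via-points.  The middle
trough (at the far target) is excluded by the formula — the task
converges to two curved lines meeting there.

When consecutive strokes merge so completely that a peak-trough pair
disappears from the speed profile, the inflection point that replaced
them supplies one height used for both the missing peak and the missing
trough.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from .preprocess import KinematicSeries
from .segmentation import MovementSegment

__all__ = [
    "PeakTroughProfile",
    "CoarticulationResult",
    "RegisteredSet",
    "find_extrema",
    "complete_profile",
    "coarticulation_score",
    "count_velocity_peaks",
    "normalize_scores",
    "register_trials",
]

DEFAULT_VIA_FRACTIONS = (0.25, 0.5, 0.75)


@dataclass
class PeakTroughProfile:
    """Ordered extrema of a tangential-speed profile.

    Peaks and troughs strictly alternate in time starting (and ending)
    with a peak.  ``substituted_*`` flags mark entries supplied by
    inflection-point substitution rather than detected extrema.  The
    cropped speed profile the extrema came from is carried along so
    substitution can search it.
    """

    peak_times: np.ndarray
    peak_heights: np.ndarray
    trough_times: np.ndarray
    trough_heights: np.ndarray
    n_detected_peaks: int
    substituted_peaks: np.ndarray = field(default=None)  # type: ignore[assignment]
    substituted_troughs: np.ndarray = field(default=None)  # type: ignore[assignment]
    t_grid: np.ndarray | None = None
    v_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_heights = np.asarray(self.peak_heights, dtype=float)
        self.trough_times = np.asarray(self.trough_times, dtype=float)
        self.trough_heights = np.asarray(self.trough_heights, dtype=float)
        if self.substituted_peaks is None:
            self.substituted_peaks = np.zeros(self.peak_times.size, dtype=bool)
        if self.substituted_troughs is None:
            self.substituted_troughs = np.zeros(self.trough_times.size, dtype=bool)
        if self.trough_times.size != max(self.peak_times.size - 1, 0):
            raise ValueError(
                f"{self.peak_times.size} peaks require "
                f"{self.peak_times.size - 1} troughs, got {self.trough_times.size}"
            )
        merged = np.empty(self.peak_times.size + self.trough_times.size)
        merged[0::2] = self.peak_times
        merged[1::2] = self.trough_times
        if merged.size > 1 and not np.all(np.diff(merged) > 0):
            raise ValueError("peaks and troughs must strictly alternate in time")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times.size)


@dataclass(frozen=True)
class CoarticulationResult:
    """Score and supporting quantities for one trial."""

    score: float
    n_peaks: int
    peak_heights: tuple[float, ...]
    trough_heights: tuple[float, ...]
    normalized_score: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 100.0 + 1e-9):
            raise ValueError(f"score {self.score} outside [0, 100]")
        if not (1 <= self.n_peaks <= 4):
            raise ValueError("n_peaks must be in 1..4")


@dataclass
class RegisteredSet:
    """Trials mapped onto a shared normalized-time grid in [0, 1]."""

    grid: np.ndarray
    v_tan: np.ndarray  # (n_trials, n_grid)
    x: np.ndarray
    y: np.ndarray
    mean_v_tan: np.ndarray
    mean_x: np.ndarray
    mean_y: np.ndarray


def find_extrema(
    series: KinematicSeries,
    segment: MovementSegment,
    prominence_fraction: float = 0.05,
) -> PeakTroughProfile:
    """Detect alternating speed peaks and troughs inside a movement segment.

    Peaks are local maxima of the tangential speed with prominence at
    least ``prominence_fraction`` of the segment's global maximum (small
    ripples are ignored); each trough is the speed minimum between two
    consecutive retained peaks, which guarantees strict alternation.
    """
    from scipy.signal import find_peaks

    if series.v_tan is None:
        raise ValueError("series must carry v_tan")
    sub = series.crop(segment.onset_idx, segment.offset_idx)
    t, v = sub.t, sub.v_tan
    vmax = float(np.max(v))
    if vmax <= 0:
        raise ValueError("no speed peaks: profile is identically zero")
    idx, _ = find_peaks(v, prominence=prominence_fraction * vmax)
    if idx.size == 0:
        raise ValueError("no interior speed peak found in segment")
    trough_idx = np.array(
        [a + int(np.argmin(v[a : b + 1])) for a, b in zip(idx[:-1], idx[1:])],
        dtype=int,
    )
    return PeakTroughProfile(
        peak_times=t[idx],
        peak_heights=v[idx],
        trough_times=t[trough_idx],
        trough_heights=v[trough_idx],
        n_detected_peaks=int(idx.size),
        t_grid=t,
        v_grid=v,
    )


def _match_troughs_to_fractions(
    trough_times: np.ndarray, expected_times: np.ndarray
) -> list[int]:
    """Indices of expected via-times left unmatched by the detected troughs.

    Order-preserving minimum-cost assignment of the detected troughs to
    the expected via-point passage times (small exhaustive search: at
    most C(3, 2) candidate assignments).
    """
    m, e = trough_times.size, expected_times.size
    best, best_cost = None, np.inf
    for combo in combinations(range(e), m):
        cost = sum(abs(trough_times[i] - expected_times[j]) for i, j in enumerate(combo))
        if cost < best_cost:
            best, best_cost = combo, cost
    return [j for j in range(e) if j not in best]


def _inflection_time(
    t: np.ndarray, v: np.ndarray, lo: float, hi: float, target: float
) -> tuple[float, float]:
    """Inflection of v(t) within [lo, hi] nearest ``target`` (first on ties).

    Inflections are zero crossings of the second time-derivative of the
    speed profile, located by sign change with linear sub-sample
    interpolation.  Returns (time, speed at that time).
    """
    dt = t[1] - t[0]
    curv = np.gradient(np.gradient(v, dt, edge_order=2), dt, edge_order=2)
    mask = (t >= lo) & (t <= hi)
    (pos,) = np.nonzero(mask)
    if pos.size < 3:
        raise ValueError("substitution region too short to search for an inflection")
    i0, i1 = pos[0], pos[-1]
    c = curv[i0 : i1 + 1]
    sgn = np.sign(c)
    crossings = []
    for k in range(c.size - 1):
        if sgn[k] == 0:
            crossings.append(t[i0 + k])
        elif sgn[k] * sgn[k + 1] < 0:
            frac = c[k] / (c[k] - c[k + 1])
            crossings.append(t[i0 + k] + frac * dt)
    if not crossings:
        raise ValueError(
            f"no speed-profile inflection found in [{lo:.3f}, {hi:.3f}] s; "
            "cannot substitute the merged peak/trough pair"
        )
    crossings = np.array(crossings)
    order = np.lexsort((crossings, np.abs(crossings - target)))
    tc = float(crossings[order[0]])
    return tc, float(np.interp(tc, t, v))


def complete_profile(
    profile: PeakTroughProfile,
    expected_peaks: int = 4,
    via_fractions: tuple[float, ...] = DEFAULT_VIA_FRACTIONS,
) -> PeakTroughProfile:
    """Restore merged peak-trough pairs by inflection-point substitution.

    When blending of consecutive strokes removes a peak-trough pair from
    the speed profile, the profile keeps an inflection (a shoulder) where
    the pair used to be; its speed value is used for BOTH the missing
    peak and the missing trough.  A 4-peak profile is returned unchanged.

    The merged region is located from the expected via-point passage
    times: detected troughs are matched to the expected times
    (``via_fractions`` of the segment duration) and each unmatched
    expected time marks a merge.  The inflection nearest that time,
    searched between the two detected extrema flanking it, supplies the
    substituted height.
    """
    k = profile.n_detected_peaks
    if k == expected_peaks:
        return profile
    if k not in (2, 3):
        raise ValueError(
            f"substitution supports 2 or 3 detected peaks, got {k}"
        )
    if profile.t_grid is None or profile.v_grid is None:
        raise ValueError("profile must carry its speed grid for substitution")

    t, v = profile.t_grid, profile.v_grid
    t0, t1 = t[0], t[-1]
    expected = t0 + np.asarray(via_fractions) * (t1 - t0)
    missing = _match_troughs_to_fractions(profile.trough_times, expected)

    peak_t = list(profile.peak_times)
    peak_h = list(profile.peak_heights)
    peak_s = list(profile.substituted_peaks)
    trough_t = list(profile.trough_times)
    trough_h = list(profile.trough_heights)
    trough_s = list(profile.substituted_troughs)
    delta = 0.5 * (t[1] - t[0])

    for j in missing:
        te = float(expected[j])
        # merged peak: the detected peak whose flanking troughs bracket te
        times = np.array(peak_t)
        jp = int(np.argmin(np.abs(times - te)))
        lo = trough_t[jp - 1] if jp >= 1 else t0
        hi = trough_t[jp] if jp < len(trough_t) else t1
        ti, h = _inflection_time(t, v, lo, hi, te)
        if ti < peak_t[jp]:
            # pair sits on the rising flank: new peak then new trough before jp
            peak_t.insert(jp, ti - delta)
            peak_h.insert(jp, h)
            peak_s.insert(jp, True)
            trough_t.insert(jp, ti)
            trough_h.insert(jp, h)
            trough_s.insert(jp, True)
        else:
            trough_t.insert(jp, ti)
            trough_h.insert(jp, h)
            trough_s.insert(jp, True)
            peak_t.insert(jp + 1, ti + delta)
            peak_h.insert(jp + 1, h)
            peak_s.insert(jp + 1, True)

    return PeakTroughProfile(
        peak_times=np.array(peak_t),
        peak_heights=np.array(peak_h),
        trough_times=np.array(trough_t),
        trough_heights=np.array(trough_h),
        n_detected_peaks=k,
        substituted_peaks=np.array(peak_s, dtype=bool),
        substituted_troughs=np.array(trough_s, dtype=bool),
        t_grid=t,
        v_grid=v,
    )


def coarticulation_score(profile: PeakTroughProfile) -> CoarticulationResult:
    """Score a completed 4-peak / 3-trough profile.

    score = 100 x mean(trough_1, trough_3) / mean(peak_1..peak_4)

    where troughs are indexed temporally (the trough after the first
    stroke and the trough after the third).
    """
    if profile.n_peaks != 4 or profile.trough_times.size != 3:
        raise ValueError(
            "scoring requires a completed profile with 4 peaks and 3 troughs; "
            "run complete_profile first"
        )
    mean_peaks = float(np.mean(profile.peak_heights))
    if mean_peaks <= 0:
        raise ValueError("mean peak height is zero; cannot score")
    score = 100.0 * float(
        np.mean([profile.trough_heights[0], profile.trough_heights[2]])
    ) / mean_peaks
    return CoarticulationResult(
        score=min(score, 100.0),
        n_peaks=min(profile.n_detected_peaks, 4),
        peak_heights=tuple(profile.peak_heights),
        trough_heights=tuple(profile.trough_heights),
    )


def count_velocity_peaks(profile: PeakTroughProfile) -> int:
    """Number of detected speed peaks before substitution, capped at 4."""
    return min(profile.n_detected_peaks, 4)


def normalize_scores(scores, baseline: float) -> np.ndarray:
    """Baseline-subtracted scores (NOT divided by baseline).

    Division is deliberately omitted for this measure: pre-test scores
    are often near zero, so a ratio would explode.
    """
    if baseline is None or not np.isfinite(baseline):
        raise ValueError("baseline (pre-test mean score) is required")
    return np.asarray(scores, dtype=float) - float(baseline)


def register_trials(
    trials: list[tuple[KinematicSeries, MovementSegment]],
    n_grid: int = 200,
) -> RegisteredSet:
    """Map trials onto a common normalized-time grid and average them.

    Each trial's movement segment is linearly rescaled to [0, 1] and its
    path and speed profile resampled to ``n_grid`` points; means are
    pointwise over trials.
    """
    if not trials:
        raise ValueError("register_trials needs at least one trial")
    grid = np.linspace(0.0, 1.0, n_grid)
    vs, xs, ys = [], [], []
    for series, seg in trials:
        sub = series.crop(seg.onset_idx, seg.offset_idx)
        if sub.v_tan is None:
            raise ValueError("series must carry v_tan")
        u = (sub.t - sub.t[0]) / (sub.t[-1] - sub.t[0])
        vs.append(np.interp(grid, u, sub.v_tan))
        xs.append(np.interp(grid, u, sub.x))
        ys.append(np.interp(grid, u, sub.y))
    v = np.vstack(vs)
    x = np.vstack(xs)
    y = np.vstack(ys)
    return RegisteredSet(
        grid=grid, v_tan=v, x=x, y=y,
        mean_v_tan=v.mean(axis=0), mean_x=x.mean(axis=0), mean_y=y.mean(axis=0),
    )
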