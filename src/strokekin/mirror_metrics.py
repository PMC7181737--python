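"""Tracking ("mirror game") analysis: jitter and tracking-error metrics.

Slow voluntary tracking is not smooth: movers emit intermittent
corrective sub-adjustments visible as extra acceleration zero-crossings
("jitter").  A jitter event is an acceleration zero-crossing of the
follower that (a) does not coincide with an acceleration zero-crossing
of the stimulus (those are obligatory direction/speed changes) and
(b) is more than 200 ms from the previous retained event — separate
voluntary corrections are not produced faster than 5 Hz.  The jitter
frequency of a pair of consecutive events is half the reciprocal of
their spacing (the frequency of the implied whole oscillation), and a
trial or subject is summarised by the mode of the jitter-frequency
distribution, located as the maximum of a Gaussian kernel density
estimate.

Tracking accuracy is summarised by three error measures on the common
100 Hz grid:

    dX = (2/n) * sum |x1 - x2| / |x1 + x2 - 2*x_c|
    dV = (2/n) * sum |v1 - v2| / |v1 + v2|
    dT = mean |t_stim_zero_vel - t_follower_zero_vel|   (matched events)

with 1 the follower, 2 the stimulus and x_c the centre position the
half-sine excursions depart from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import KinematicSeries

__all__ = [
    "JitterEvents",
    "RegisteredPair",
    "TrackingErrors",
    "PeakJitterSummary",
    "zero_crossings",
    "detect_jitter",
    "jitter_frequencies",
    "peak_jitter_frequency",
    "tracking_error_dX",
    "tracking_error_dV",
    "tracking_error_dT",
    "phase_improvement",
]


@dataclass(frozen=True)
class JitterEvents:
    """Retained acceleration zero-crossings of one tracking trial."""

    event_times: np.ndarray
    excluded_stimulus_matches: int
    excluded_refractory: int
    min_sep: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_times", np.asarray(self.event_times, dtype=float))
        gaps = np.diff(self.event_times)
        if gaps.size and not np.all(gaps > self.min_sep):
            raise ValueError(f"event gaps must exceed the {self.min_sep} s refractory window")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)


@dataclass
class RegisteredPair:
    """Follower and stimulus on one common uniform grid."""

    t: np.ndarray
    x1: np.ndarray  # follower position, mm
    x2: np.ndarray  # stimulus position, mm
    v1: np.ndarray
    v2: np.ndarray
    x_c: float = 0.0

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("x1", "x2", "v1", "v2"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name} length differs from grid")

    @classmethod
    def from_series(
        cls, follower: KinematicSeries, stimulus: KinematicSeries, x_c: float = 0.0
    ) -> "RegisteredPair":
        """Align a stimulus to the follower's grid by linear interpolation."""
        if follower.vx is None or stimulus.vx is None:
            raise ValueError("both series need velocities (run differentiate first)")
        t = follower.t
        return cls(
            t=t,
            x1=follower.x,
            x2=np.interp(t, stimulus.t, stimulus.x),
            v1=follower.vx,
            v2=np.interp(t, stimulus.t, stimulus.vx),
            x_c=x_c,
        )


@dataclass(frozen=True)
class TrackingErrors:
    dX: float
    dV: float
    dT: float

    def __post_init__(self) -> None:
        if self.dX < 0 or self.dV < 0 or self.dT < 0:
            raise ValueError("tracking errors are non-negative")


@dataclass(frozen=True)
class PeakJitterSummary:
    peak_frequency: float
    n_events: int
    bandwidth_used: float
    improvement: float | None = None


def zero_crossings(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Times where y changes sign, with linear sub-sample interpolation.

    Samples exactly at zero count as crossings only when the signal
    changes sign around them; a run of zeros with a sign flip across it
    yields the run's first time.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    s = np.sign(y)
    out: list[float] = []
    i = 0
    n = y.size
    while i < n - 1:
        if s[i] == 0:
            j = i
            while j < n and s[j] == 0:
                j += 1
            before = s[i - 1] if i > 0 else 0
            after = s[j] if j < n else 0
            if before * after < 0:
                out.append(float(t[i]))
            i = j
        elif s[i] * s[i + 1] < 0:
            frac = y[i] / (y[i] - y[i + 1])
            out.append(float(t[i] + frac * (t[i + 1] - t[i])))
            i += 1
        else:
            i += 1
    return np.array(out)


def detect_jitter(
    series: KinematicSeries,
    stimulus: KinematicSeries,
    min_sep: float = 0.2,
    stim_match_window: float = 0.05,
) -> JitterEvents:
    """Find the follower's non-obligatory acceleration zero-crossings.

    Crossings within ``stim_match_window`` of any stimulus acceleration
    zero-crossing are removed first (they are obligatory), then the
    remainder is thinned so consecutive gaps exceed ``min_sep``, keeping
    the earlier event of each conflicting pair.
    """
    if series.ax is None or stimulus.ax is None:
        raise ValueError("both series need acceleration channels")
    if stimulus.t[-1] < series.t[-1] - 1e-9:
        raise ValueError("stimulus record is shorter than the participant record")
    cand = zero_crossings(series.t, series.ax)
    stim_cross = zero_crossings(stimulus.t, stimulus.ax)

    excluded_stim = 0
    kept: list[float] = []
    for tc in cand:
        if stim_cross.size and np.min(np.abs(stim_cross - tc)) <= stim_match_window:
            excluded_stim += 1
        else:
            kept.append(tc)

    retained: list[float] = []
    excluded_refr = 0
    for tc in kept:
        if retained and tc - retained[-1] <= min_sep:
            excluded_refr += 1
        else:
            retained.append(tc)

    return JitterEvents(
        event_times=np.array(retained),
        excluded_stimulus_matches=excluded_stim,
        excluded_refractory=excluded_refr,
        min_sep=min_sep,
    )


def jitter_frequencies(events: JitterEvents) -> np.ndarray:
    """Whole-wave frequency per consecutive event pair: 1 / (2 * gap).

    Fewer than two events yield an empty array (not an error): jitter
    frequencies are typically pooled over trials before summarising.
    """
    if events.n_events < 2:
        return np.array([])
    return 1.0 / (2.0 * np.diff(events.event_times))


def peak_jitter_frequency(
    frequencies: np.ndarray,
    bandwidth: float | str = "silverman",
    min_events: int = 5,
    grid_size: int = 2048,
) -> PeakJitterSummary:
    """Mode of the jitter-frequency distribution via a Gaussian KDE.

    ``bandwidth`` is either a rule name understood by
    ``scipy.stats.gaussian_kde`` ("silverman", "scott") or an absolute
    bandwidth in Hz.  The KDE is evaluated on a dense grid spanning the
    sample plus three bandwidths; the grid argmax is the peak.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.size < min_events:
        raise ValueError(
            f"need at least {min_events} jitter frequencies (got {f.size}); "
            "pool events across trials"
        )
    sd = float(np.std(f, ddof=1))
    if sd == 0.0:
        # degenerate sample: every gap identical
        return PeakJitterSummary(
            peak_frequency=float(f[0]), n_events=int(f.size), bandwidth_used=0.0
        )
    if isinstance(bandwidth, str):
        kde = stats.gaussian_kde(f, bw_method=bandwidth)
    else:
        kde = stats.gaussian_kde(f, bw_method=float(bandwidth) / sd)
    bw = float(kde.factor * sd)
    grid = np.linspace(f.min() - 3 * bw, f.max() + 3 * bw, grid_size)
    dens = kde(grid)
    peak = float(grid[int(np.argmax(dens))])
    # report within the observed span
    peak = float(np.clip(peak, f.min(), f.max()))
    return PeakJitterSummary(peak_frequency=peak, n_events=int(f.size), bandwidth_used=bw)


def _relative_error(num: np.ndarray, den: np.ndarray, floor: float) -> tuple[float, int]:
    keep = np.abs(den) > floor
    n_kept = int(np.count_nonzero(keep))
    if n_kept == 0:
        raise ValueError("all denominators below the floor; relative error undefined")
    val = (2.0 / n_kept) * float(np.sum(np.abs(num[keep]) / np.abs(den[keep])))
    return val, int(den.size - n_kept)


def tracking_error_dX(pair: RegisteredPair, denom_floor: float = 1.0) -> float:
    """Relative position error: (2/n) sum |x1-x2| / |x1+x2-2*x_c|.

    Samples whose denominator falls below ``denom_floor`` (default 1 mm:
    both players essentially at the centre position, where the relative
    error is undefined) are excluded from the sum and from n, mirroring
    the velocity-error guard.
    """
    val, _ = _relative_error(
        pair.x1 - pair.x2, pair.x1 + pair.x2 - 2.0 * pair.x_c, denom_floor
    )
    return val


def tracking_error_dV(pair: RegisteredPair, denom_floor: float = 1.0) -> float:
    """Relative velocity error: (2/n) sum |v1-v2| / |v1+v2|.

    The denominator vanishes whenever the two velocities cancel, so
    samples with |v1+v2| below ``denom_floor`` (default 1 mm/s) are
    excluded from the sum and from n.
    """
    val, _ = _relative_error(pair.v1 - pair.v2, pair.v1 + pair.v2, denom_floor)
    return val


def tracking_error_dT(
    participant: KinematicSeries, stimulus: KinematicSeries
) -> float:
    """Mean absolute time difference between zero-velocity events.

    Stimulus zero-velocity events are matched one-to-one to participant
    zero-velocity events, greedily by smallest absolute time difference
    (before any registration); unmatched surplus events on either side
    are ignored.
    """
    if participant.vx is None or stimulus.vx is None:
        raise ValueError("both series need velocities")
    ev_p = zero_crossings(participant.t, participant.vx)
    ev_s = zero_crossings(stimulus.t, stimulus.vx)
    if ev_p.size == 0 or ev_s.size == 0:
        raise ValueError("no zero-velocity events to match")
    diffs = np.abs(ev_s[:, None] - ev_p[None, :])
    order = np.argsort(diffs, axis=None)
    used_s = np.zeros(ev_s.size, dtype=bool)
    used_p = np.zeros(ev_p.size, dtype=bool)
    matched: list[float] = []
    for flat in order:
        i, j = divmod(int(flat), ev_p.size)
        if not used_s[i] and not used_p[j]:
            used_s[i] = used_p[j] = True
            matched.append(float(diffs[i, j]))
            if used_s.all() or used_p.all():
                break
    return float(np.mean(matched))


def phase_improvement(
    pre: dict[float, float], post: dict[float, float]
) -> dict[float, float]:
    """Per-stimulus-frequency improvement: pre minus post (Hz).

    Positive values mean the peak jitter frequency dropped after
    instruction; negative values mean worsening.
    """
    if set(pre) != set(post):
        raise ValueError(
            f"frequency keys differ: pre={sorted(pre)} post={sorted(post)}"
        )
    return {f: pre[f] - post[f] for f in pre}
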