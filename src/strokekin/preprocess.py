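"""Turn raw pen records into differentiable kinematic series.

Two distinct recipes are used, one per task:

* drawing trials — least-squares cubic regression splines with knots
  every 6 samples (knot density is the smoothing control; no roughness
  penalty), derivatives taken analytically from the spline;
* 1-D tracking trials — zero-phase (two-way) 4th-order Butterworth
  low-pass at 5 Hz, finite-difference derivatives, then resampling to a
  uniform 100 Hz grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import interpolate, signal

from .io_formats import RawTrajectory

__all__ = [
    "KinematicSeries",
    "smooth_with_splines",
    "lowpass_two_way",
    "resample_uniform",
    "differentiate",
]


@dataclass
class KinematicSeries:
    """Filtered positions on a uniform grid with optional derivatives.

    ``v_tan`` is the tangential speed: the Euclidean norm of (vx, vy)
    at every sample (|vx| for 1-D records).  ``provenance`` names the
    recipe that produced the series.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None
    ax: np.ndarray | None = None
    ay: np.ndarray | None = None
    v_tan: np.ndarray | None = None
    pressure: np.ndarray | None = None
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.t.size or self.y.size != self.t.size:
            raise ValueError("position channels must match the time grid length")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.t)
        return bool(d.size == 0 or np.allclose(d, d[0], rtol=rtol, atol=1e-12))

    def crop(self, i0: int, i1: int) -> "KinematicSeries":
        """Return the sub-series covering samples [i0, i1] inclusive."""
        sl = slice(i0, i1 + 1)
        pick = lambda a: None if a is None else a[sl]
        return replace(
            self,
            t=self.t[sl], x=self.x[sl], y=self.y[sl],
            vx=pick(self.vx), vy=pick(self.vy),
            ax=pick(self.ax), ay=pick(self.ay),
            v_tan=pick(self.v_tan), pressure=pick(self.pressure),
        )


def _lsq_spline(t: np.ndarray, vals: np.ndarray, knot_spacing: int, k: int = 3):
    """Least-squares cubic B-spline with interior knots every ``knot_spacing`` samples."""
    interior = t[knot_spacing:-1:knot_spacing]
    # full knot vector with (k+1)-fold boundary knots
    knots = np.concatenate([np.repeat(t[0], k + 1), interior, np.repeat(t[-1], k + 1)])
    return interpolate.make_lsq_spline(t, vals, knots, k=k)


def smooth_with_splines(
    raw: RawTrajectory,
    knot_spacing: int = 6,
    analytic_derivatives: bool = True,
) -> KinematicSeries:
    """Smooth a drawing trial and fill all kinematic channels.

    Cubic regression splines with knots every ``knot_spacing`` samples
    are fit to x(t) and y(t) by least squares and evaluated back on the
    original time grid.  Derivatives come from the spline itself by
    default; set ``analytic_derivatives=False`` for finite differences
    on the smoothed samples.
    """
    n = len(raw)
    if n < 2 * knot_spacing:
        raise ValueError(
            f"need at least {2 * knot_spacing} samples for knot spacing "
            f"{knot_spacing}, got {n}"
        )
    t = raw.t
    sx = _lsq_spline(t, raw.x, knot_spacing)
    sy = _lsq_spline(t, raw.y, knot_spacing)
    x, y = sx(t), sy(t)
    series = KinematicSeries(
        t=t, x=x, y=y, pressure=raw.pressure, provenance="spline"
    )
    if analytic_derivatives:
        vx, vy = sx.derivative(1)(t), sy.derivative(1)(t)
        ax, ay = sx.derivative(2)(t), sy.derivative(2)(t)
        series.vx, series.vy, series.ax, series.ay = vx, vy, ax, ay
        series.v_tan = np.hypot(vx, vy)
        return series
    return differentiate(series)


def lowpass_two_way(
    raw: RawTrajectory, order: int = 4, cutoff_hz: float = 5.0
) -> KinematicSeries:
    """Zero-phase Butterworth low-pass of a 1-D tracking record.

    The filter is applied forward then backward (``filtfilt``) so the
    net phase shift is zero and peak timings are preserved; the
    magnitude response is the squared one-way 4th-order response.
    Derivatives are left unfilled (finite differences come next in the
    tracking recipe).
    """
    fs = raw.sample_rate_nominal
    if fs <= 2.0 * cutoff_hz:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the cutoff ({2 * cutoff_hz} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, raw.x)
    # y is constant/absent for tracking trials but filter it when it varies
    y = signal.sosfiltfilt(sos, raw.y) if np.ptp(raw.y) > 0 else raw.y.astype(float)
    return KinematicSeries(
        t=raw.t.copy(), x=x, y=y, pressure=raw.pressure, provenance="butterworth"
    )


def resample_uniform(series: KinematicSeries, target_rate: float = 100.0) -> KinematicSeries:
    """Linearly interpolate all channels onto a uniform grid at ``target_rate``.

    The new grid spans the original interval; no extrapolation occurs.
    """
    if len(series) == 0:
        raise ValueError("cannot resample an empty series")
    t0, t1 = series.t[0], series.t[-1]
    if t1 <= t0:
        raise ValueError("series time span must be > 0")
    n = int(np.floor((t1 - t0) * target_rate)) + 1
    grid = t0 + np.arange(n) / target_rate
    interp = lambda a: None if a is None else np.interp(grid, series.t, a)
    out = KinematicSeries(
        t=grid,
        x=np.interp(grid, series.t, series.x),
        y=np.interp(grid, series.t, series.y),
        vx=interp(series.vx), vy=interp(series.vy),
        ax=interp(series.ax), ay=interp(series.ay),
        pressure=interp(series.pressure),
        provenance=series.provenance + "+resample",
    )
    if out.vx is not None and out.vy is not None:
        out.v_tan = np.hypot(out.vx, out.vy)
    return out


def differentiate(series: KinematicSeries) -> KinematicSeries:
    """Fill velocity, acceleration and tangential speed by finite differences.

    Central differences in the interior, second-order one-sided stencils
    at the two ends (segmentation should ignore the first and last
    samples where the one-sided stencils live).
    """
    if len(series) < 3:
        raise ValueError("finite differences need at least 3 samples")
    if not series.is_uniform():
        raise ValueError("finite differences require a uniform time grid")
    dt = series.dt
    vx = np.gradient(series.x, dt, edge_order=2)
    vy = np.gradient(series.y, dt, edge_order=2)
    ax = np.gradient(vx, dt, edge_order=2)
    ay = np.gradient(vy, dt, edge_order=2)
    out = replace(series, vx=vx, vy=vy, ax=ax, ay=ay)
    out.v_tan = np.hypot(vx, vy)
    return out
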