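"""Ground-truthed synthetic trials for both tasks.

The drawing generator composes four minimum-jerk strokes (A>B>C>D>A)
whose velocity profiles are either separated by full stops (dwells) or
superposed with a controllable temporal overlap — the standard
composite-movement construction for blended point-to-point sequences.
Overlap raises the speed troughs at the via-points, which is exactly
what the coarticulation score measures, so the overlap parameter is the
generator-side ground truth for that score.

The tracking generator builds a stimulus from half-sine velocity waves
(position and velocity continuous everywhere, direction changes at each
half-wave boundary) and a follower that replays it with an optional
delay plus corrective sub-movements in one of two forms: an oscillatory
over/under-correction wobble at a programmed whole-wave frequency
(acceleration zero-crossings every half-period), or isolated
alternating-sign minimum-jerk offset steps at Poisson times.  The
scheduled crossing/step times are the ground truth the jitter detector
should recover.

Every generator is a pure function of its plan and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_formats import (
    ExperimentManifest,
    RawTrajectory,
    StimulusProgram,
    TargetLayout,
    save_json,
    write_trajectory,
)
from .preprocess import KinematicSeries

__all__ = [
    "TargetTrialPlan",
    "MirrorTrialPlan",
    "TrialGroundTruth",
    "default_layout",
    "min_jerk_stroke",
    "generate_target_trial",
    "generate_stimulus",
    "generate_follower",
    "generate_experiment",
    "DEFAULT_STIMULUS_FREQUENCIES_HZ",
]

# The protocol names 0.25 and 0.375 Hz and implies five levels; the
# remaining three are configurable placeholders, not canonical values.
DEFAULT_STIMULUS_FREQUENCIES_HZ = (0.25, 0.375, 0.5, 0.75, 1.0)


def default_layout(half_width: float = 50.0, half_height: float = 50.0,
                   radius: float = 2.5) -> TargetLayout:
    """A square arrangement of the four targets on the drawing sheet.

    The published task prints the targets on an A4 sheet without giving
    coordinates, so any layout is as canonical as another; a centred
    square keeps stroke lengths equal.
    """
    return TargetLayout(
        targets=(
            ("A", -half_width, -half_height, radius),
            ("B", -half_width, half_height, radius),
            ("C", half_width, half_height, radius),
            ("D", half_width, -half_height, radius),
        )
    )


def _as_via_triple(value) -> tuple[float, float, float]:
    if np.isscalar(value):
        v = float(value)
        return (v, v, v)
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValueError("per-via parameter needs exactly 3 values (at B, C, D)")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class TargetTrialPlan:
    """Recipe for one synthetic drawing trial.

    ``overlap`` blends consecutive strokes: the next stroke's onset is
    advanced by overlap x its duration, and the velocity profiles are
    summed.  ``dwell_times`` insert full stops at the via-points; a
    positive dwell forces zero overlap at that via-point.  Either may be
    a scalar / triple over the via-points (B, C, D).
    """

    layout: TargetLayout = field(default_factory=default_layout)
    stroke_durations: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5)
    dwell_times: tuple[float, float, float] | float = (0.0, 0.0, 0.0)
    overlap: tuple[float, float, float] | float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    rate: float = 200.0
    lead_in_s: float = 0.3
    lead_out_s: float = 0.3

    def resolved(self) -> tuple[tuple[float, ...], tuple[float, ...]]:
        dwell = _as_via_triple(self.dwell_times)
        overlap = _as_via_triple(self.overlap)
        if any(d < 0 for d in dwell) or any(not (0 <= o < 1) for o in overlap):
            raise ValueError("dwells must be >= 0 and overlaps in [0, 1)")
        for i, (d, o) in enumerate(zip(dwell, overlap)):
            if d > 0 and o > 0:
                raise ValueError(
                    f"via-point {i}: dwell and overlap are mutually exclusive"
                )
        if any(T <= 0 for T in self.stroke_durations):
            raise ValueError("stroke durations must be > 0")
        return dwell, overlap


@dataclass(frozen=True)
class MirrorTrialPlan:
    """Recipe for one synthetic tracking trial's follower.

    Exactly one of ``correction_rate`` (Poisson corrective events per
    second) or ``correction_wave_hz`` (regular events at spacing
    1/(2f), implementing a programmed whole-wave jitter frequency) may
    be positive.
    """

    program: StimulusProgram
    follower_delay: float = 0.0
    correction_rate: float = 0.0
    correction_wave_hz: float = 0.0
    correction_amplitude: float = 4.0
    correction_duration: float = 0.15
    noise_sd: float = 0.0
    seed: int = 0
    rate: float = 200.0

    def __post_init__(self) -> None:
        if self.follower_delay < 0:
            raise ValueError("follower delay must be >= 0")
        if self.correction_rate < 0 or self.correction_wave_hz < 0:
            raise ValueError("correction parameters must be >= 0")
        if self.correction_rate > 0 and self.correction_wave_hz > 0:
            raise ValueError("choose either a correction rate or a programmed frequency")
        if self.correction_wave_hz >= 2.5:
            raise ValueError(
                "programmed jitter frequency >= 2.5 Hz puts events less than "
                "200 ms apart, faster than the 5 Hz bound on voluntary corrections"
            )
        if self.correction_rate > 5.0:
            raise ValueError("correction rate above 5 events/s exceeds the 5 Hz bound")


@dataclass(frozen=True)
class TrialGroundTruth:
    """Generator-side truth written as a JSON sidecar next to each trial."""

    segment_start: float | None = None
    segment_end: float | None = None
    stroke_onsets: tuple[float, ...] = ()
    stroke_offsets: tuple[float, ...] = ()
    true_overlap: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dwell_times: tuple[float, float, float] = (0.0, 0.0, 0.0)
    injected_correction_times: tuple[float, ...] = ()
    program_frequencies: tuple[float, ...] = ()
    follower_delay: float = 0.0

    def to_dict(self) -> dict:
        return {
            "segment_start": self.segment_start,
            "segment_end": self.segment_end,
            "stroke_onsets": list(self.stroke_onsets),
            "stroke_offsets": list(self.stroke_offsets),
            "true_overlap": list(self.true_overlap),
            "dwell_times": list(self.dwell_times),
            "injected_correction_times": list(self.injected_correction_times),
            "program_frequencies": list(self.program_frequencies),
            "follower_delay": self.follower_delay,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialGroundTruth":
        return cls(
            segment_start=d.get("segment_start"),
            segment_end=d.get("segment_end"),
            stroke_onsets=tuple(d.get("stroke_onsets", ())),
            stroke_offsets=tuple(d.get("stroke_offsets", ())),
            true_overlap=tuple(d.get("true_overlap", (0.0, 0.0, 0.0))),
            dwell_times=tuple(d.get("dwell_times", (0.0, 0.0, 0.0))),
            injected_correction_times=tuple(d.get("injected_correction_times", ())),
            program_frequencies=tuple(d.get("program_frequencies", ())),
            follower_delay=float(d.get("follower_delay", 0.0)),
        )


def _min_jerk_shape(tau: np.ndarray) -> np.ndarray:
    """Quintic position shape s(tau) with s(0)=0, s(1)=1, zero endpoint
    velocity and acceleration."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _min_jerk_shape_d1(tau: np.ndarray) -> np.ndarray:
    out = np.zeros_like(tau)
    m = (tau > 0) & (tau < 1)
    tm = tau[m]
    out[m] = 30.0 * tm**2 * (1.0 - tm) ** 2
    return out


def min_jerk_stroke(
    start: tuple[float, float],
    end: tuple[float, float],
    duration: float,
    rate: float = 200.0,
) -> KinematicSeries:
    """Sample one minimum-jerk point-to-point stroke.

    The quintic profile has zero velocity and acceleration at both
    endpoints and reaches its peak speed, 15/8 x distance / duration, at
    the temporal midpoint.  A zero-length displacement is a static hold.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    tau = t / duration
    s = _min_jerk_shape(tau)
    ds = _min_jerk_shape_d1(tau) / duration
    dx, dy = end[0] - start[0], end[1] - start[1]
    vx, vy = dx * ds, dy * ds
    series = KinematicSeries(
        t=t,
        x=start[0] + dx * s,
        y=start[1] + dy * s,
        vx=vx,
        vy=vy,
        provenance="min_jerk",
    )
    series.v_tan = np.hypot(vx, vy)
    return series


def _stroke_schedule(plan: TargetTrialPlan) -> tuple[np.ndarray, np.ndarray]:
    """Onset and offset times of the four strokes, relative to drawing start."""
    dwell, overlap = plan.resolved()
    T = plan.stroke_durations
    onsets = np.empty(4)
    onsets[0] = 0.0
    for k in range(1, 4):
        onsets[k] = onsets[k - 1] + T[k - 1] + dwell[k - 1] - overlap[k - 1] * T[k]
    offsets = onsets + np.asarray(T)
    return onsets, offsets


def _clean_drawing_profile(
    plan: TargetTrialPlan, t: np.ndarray, t_draw_start: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free x, y, vx, vy of the composed four-stroke movement."""
    layout = plan.layout
    pts = [layout.center(lbl) for lbl in layout.order]
    onsets, _ = _stroke_schedule(plan)
    x = np.full_like(t, pts[0][0])
    y = np.full_like(t, pts[0][1])
    vx = np.zeros_like(t)
    vy = np.zeros_like(t)
    for k in range(4):
        T = plan.stroke_durations[k]
        tau = (t - t_draw_start - onsets[k]) / T
        s = _min_jerk_shape(tau)
        ds = _min_jerk_shape_d1(tau) / T
        dx = pts[k + 1][0] - pts[k][0]
        dy = pts[k + 1][1] - pts[k][1]
        x = x + dx * s
        y = y + dy * s
        vx = vx + dx * ds
        vy = vy + dy * ds
    return x, y, vx, vy


def _threshold_bounds(
    plan: TargetTrialPlan, t_draw_start: float, threshold_fraction: float = 0.05
) -> tuple[float, float]:
    """Analytic 5%-of-peak speed bounds of the clean composed profile.

    Evaluated on a fine grid (10x the sampling rate) so the truth is
    independent of the analysis-side sampling and smoothing.
    """
    _, offsets = _stroke_schedule(plan)
    t_end = t_draw_start + offsets[-1]
    fine = np.arange(0.0, t_end + 0.1, 1.0 / (10.0 * plan.rate))
    _, _, vx, vy = _clean_drawing_profile(plan, fine, t_draw_start)
    v = np.hypot(vx, vy)
    thr = threshold_fraction * float(np.max(v))
    above = np.nonzero(v > thr)[0]
    return float(fine[above[0]]), float(fine[above[-1]])


def generate_target_trial(
    plan: TargetTrialPlan, trial_id: str = "trial"
) -> tuple[RawTrajectory, TrialGroundTruth]:
    """Synthesize one drawing trial and its ground truth.

    The record starts with a pen-up lead-in resting at target A
    (pressure 0) so the pressure-gated onset rule is exercised, then the
    composed movement with pressure 1, then a pen-down hold at A.
    Gaussian position noise of ``noise_sd`` mm is added when requested.
    """
    dwell, overlap = plan.resolved()
    onsets, offsets = _stroke_schedule(plan)
    t_draw = plan.lead_in_s
    total = t_draw + offsets[-1] + plan.lead_out_s
    n = int(round(total * plan.rate)) + 1
    t = np.arange(n) / plan.rate
    x, y, _, _ = _clean_drawing_profile(plan, t, t_draw)
    rng = np.random.default_rng(plan.seed)
    if plan.noise_sd > 0:
        x = x + rng.normal(0.0, plan.noise_sd, n)
        y = y + rng.normal(0.0, plan.noise_sd, n)
    pressure = np.where(t >= t_draw, 1.0, 0.0)
    seg0, seg1 = _threshold_bounds(plan, t_draw)
    raw = RawTrajectory(
        trial_id=trial_id, t=t, x=x, y=y, pressure=pressure,
        sample_rate_nominal=plan.rate,
    )
    truth = TrialGroundTruth(
        segment_start=seg0,
        segment_end=seg1,
        stroke_onsets=tuple(t_draw + onsets),
        stroke_offsets=tuple(t_draw + offsets),
        true_overlap=overlap,
        dwell_times=dwell,
    )
    return raw, truth


def generate_stimulus(program: StimulusProgram, rate: float = 200.0) -> KinematicSeries:
    """Sample a half-sine-velocity stimulus with analytic derivatives.

    Within each half-wave of period-half T at block frequency f
    (T = 1/(2f)) the velocity is a half sine; the sign alternates from
    one half-wave to the next so the pen shuttles between ``center_x``
    and ``center_x + amplitude`` with position and velocity continuous
    everywhere, including across frequency-block boundaries (where the
    velocity is exactly zero).
    """
    # half-wave boundaries and directions
    bounds = [0.0]
    freqs: list[float] = []
    for f, n_half in program.blocks:
        T = 1.0 / (2.0 * f)
        for _ in range(n_half):
            bounds.append(bounds[-1] + T)
            freqs.append(f)
    bounds_arr = np.array(bounds)
    duration = bounds_arr[-1]
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    x = np.full(n, program.center_x, dtype=float)
    vx = np.zeros(n)
    ax = np.zeros(n)
    A = program.amplitude
    x0 = program.center_x
    for k in range(len(freqs)):
        lo, hi = bounds_arr[k], bounds_arr[k + 1]
        T = hi - lo
        direction = 1.0 if k % 2 == 0 else -1.0
        base = x0 if direction > 0 else x0 + A
        m = (t >= lo) & (t < hi) if k < len(freqs) - 1 else (t >= lo) & (t <= hi + 1e-12)
        ph = np.pi * (t[m] - lo) / T
        x[m] = base + direction * A * 0.5 * (1.0 - np.cos(ph))
        vx[m] = direction * A * np.pi / (2.0 * T) * np.sin(ph)
        ax[m] = direction * A * np.pi**2 / (2.0 * T**2) * np.cos(ph)
    series = KinematicSeries(
        t=t, x=x, y=np.zeros(n), vx=vx, vy=np.zeros(n),
        ax=ax, ay=np.zeros(n), provenance="stimulus",
    )
    series.v_tan = np.abs(vx)
    return series


def _correction_times(plan: MirrorTrialPlan, duration: float, rng) -> np.ndarray:
    d = plan.correction_duration
    margin = 0.5 + d
    if plan.correction_wave_hz > 0:
        gap = 1.0 / (2.0 * plan.correction_wave_hz)
        return np.arange(margin, duration - margin, gap)
    if plan.correction_rate > 0:
        # Poisson arrivals thinned to the voluntary-correction refractory gap
        times = []
        tcur = margin + rng.exponential(1.0 / plan.correction_rate)
        while tcur < duration - margin:
            if not times or tcur - times[-1] > max(0.25, d):
                times.append(tcur)
            tcur += rng.exponential(1.0 / plan.correction_rate)
        return np.array(times)
    return np.array([])


def generate_follower(
    stimulus: KinematicSeries, plan: MirrorTrialPlan, trial_id: str = "trial"
) -> tuple[RawTrajectory, TrialGroundTruth]:
    """Synthesize a follower record for a sampled stimulus.

    The base record is the stimulus replayed with ``follower_delay``
    (holding the initial position before the delayed record begins).
    Corrective behaviour takes one of two forms:

    * ``correction_wave_hz`` > 0 — oscillatory corrective wobble: a
      sinusoidal over/under-correction around the tracked trajectory at
      frequency f, i.e. one corrective submovement per half-period.
      Its amplitude is scaled so the corrective acceleration exceeds
      the stimulus acceleration by a fixed margin, so the follower's
      acceleration crosses zero at every wobble half-period — a
      programmed whole-wave jitter frequency of exactly f.  (In slow
      tracking the corrective velocity is comparable to the stimulus
      velocity, which is what this scaling reproduces.)
    * ``correction_rate`` > 0 — isolated corrections: alternating-sign
      minimum-jerk offset steps of ``correction_amplitude`` at Poisson
      times, each contributing an extra acceleration zero-crossing near
      its centre.
    """
    t = stimulus.t
    rng = np.random.default_rng(plan.seed)
    x = np.interp(t - plan.follower_delay, t, stimulus.x, left=stimulus.x[0])
    if plan.correction_wave_hz > 0:
        f = plan.correction_wave_hz
        omega = 2.0 * np.pi * f
        a_stim_max = float(np.max(np.abs(stimulus.ax))) if stimulus.ax is not None else 0.0
        # 3x margin keeps crossing times within ~arcsin(1/3)/omega of the
        # programmed schedule even where the stimulus acceleration peaks
        amp = max(plan.correction_amplitude, 3.0 * a_stim_max / omega**2)
        # random phase: a wobble phase-locked to a commensurate stimulus
        # block would have all its crossings excluded as obligatory
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x = x + amp * np.sin(omega * t + phase)
        # acceleration zero-crossings of the wobble: every half-period
        first = (np.ceil(phase / np.pi) * np.pi - phase) / omega
        events = np.arange(first, float(t[-1]), 1.0 / (2.0 * f))
    else:
        events = _correction_times(plan, float(t[-1]), rng)
        d = plan.correction_duration
        sign = 1.0
        for tc in events:
            tau = (t - (tc - d / 2.0)) / d
            x = x + sign * plan.correction_amplitude * _min_jerk_shape(tau)
            sign = -sign
    if plan.noise_sd > 0:
        x = x + rng.normal(0.0, plan.noise_sd, t.size)
    raw = RawTrajectory(
        trial_id=trial_id, t=t.copy(), x=x, y=np.zeros_like(t),
        pressure=np.ones_like(t), sample_rate_nominal=plan.rate,
    )
    truth = TrialGroundTruth(
        injected_correction_times=tuple(float(v) for v in events),
        program_frequencies=tuple(sorted({f for f, _ in plan.program.blocks})),
        follower_delay=plan.follower_delay,
    )
    return raw, truth


def _random_program(
    rng, frequencies, duration_s: float, amplitude: float, center_x: float
) -> StimulusProgram:
    """A 2-3 block program of roughly ``duration_s`` total, one block per
    distinct frequency."""
    n_blocks = min(int(rng.integers(2, 4)), len(frequencies))
    chosen = rng.choice(len(frequencies), size=n_blocks, replace=False)
    per_block = duration_s / n_blocks
    blocks = []
    for i in chosen:
        f = float(frequencies[i])
        n_half = max(1, int(round(per_block * 2.0 * f)))
        blocks.append((f, n_half))
    return StimulusProgram(blocks=tuple(blocks), amplitude=amplitude, center_x=center_x)


def generate_experiment(
    manifest: ExperimentManifest,
    effects: Mapping[str, Mapping[str, Mapping[str, object]]],
    out_dir,
    seed: int = 0,
    base_plan_kwargs: Mapping[str, object] | None = None,
    mirror_duration_s: float = 60.0,
    stimulus_frequencies=DEFAULT_STIMULUS_FREQUENCIES_HZ,
) -> Path:
    """Write a full synthetic study to ``out_dir``.

    ``effects`` maps group -> phase -> plan-parameter overrides (e.g.
    the treated groups raise ``overlap`` or lower ``correction_rate``
    after the pre-test while the control group holds its parameters).
    One trajectory file and one ground-truth JSON sidecar are written
    per trial, plus the manifest, layout / stimulus descriptions and an
    index of trials.

    Returns the output directory path.
    """
    valid_phases = {p for p, _ in manifest.phases}
    for group, phase_map in effects.items():
        if group not in {g for _, g in manifest.subjects}:
            raise ValueError(f"effects reference unknown group {group!r}")
        unknown = set(phase_map) - valid_phases
        if unknown:
            raise ValueError(f"effects for {group!r} reference unknown phases {sorted(unknown)}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_json(manifest, out / "manifest.json")
    base = dict(base_plan_kwargs or {})
    root_rng = np.random.default_rng(seed)
    layout = base.get("layout", default_layout())
    if manifest.task == "target":
        save_json(layout, out / "layout.json")

    index = []
    for subject_id, group in manifest.subjects:
        for phase, n_trials in manifest.phases:
            overrides = dict(effects.get(group, {}).get(phase, {}))
            for i in range(n_trials):
                trial_seed = int(root_rng.integers(0, 2**31 - 1))
                trial_id = f"{subject_id}_{phase}_{i:03d}"
                if manifest.task == "target":
                    kwargs = {**base, **overrides, "layout": layout, "seed": trial_seed}
                    plan = TargetTrialPlan(**kwargs)
                    raw, truth = generate_target_trial(plan, trial_id)
                else:
                    kwargs = {**base, **overrides, "seed": trial_seed}
                    kwargs.pop("layout", None)
                    program = kwargs.pop("program", None)
                    if program is None:
                        program = _random_program(
                            root_rng, stimulus_frequencies, mirror_duration_s,
                            amplitude=float(kwargs.pop("amplitude", 100.0)),
                            center_x=float(kwargs.pop("center_x", 0.0)),
                        )
                    plan = MirrorTrialPlan(program=program, **kwargs)
                    stim = generate_stimulus(program, rate=plan.rate)
                    raw, truth = generate_follower(stim, plan, trial_id)
                    save_json(program, out / f"{trial_id}.stimulus.json")
                write_trajectory(raw, out / f"{trial_id}.csv")
                save_json(truth.to_dict(), out / f"{trial_id}.truth.json")
                index.append(
                    {"trial_id": trial_id, "subject_id": subject_id,
                     "group": group, "phase": phase, "trial_index": i}
                )
    (out / "trials.json").write_text(json.dumps(index, indent=2) + "\n")
    return out
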