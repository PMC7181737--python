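"""End-to-end orchestration: simulate a dataset, analyze it, summarize.

The analysis entry points are plain functions over a `PipelineConfig`;
the command-line wrapper in `cli` adds nothing but argument parsing.
Outputs are tidy long-format CSV tables (one row per trial) plus a
machine-readable JSON run-log carrying the full configuration, its
hash, the seed and library versions, so any table can be traced back to
the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accuracy import movement_duration, percent_improvement, spatial_error
from .coarticulation import (
    complete_profile,
    coarticulation_score,
    count_velocity_peaks,
    find_extrema,
)
from .io_formats import (
    ColumnDialect,
    load_layout,
    load_manifest,
    load_program,
    read_trajectory,
    write_results_table,
)
from .mirror_metrics import (
    RegisteredPair,
    detect_jitter,
    jitter_frequencies,
    peak_jitter_frequency,
    tracking_error_dT,
    tracking_error_dV,
    tracking_error_dX,
)
from .preprocess import (
    KinematicSeries,
    differentiate,
    lowpass_two_way,
    resample_uniform,
    smooth_with_splines,
)
from .segmentation import detect_bounds, qc_trial
from .synthetic import TrialGroundTruth, generate_experiment, generate_stimulus

__all__ = ["PipelineConfig", "run_target_analysis", "run_mirror_analysis", "simulate"]


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, with the published constants as
    defaults: 6-sample spline knots, 4th-order two-way 5 Hz Butterworth,
    100 Hz resampling, 5% onset/offset threshold, 200 ms jitter
    refractory window."""

    task: str = "target"
    input_dir: str = "."
    output_dir: str = "results"
    seed: int = 0
    # drawing-task parameters
    knot_spacing_samples: int = 6
    threshold_fraction: float = 0.05
    peak_prominence_fraction: float = 0.05
    gap_limit_s: float = 0.1
    completeness_radius_mm: float = 10.0
    # tracking-task parameters
    filter_order: int = 4
    filter_cutoff_hz: float = 5.0
    resample_hz: float = 100.0
    min_sep_s: float = 0.2
    stim_match_window_s: float = 0.05
    kde_bandwidth: str | float = "silverman"
    kde_min_events: int = 5
    dv_floor_mm_s: float = 1.0
    dx_floor_mm: float = 1.0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_run_log(config: PipelineConfig, out: Path, extra: dict) -> None:
    log = {
        "strokekin_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        **extra,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")


def _load_index(input_dir: Path) -> list[dict]:
    index_path = input_dir / "trials.json"
    if index_path.exists():
        return json.loads(index_path.read_text())
    # fall back to globbing trajectory files
    return [
        {"trial_id": p.stem, "subject_id": "s0", "group": "control", "phase": "pre",
         "trial_index": i}
        for i, p in enumerate(sorted(input_dir.glob("*.csv")))
        if not p.stem.endswith("results")
    ]


def _phase_order(rows: pd.DataFrame) -> list[str]:
    seen: list[str] = []
    for p in rows["phase"]:
        if p not in seen:
            seen.append(p)
    return seen


def run_target_analysis(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every drawing trial in ``input_dir`` and summarize by subject/phase.

    Writes ``trial_results.csv`` (QC verdict, coarticulation score, peak
    count, spatial error, duration per trial), ``summary.csv``
    (per-subject per-phase means, medians for error and duration, and
    baseline-normalized scores) and a run-log.  A trial that cannot be
    read or scored is flagged in its row; the run continues.
    """
    input_dir, out = Path(config.input_dir), Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = load_layout(input_dir / "layout.json")
    index = _load_index(input_dir)
    rows = []
    for entry in index:
        trial_id = entry["trial_id"]
        row = {
            "trial_id": trial_id,
            "subject_id": entry.get("subject_id", ""),
            "group": entry.get("group", ""),
            "phase": entry.get("phase", ""),
            "block": entry.get("trial_index", 0),
            "kept": False,
            "qc_reason": "",
            "score": np.nan,
            "n_peaks": np.nan,
            "substituted_count": np.nan,
            "spatial_error_mm": np.nan,
            "duration_s": np.nan,
            "status": "ok",
        }
        try:
            raw = read_trajectory(input_dir / f"{trial_id}.csv", trial_id=trial_id)
            qc = qc_trial(
                raw, layout,
                gap_limit_s=config.gap_limit_s,
                completeness_radius_mm=config.completeness_radius_mm,
            )
            row["kept"] = qc.kept
            row["qc_reason"] = qc.reason.value
            if qc.kept:
                series = smooth_with_splines(raw, knot_spacing=config.knot_spacing_samples)
                seg = detect_bounds(
                    series,
                    threshold_fraction=config.threshold_fraction,
                    peak_prominence_fraction=config.peak_prominence_fraction,
                )
                profile = find_extrema(series, seg, config.peak_prominence_fraction)
                completed = complete_profile(profile)
                result = coarticulation_score(completed)
                acc = spatial_error(series, seg, layout)
                row.update(
                    score=result.score,
                    n_peaks=count_velocity_peaks(profile),
                    substituted_count=int(np.sum(completed.substituted_peaks)),
                    spatial_error_mm=acc.spatial_error,
                    duration_s=movement_duration(seg),
                )
        except Exception as exc:  # noqa: BLE001 - per-trial fault isolation
            row["kept"] = False
            row["qc_reason"] = row["qc_reason"] or "error"
            row["status"] = f"error: {exc}"
        rows.append(row)

    trials = pd.DataFrame(rows)
    trials.to_csv(out / "trial_results.csv", index=False)
    summary = summarize_target(trials)
    summary.to_csv(out / "summary.csv", index=False)
    _write_run_log(config, out, {"task": "target", "n_trials": len(trials),
                                 "n_kept": int(trials["kept"].sum())})
    return trials, summary


def summarize_target(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject per-phase aggregation of the drawing-task metrics.

    Scores are averaged (mean), spatial error and duration summarized by
    both median and mean; the normalized score subtracts each subject's
    pre-test (first phase) mean, and duration improvement is percent of
    the pre-test median.
    """
    kept = trials[trials["kept"]].copy()
    phases = _phase_order(trials)
    recs = []
    for (subject, group), sub in kept.groupby(["subject_id", "group"], sort=True):
        pre = sub[sub["phase"] == phases[0]]
        baseline_score = float(pre["score"].mean()) if len(pre) else np.nan
        baseline_dur = float(pre["duration_s"].median()) if len(pre) else np.nan
        for phase in phases:
            ph = sub[sub["phase"] == phase]
            if not len(ph):
                continue
            mean_score = float(ph["score"].mean())
            dur_med = float(ph["duration_s"].median())
            if np.isfinite(baseline_dur) and baseline_dur > 0:
                improvement, _ = percent_improvement(dur_med, baseline_dur)
            else:
                improvement = np.nan
            recs.append(
                {
                    "subject_id": subject,
                    "group": group,
                    "phase": phase,
                    "n_trials": int(len(ph)),
                    "mean_score": mean_score,
                    "normalized_score": mean_score - baseline_score,
                    "mean_n_peaks": float(ph["n_peaks"].mean()),
                    "median_spatial_error_mm": float(ph["spatial_error_mm"].median()),
                    "mean_spatial_error_mm": float(ph["spatial_error_mm"].mean()),
                    "median_duration_s": dur_med,
                    "mean_duration_s": float(ph["duration_s"].mean()),
                    "pct_duration_improvement": improvement,
                }
            )
    return pd.DataFrame(recs)


def _block_intervals(program) -> list[tuple[float, float, float]]:
    """(t_start, t_end, frequency) per block of a stimulus program."""
    t = 0.0
    out = []
    for f, n_half in program.blocks:
        dur = n_half / (2.0 * f)
        out.append((t, t + dur, f))
        t += dur
    return out


def run_mirror_analysis(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze every tracking trial: jitter events plus dX/dV/dT.

    Each trial file must have a ``<trial_id>.stimulus.json`` program
    next to it; a missing stimulus flags the trial and the run
    continues.  Jitter frequencies are assigned to the stimulus
    frequency block their events fall in and pooled per subject, phase
    and stimulus frequency; the pre/post table reports the KDE-peak
    improvement (pre minus post) per subject and frequency.
    """
    input_dir, out = Path(config.input_dir), Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = _load_index(input_dir)
    rows = []
    pooled: dict[tuple[str, str, float], list[float]] = {}
    for entry in index:
        trial_id = entry["trial_id"]
        row = {
            "trial_id": trial_id,
            "subject_id": entry.get("subject_id", ""),
            "group": entry.get("group", ""),
            "phase": entry.get("phase", ""),
            "stimulus_frequencies": "",
            "n_jitter_events": np.nan,
            "peak_jitter_hz": np.nan,
            "dX": np.nan,
            "dV": np.nan,
            "dT_s": np.nan,
            "status": "ok",
        }
        try:
            stim_path = input_dir / f"{trial_id}.stimulus.json"
            if not stim_path.exists():
                raise FileNotFoundError(f"no stimulus program for trial {trial_id}")
            program = load_program(stim_path)
            raw = read_trajectory(input_dir / f"{trial_id}.csv", trial_id=trial_id)

            filtered = lowpass_two_way(
                raw, order=config.filter_order, cutoff_hz=config.filter_cutoff_hz
            )
            follower = resample_uniform(differentiate(filtered), config.resample_hz)
            stim_raw = generate_stimulus(program, rate=raw.sample_rate_nominal)
            # put the stimulus on the follower's exact grid so timestamp
            # round-off in the trajectory file cannot misalign the two
            stim = KinematicSeries(
                t=follower.t,
                x=np.interp(follower.t, stim_raw.t, stim_raw.x),
                y=np.zeros_like(follower.t),
                vx=np.interp(follower.t, stim_raw.t, stim_raw.vx),
                vy=np.zeros_like(follower.t),
                ax=np.interp(follower.t, stim_raw.t, stim_raw.ax),
                ay=np.zeros_like(follower.t),
                provenance="stimulus+resample",
            )
            stim.v_tan = np.abs(stim.vx)

            events = detect_jitter(
                follower, stim,
                min_sep=config.min_sep_s,
                stim_match_window=config.stim_match_window_s,
            )
            freqs = jitter_frequencies(events)
            pair = RegisteredPair.from_series(follower, stim, x_c=program.center_x)
            row.update(
                stimulus_frequencies=";".join(
                    f"{f:g}" for f, _ in program.blocks
                ),
                n_jitter_events=events.n_events,
                dX=tracking_error_dX(pair, denom_floor=config.dx_floor_mm),
                dV=tracking_error_dV(pair, denom_floor=config.dv_floor_mm_s),
                dT_s=tracking_error_dT(follower, stim),
            )
            if freqs.size >= config.kde_min_events:
                row["peak_jitter_hz"] = peak_jitter_frequency(
                    freqs, bandwidth=config.kde_bandwidth,
                    min_events=config.kde_min_events,
                ).peak_frequency
            # pool event frequencies by the stimulus block they occur in
            mids = 0.5 * (events.event_times[1:] + events.event_times[:-1])
            intervals = _block_intervals(program)
            for m, fj in zip(mids, freqs):
                f_stim = next((b[2] for b in intervals if b[0] <= m <= b[1]), None)
                if f_stim is not None:
                    key = (row["subject_id"], row["phase"], float(f_stim))
                    pooled.setdefault(key, []).append(float(fj))
        except Exception as exc:  # noqa: BLE001 - per-trial fault isolation
            row["status"] = f"error: {exc}"
        rows.append(row)

    trials = pd.DataFrame(rows)
    trials.to_csv(out / "trial_results.csv", index=False)

    phases = _phase_order(trials)
    subjects = {(e.get("subject_id", ""), e.get("group", "")) for e in index}
    recs = []
    for subject, group in sorted(subjects):
        stim_fs = sorted({k[2] for k in pooled if k[0] == subject})
        for f_stim in stim_fs:
            peaks: dict[str, float] = {}
            for phase in phases:
                sample = pooled.get((subject, phase, f_stim), [])
                if len(sample) >= config.kde_min_events:
                    peaks[phase] = peak_jitter_frequency(
                        np.array(sample), bandwidth=config.kde_bandwidth,
                        min_events=config.kde_min_events,
                    ).peak_frequency
            rec = {"subject_id": subject, "group": group, "stimulus_frequency_hz": f_stim}
            for phase in phases:
                rec[f"peak_jitter_hz_{phase}"] = peaks.get(phase, np.nan)
            if len(phases) >= 2 and phases[0] in peaks and phases[-1] in peaks:
                rec["improvement_hz"] = peaks[phases[0]] - peaks[phases[-1]]
            else:
                rec["improvement_hz"] = np.nan
            recs.append(rec)
    summary = pd.DataFrame(recs)
    summary.to_csv(out / "summary.csv", index=False)
    _write_run_log(config, out, {"task": "mirror", "n_trials": len(trials)})
    return trials, summary


def simulate(
    manifest, effects, out_dir, seed: int = 0, **kwargs
):
    """Generate a synthetic dataset consumable by the analysis commands."""
    if not isinstance(manifest, (str, Path)):
        m = manifest
    else:
        m = load_manifest(manifest)
    return generate_experiment(m, effects, out_dir, seed=seed, **kwargs)
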