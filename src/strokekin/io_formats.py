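"""File formats and domain containers for pen-trajectory experiments.

Trajectories are delimited text (comma by default, tab accepted) with a
header row; layouts, stimulus programs and experiment manifests are JSON.
Times are seconds, positions millimetres, pressure in arbitrary device
units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawTrajectory",
    "TargetLayout",
    "StimulusProgram",
    "ExperimentManifest",
    "ColumnDialect",
    "TrajectoryFormatError",
    "TrajectoryValidationError",
    "read_trajectory",
    "write_trajectory",
    "write_results_table",
    "read_results_table",
]


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file does not have the expected columns."""


class TrajectoryValidationError(ValueError):
    """Raised when parsed trajectory data violates an invariant."""


@dataclass(frozen=True)
class ColumnDialect:
    """Column-name mapping for trajectory files.

    The acquisition software's column names are not standardised, so the
    mapping is configurable.  ``y`` and ``pressure`` may be absent in the
    file (1-D tracking records have no y channel; some exports drop
    pressure), in which case they default to zeros / ones respectively.
    """

    t: str = "t"
    x: str = "x"
    y: str = "y"
    pressure: str = "pressure"
    delimiter: str = ","


@dataclass
class RawTrajectory:
    """One trial's sampled pen record.

    Attributes
    ----------
    trial_id : str
        Identifier carried through analysis output tables.
    t : ndarray
        Sample times in seconds, strictly increasing.
    x, y : ndarray
        Planar position in mm.  ``y`` is constant (typically zero) for
        1-D tracking trials.
    pressure : ndarray
        Stylus pressure, arbitrary units >= 0.
    sample_rate_nominal : float
        Nominal acquisition rate in Hz (200 for the tablet used here).
    """

    trial_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    sample_rate_nominal: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        n = self.t.size
        if not (self.x.size == self.y.size == self.pressure.size == n):
            raise TrajectoryValidationError(
                f"channel lengths differ: t={n}, x={self.x.size}, "
                f"y={self.y.size}, pressure={self.pressure.size}"
            )
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise TrajectoryValidationError(
                f"trial {self.trial_id!r}: time stamps not strictly increasing"
            )
        if self.sample_rate_nominal <= 0:
            raise TrajectoryValidationError("sample_rate_nominal must be > 0")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0


@dataclass(frozen=True)
class TargetLayout:
    """Four labelled disk targets and the order they are visited in.

    ``order`` starts and ends at the same label (a closed shape, e.g.
    A>B>C>D>A).  Radii are layout parameters: the printed sheet shows
    dots whose size the task description does not fix.
    """

    targets: tuple[tuple[str, float, float, float], ...]
    order: tuple[str, ...] = ("A", "B", "C", "D", "A")

    def __post_init__(self) -> None:
        labels = [t[0] for t in self.targets]
        if len(labels) != 4 or len(set(labels)) != 4:
            raise ValueError("layout requires 4 distinct target labels")
        if any(t[3] <= 0 for t in self.targets):
            raise ValueError("target radii must be > 0")
        if self.order[0] != self.order[-1]:
            raise ValueError("visiting order must start and end at the same label")
        unknown = set(self.order) - set(labels)
        if unknown:
            raise ValueError(f"order references unknown labels: {sorted(unknown)}")

    def center(self, label: str) -> tuple[float, float]:
        for lab, cx, cy, _ in self.targets:
            if lab == label:
                return (cx, cy)
        raise KeyError(label)

    def radius(self, label: str) -> float:
        for lab, _, _, r in self.targets:
            if lab == label:
                return r
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "targets": [
                {"label": lab, "center_x": cx, "center_y": cy, "radius": r}
                for lab, cx, cy, r in self.targets
            ],
            "order": list(self.order),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TargetLayout":
        return cls(
            targets=tuple(
                (t["label"], float(t["center_x"]), float(t["center_y"]), float(t["radius"]))
                for t in d["targets"]
            ),
            order=tuple(d.get("order", ("A", "B", "C", "D", "A"))),
        )


@dataclass(frozen=True)
class StimulusProgram:
    """A 1-D tracking stimulus built from half-sine velocity waves.

    Each block contributes ``n_half_waves`` half-period excursions at the
    block frequency; the wave train alternates direction so position and
    velocity are continuous everywhere, including across frequency
    changes.  ``amplitude`` is the per-excursion travel in mm and
    ``center_x`` the position every excursion departs from.
    """

    blocks: tuple[tuple[float, int], ...]
    amplitude: float = 100.0
    center_x: float = 0.0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("program needs at least one block")
        for f, n in self.blocks:
            if f <= 0:
                raise ValueError(f"block frequency must be > 0, got {f}")
            if n < 1:
                raise ValueError("each block needs >= 1 half-wave")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    @property
    def duration(self) -> float:
        """Total duration in seconds: each half-wave lasts 1/(2f)."""
        return float(sum(n / (2.0 * f) for f, n in self.blocks))

    def to_dict(self) -> dict:
        return {
            "blocks": [{"frequency": f, "n_half_waves": n} for f, n in self.blocks],
            "amplitude": self.amplitude,
            "center_x": self.center_x,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StimulusProgram":
        return cls(
            blocks=tuple((float(b["frequency"]), int(b["n_half_waves"])) for b in d["blocks"]),
            amplitude=float(d.get("amplitude", 100.0)),
            center_x=float(d.get("center_x", 0.0)),
        )


VALID_GROUPS = ("analogy", "explicit", "control")
VALID_TASKS = ("target", "mirror")


@dataclass(frozen=True)
class ExperimentManifest:
    """Subjects, phases and task of one (synthetic) experiment.

    ``phases`` maps ordered phase names (pre, train, post) to the number
    of trials per phase.  A full-scale drawing protocol is pre=40, 4x30
    training, post=40; a full-scale tracking session is 3 pre + 8
    training one-minute trials — but the manifest is free to scale these
    down for quick runs.
    """

    subjects: tuple[tuple[str, str], ...]
    phases: tuple[tuple[str, int], ...]
    task: str = "target"

    def __post_init__(self) -> None:
        if self.task not in VALID_TASKS:
            raise ValueError(f"task must be one of {VALID_TASKS}")
        for _, group in self.subjects:
            if group not in VALID_GROUPS:
                raise ValueError(f"group must be one of {VALID_GROUPS}, got {group!r}")
        names = [p for p, _ in self.phases]
        if len(names) != len(set(names)):
            raise ValueError("phase names must be unique")
        if any(n <= 0 for _, n in self.phases):
            raise ValueError("phase block sizes must be > 0")

    def to_dict(self) -> dict:
        return {
            "subjects": [{"subject_id": s, "group": g} for s, g in self.subjects],
            "phases": [{"phase_name": p, "n_trials": n} for p, n in self.phases],
            "task": self.task,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentManifest":
        return cls(
            subjects=tuple((s["subject_id"], s["group"]) for s in d["subjects"]),
            phases=tuple((p["phase_name"], int(p["n_trials"])) for p in d["phases"]),
            task=d.get("task", "target"),
        )


def save_json(obj, path) -> None:
    """Write a TargetLayout / StimulusProgram / ExperimentManifest (or dict)."""
    d = obj.to_dict() if hasattr(obj, "to_dict") else obj
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def load_layout(path) -> TargetLayout:
    return TargetLayout.from_dict(json.loads(Path(path).read_text()))


def load_program(path) -> StimulusProgram:
    return StimulusProgram.from_dict(json.loads(Path(path).read_text()))


def load_manifest(path) -> ExperimentManifest:
    return ExperimentManifest.from_dict(json.loads(Path(path).read_text()))


def read_trajectory(
    path,
    dialect: ColumnDialect = ColumnDialect(),
    trial_id: str | None = None,
    sample_rate_nominal: float | None = None,
) -> RawTrajectory:
    """Read one trial's time series from a delimited text file.

    Missing optional columns (``y``, ``pressure``) are filled with zeros
    and ones respectively.  The nominal sample rate defaults to the
    median sampling interval's reciprocal.

    Raises
    ------
    TrajectoryFormatError
        If a required column is absent.
    TrajectoryValidationError
        If timestamps are not strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter)
    if dialect.t not in df.columns:
        raise TrajectoryFormatError(f"{path.name}: missing time column {dialect.t!r}")
    if dialect.x not in df.columns:
        raise TrajectoryFormatError(f"{path.name}: missing position column {dialect.x!r}")
    t = df[dialect.t].to_numpy(dtype=float)
    x = df[dialect.x].to_numpy(dtype=float)
    y = (
        df[dialect.y].to_numpy(dtype=float)
        if dialect.y in df.columns
        else np.zeros_like(x)
    )
    pressure = (
        df[dialect.pressure].to_numpy(dtype=float)
        if dialect.pressure in df.columns
        else np.ones_like(x)
    )
    if sample_rate_nominal is None:
        dt = np.median(np.diff(t)) if t.size > 1 else 1.0
        sample_rate_nominal = 1.0 / float(dt)
    return RawTrajectory(
        trial_id=trial_id if trial_id is not None else path.stem,
        t=t,
        x=x,
        y=y,
        pressure=pressure,
        sample_rate_nominal=float(sample_rate_nominal),
    )


def write_trajectory(raw: RawTrajectory, path, dialect: ColumnDialect = ColumnDialect()) -> None:
    """Write a trajectory as delimited text with a header row."""
    df = pd.DataFrame(
        {
            dialect.t: raw.t,
            dialect.x: raw.x,
            dialect.y: raw.y,
            dialect.pressure: raw.pressure,
        }
    )
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.9g")


def write_results_table(rows: Sequence[Mapping], path, columns: Sequence[str] | None = None) -> None:
    """Write per-trial metric records as CSV with a stable column order.

    All records must share one schema (same keys); the first record fixes
    the column order.  An empty record list writes a header-only file,
    using ``columns`` for the header (empty file if also absent).
    """
    rows = list(rows)
    if rows:
        schema = list(rows[0].keys())
        for i, r in enumerate(rows[1:], start=1):
            if list(r.keys()) != schema:
                raise ValueError(
                    f"record {i} schema {sorted(r.keys())} differs from first "
                    f"record schema {sorted(schema)}"
                )
        df = pd.DataFrame(rows, columns=schema)
    else:
        df = pd.DataFrame(columns=list(columns) if columns else [])
    df.to_csv(path, index=False)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
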