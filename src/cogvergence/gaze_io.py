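"""Data model and CSV readers/writers for binocular gaze recordings.

A *gaze recording* is the raw output of a screen-based eye tracker: a
time-ordered sequence of binocular samples, each carrying the on-screen
gaze point of the left and the right eye (in pixels) plus a per-eye
integer validity code.  Code 0 means the tracker considered the detection
valid; any non-zero code marks an unreliable sample (lost pupil, blink,
occlusion).  An *event log* is the stimulus schedule of one oddball
session: each trial shows a gray mask followed by a letter-string
stimulus, with the rare "target" trials differing from the frequent
"distractor" trials only in stimulus colour.

File formats (comma-separated, UTF-8, header row mandatory, "." decimal):

gaze CSV      t,left_x,left_y,right_x,right_y,valid_left,valid_right
events CSV    trial_index,condition,mask_onset,stimulus_onset,
              mask_duration,stimulus_duration,stimulus_string

All times are milliseconds; coordinates are screen pixels.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError

GAZE_COLUMNS = ["t", "left_x", "left_y", "right_x", "right_y", "valid_left", "valid_right"]
EVENT_COLUMNS = [
    "trial_index",
    "condition",
    "mask_onset",
    "stimulus_onset",
    "mask_duration",
    "stimulus_duration",
    "stimulus_string",
]
CONDITIONS = ("target", "distractor")


@dataclass(frozen=True)
class GazeSample:
    """One binocular sample.

    Coordinates may lie outside the screen bounds (trackers report
    overshoot) but must be finite whenever the corresponding validity
    code is 0.
    """

    t: float
    left_x: float
    left_y: float
    right_x: float
    right_y: float
    valid_left: int = 0
    valid_right: int = 0


@dataclass
class GazeRecording:
    """A tracker's full session for one subject.

    ``samples`` is a DataFrame with the ``GAZE_COLUMNS`` schema, strictly
    increasing in ``t``.
    """

    subject_id: str
    tracker_id: str
    nominal_rate: float
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.nominal_rate <= 0:
            raise DataError("nominal_rate must be > 0")
        missing = [c for c in GAZE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise FormatError(f"gaze samples missing column(s): {', '.join(missing)}")
        self.samples = self.samples[GAZE_COLUMNS].reset_index(drop=True)
        _check_samples(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def iter_samples(self) -> Iterable[GazeSample]:
        for row in self.samples.itertuples(index=False):
            yield GazeSample(
                row.t, row.left_x, row.left_y, row.right_x, row.right_y,
                int(row.valid_left), int(row.valid_right),
            )

    @classmethod
    def from_samples(
        cls, subject_id: str, tracker_id: str, nominal_rate: float,
        samples: Iterable[GazeSample],
    ) -> "GazeRecording":
        df = pd.DataFrame([dataclasses.asdict(s) for s in samples], columns=GAZE_COLUMNS)
        return cls(subject_id, tracker_id, nominal_rate, df)


def _check_samples(df: pd.DataFrame) -> None:
    t = df["t"].to_numpy(float)
    if len(t) and t[0] < 0:
        raise DataError("sample times must be non-negative")
    if len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise DataError(f"timestamps not strictly increasing at row {bad[0] + 1}")
    for code_col in ("valid_left", "valid_right"):
        codes = df[code_col].to_numpy()
        if np.any(codes < 0):
            raise DataError(f"{code_col} contains negative validity codes")
    # A sample flagged valid on an eye must carry finite coordinates for it.
    for eye in ("left", "right"):
        valid = df[f"valid_{eye}"].to_numpy() == 0
        coords = df[[f"{eye}_x", f"{eye}_y"]].to_numpy(float)
        bad = valid & ~np.isfinite(coords).all(axis=1)
        if bad.any():
            raise DataError(
                f"row {int(np.flatnonzero(bad)[0])}: non-finite {eye}-eye "
                "coordinates on a sample with validity 0"
            )


@dataclass
class EventLog:
    """Oddball trial schedule; ``trials`` follows the ``EVENT_COLUMNS`` schema."""

    trials: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.trials.columns]
        if missing:
            raise FormatError(f"event log missing column(s): {', '.join(missing)}")
        df = self.trials[EVENT_COLUMNS].reset_index(drop=True).copy()
        df["condition"] = df["condition"].astype(str).str.strip().str.lower()
        unknown = sorted(set(df["condition"]) - set(CONDITIONS))
        if unknown:
            raise FormatError(f"unknown condition label(s): {', '.join(unknown)}")
        df["trial_index"] = df["trial_index"].astype(int)
        for col in ("mask_onset", "stimulus_onset", "mask_duration", "stimulus_duration"):
            df[col] = df[col].astype(float)
        df["stimulus_string"] = df["stimulus_string"].astype(str)
        idx = df["trial_index"].to_numpy(int)
        if not np.array_equal(idx, np.arange(1, len(df) + 1)):
            raise DataError("trial_index must be contiguous starting at 1")
        onset_err = np.abs(
            df["stimulus_onset"].to_numpy(float)
            - df["mask_onset"].to_numpy(float)
            - df["mask_duration"].to_numpy(float)
        )
        if len(df) and onset_err.max() > 1e-6:
            raise DataError("stimulus_onset must equal mask_onset + mask_duration")
        lengths = df["stimulus_string"].astype(str).str.len()
        if len(df) and lengths.nunique() != 1:
            raise DataError("stimulus_string length must be fixed within a session")
        self.trials = df

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_targets(self) -> int:
        return int((self.trials["condition"] == "target").sum())

    @property
    def n_distractors(self) -> int:
        return int((self.trials["condition"] == "distractor").sum())


@dataclass
class GeometryConfig:
    """Viewing geometry linking screen pixels to visual angles.

    Defaults describe the study setup: a 15.6-inch 16:9 HD laptop panel
    (1366 x 768 px, 345.2 x 194.2 mm) viewed from ~500 mm, with the
    population-average interocular distance of 63 mm.  All lengths in mm.
    """

    viewing_distance: float = 500.0
    screen_w_px: int = 1366
    screen_h_px: int = 768
    screen_w_mm: float = 345.2
    screen_h_mm: float = 194.2
    ipd: float = 63.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise DataError(f"geometry field {f.name} must be strictly positive")

    @property
    def px_per_mm(self) -> float:
        return self.screen_w_px / self.screen_w_mm

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeometryConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


# ---------------------------------------------------------------------------
# readers / writers

def read_gaze_csv(path: str | Path, tracker_id: str, subject_id: str = "",
                  nominal_rate: float = 30.0) -> GazeRecording:
    """Read a gaze CSV into a :class:`GazeRecording`.

    Raises :class:`FormatError` naming any missing column and
    :class:`DataError` (with the first offending row) on non-monotone
    timestamps or on valid-flagged rows with non-numeric coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s): {', '.join(missing)}")
    for col in GAZE_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df[["t", "valid_left", "valid_right"]].isna().any().any():
        raise DataError(f"{path.name}: non-numeric time or validity field")
    df["valid_left"] = df["valid_left"].astype(int)
    df["valid_right"] = df["valid_right"].astype(int)
    return GazeRecording(subject_id or path.stem, tracker_id, nominal_rate, df)


def write_gaze_csv(recording: GazeRecording, path: str | Path) -> None:
    """Write a recording to CSV, preserving reals to at least 6 significant digits."""
    recording.samples.to_csv(Path(path), index=False, float_format="%.10g")


def read_event_log(path: str | Path) -> EventLog:
    """Read an events CSV; conditions are normalised to lower case."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"stimulus_string": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s): {', '.join(missing)}")
    return EventLog(df)


def write_event_log(events: EventLog, path: str | Path) -> None:
    events.trials.to_csv(Path(path), index=False, float_format="%.10g")


def read_geometry_yaml(path: str | Path) -> GeometryConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return GeometryConfig.from_dict(doc.get("geometry", doc))


def write_geometry_yaml(geometry: GeometryConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"geometry": geometry.to_dict()}, fh, sort_keys=False)
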