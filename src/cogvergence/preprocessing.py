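"""Trial segmentation, validity-based exclusion, and resampling.

Raw tracker streams are cut into per-trial epochs time-locked to
stimulus onset.  A sample is invalid whenever *either* eye's validity
code is non-zero (vergence needs both eyes).  Trials accumulating 15 or
more invalid samples inside the epoch window are discarded; retained
trials are linearly interpolated (invalid samples removed first) onto an
evenly spaced grid at the tracker's nominal rate, with end values
clamped to the nearest valid sample so no extrapolation slope is ever
applied.

Webcam-style recordings carry validity 0 everywhere, so the exclusion
rule never fires on them; it can also be switched off wholesale with
``apply_exclusion=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .gaze_io import EventLog, GazeRecording, GeometryConfig
from .vergence import GRID_TOL, gamma_from_gaze

#: invalid samples per epoch at or above which a trial is discarded
EXCLUSION_THRESHOLD = 15

#: default epoch bounds (ms) relative to stimulus onset; the pre-stimulus
#: 200 ms supports baseline inspection, the 2000 ms covers the stimulus.
DEFAULT_EPOCH_WINDOW = (-200.0, 2000.0)

COORD_CHANNELS = ("left_x", "left_y", "right_x", "right_y")


@dataclass
class RawTrialSlice:
    """All raw samples of one trial's epoch window, times relative to onset."""

    trial_index: int
    condition: str
    stimulus_onset: float
    samples: pd.DataFrame        # gaze columns plus t_rel
    truncated: bool = False


@dataclass
class TrialEpoch:
    """One trial's vergence series on a uniform grid relative to stimulus onset."""

    subject_id: str
    tracker_id: str
    trial_index: int
    condition: str
    t_rel: np.ndarray
    gamma: np.ndarray
    n_invalid: int
    excluded: bool
    reason: str = ""


def uniform_grid(epoch_window: tuple[float, float], rate: float) -> np.ndarray:
    """Grid start, start+step, ... covering [start, end) at ``rate`` Hz."""
    start, end = epoch_window
    step = 1000.0 / rate
    n = int(np.floor((end - start) / step - GRID_TOL)) + 1
    return start + step * np.arange(n)


def segment_trials(
    recording: GazeRecording,
    events: EventLog,
    epoch_window: tuple[float, float] = DEFAULT_EPOCH_WINDOW,
) -> list[RawTrialSlice]:
    """Slice the recording into per-trial epochs, one slice per event.

    A slice holds every sample with onset+start <= t < onset+end; slices
    whose window runs past the end of the recording are flagged truncated.
    """
    start, end = epoch_window
    if start >= end:
        raise DataError("epoch_window start must precede end")
    t = recording.samples["t"].to_numpy(float)
    t_max = t[-1] if len(t) else -np.inf
    out: list[RawTrialSlice] = []
    for row in events.trials.itertuples(index=False):
        onset = float(row.stimulus_onset)
        lo, hi = onset + start, onset + end
        sel = (t >= lo - GRID_TOL) & (t < hi - GRID_TOL)
        sl = recording.samples.loc[sel].copy()
        sl["t_rel"] = sl["t"] - onset
        out.append(
            RawTrialSlice(
                int(row.trial_index), str(row.condition), onset, sl,
                truncated=bool(hi - GRID_TOL > t_max + 1000.0 / recording.nominal_rate),
            )
        )
    return out


def count_invalid(samples: pd.DataFrame) -> int:
    """Samples invalid on either eye (union, not per-eye sum)."""
    bad = (samples["valid_left"].to_numpy() != 0) | (samples["valid_right"].to_numpy() != 0)
    return int(bad.sum())


def exclude_trial(n_invalid: int, threshold: int = EXCLUSION_THRESHOLD) -> bool:
    """True iff the trial accumulates ``threshold`` or more invalid samples."""
    if n_invalid < 0:
        raise DataError("n_invalid must be non-negative")
    return n_invalid >= threshold


def interpolate_uniform(
    samples: pd.DataFrame,
    rate: float,
    epoch_window: tuple[float, float] = DEFAULT_EPOCH_WINDOW,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Resample the valid samples of one slice onto the uniform epoch grid.

    Returns ``(t_rel grid, {channel: values})`` for the four coordinate
    channels.  Grid points outside the span of valid timestamps take the
    nearest valid value.  Raises :class:`DataError` with reason
    "insufficient data" when fewer than two valid samples remain.
    """
    valid = (samples["valid_left"].to_numpy() == 0) & (samples["valid_right"].to_numpy() == 0)
    if valid.sum() < 2:
        raise DataError("insufficient data")
    t_val = samples["t_rel"].to_numpy(float)[valid]
    grid = uniform_grid(epoch_window, rate)
    channels = {
        ch: np.interp(grid, t_val, samples[ch].to_numpy(float)[valid])
        for ch in COORD_CHANNELS
    }
    return grid, channels


def build_epochs(
    recording: GazeRecording,
    events: EventLog,
    geometry: GeometryConfig,
    epoch_window: tuple[float, float] = DEFAULT_EPOCH_WINDOW,
    threshold: int = EXCLUSION_THRESHOLD,
    apply_exclusion: bool = True,
) -> list[TrialEpoch]:
    """Segment, QC and resample a whole recording into vergence epochs.

    Every event yields exactly one epoch; excluded epochs carry a reason
    ("no data", "insufficient data", or "invalid samples >= threshold")
    and an empty gamma series.
    """
    grid = uniform_grid(epoch_window, recording.nominal_rate)
    epochs: list[TrialEpoch] = []
    for sl in segment_trials(recording, events, epoch_window):
        n_invalid = count_invalid(sl.samples)
        common = dict(
            subject_id=recording.subject_id, tracker_id=recording.tracker_id,
            trial_index=sl.trial_index, condition=sl.condition,
        )
        if len(sl.samples) == 0:
            epochs.append(TrialEpoch(**common, t_rel=grid, gamma=np.full_like(grid, np.nan),
                                     n_invalid=n_invalid, excluded=True, reason="no data"))
            continue
        if apply_exclusion and exclude_trial(n_invalid, threshold):
            epochs.append(TrialEpoch(**common, t_rel=grid, gamma=np.full_like(grid, np.nan),
                                     n_invalid=n_invalid, excluded=True,
                                     reason=f"invalid samples >= {threshold}"))
            continue
        try:
            t_rel, ch = interpolate_uniform(sl.samples, recording.nominal_rate, epoch_window)
        except DataError as exc:
            epochs.append(TrialEpoch(**common, t_rel=grid, gamma=np.full_like(grid, np.nan),
                                     n_invalid=n_invalid, excluded=True, reason=str(exc)))
            continue
        gamma = gamma_from_gaze(ch["left_x"], ch["right_x"], geometry)
        epochs.append(TrialEpoch(**common, t_rel=t_rel, gamma=gamma,
                                 n_invalid=n_invalid, excluded=False))
    return epochs


def exclusion_rate(epochs: Sequence[TrialEpoch]) -> float:
    """Fraction of epochs flagged excluded, in [0, 1]."""
    if not epochs:
        raise DataError("exclusion_rate of an empty epoch sequence is undefined")
    return sum(e.excluded for e in epochs) / len(epochs)


def qc_table(epochs: Sequence[TrialEpoch]) -> pd.DataFrame:
    """Per-trial QC record: subject, tracker, trial, n_invalid, excluded, reason."""
    return pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in epochs],
            "tracker_id": [e.tracker_id for e in epochs],
            "trial_index": [e.trial_index for e in epochs],
            "condition": [e.condition for e in epochs],
            "n_invalid": [e.n_invalid for e in epochs],
            "excluded": [e.excluded for e in epochs],
            "reason": [e.reason for e in epochs],
        }
    )
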