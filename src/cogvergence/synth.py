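"""Seedable simulator of oddball sessions and binocular gaze recordings.

The generator produces data with the statistical structure the analysis
assumes, so that every pipeline stage is testable end to end:

* an oddball schedule of 100 trials per session — 2000 ms gray mask,
  2000 ms 11-character letter-string stimulus, exactly 20% targets in a
  seeded random order;
* a per-trial vergence response: a transient convergence starting
  ~300 ms after stimulus onset, peaking ~450 ms, relaxing onto a
  sustained component that persists through 1250 ms — larger for
  targets than distractors, scaled per subject by a log-normal
  amplitude factor;
* tracker front-ends that invert the binocular viewing geometry into
  per-eye on-screen gaze coordinates, add per-eye Gaussian sample noise,
  and (for the infrared-like tracker) drop samples at random by marking
  them invalid, reproducing realistic trial-exclusion rates.

Everything is driven by a single integer seed; a fixed seed reproduces
a cohort bit for bit.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .gaze_io import (
    EVENT_COLUMNS,
    GAZE_COLUMNS,
    EventLog,
    GazeRecording,
    GeometryConfig,
    write_event_log,
    write_gaze_csv,
)

#: random letter strings are re-drawn if they spell one of these
WORD_BLACKLIST = frozenset({
    "information", "development", "environment", "temperatures", "performance",
    "approximate", "explanation", "measurement", "convergence",
})

#: code written into the validity columns of dropped samples
INVALID_CODE = 4


@dataclass(frozen=True)
class ResponseKernel:
    """Parametric event-locked vergence increment over baseline (deg).

    Zero before ``latency``; raised-cosine rise to ``peak_amp`` at
    ``peak_time``; exponential relaxation (time constant ``decay``)
    toward the sustained ``delay_amp``, held through ``sustain_end``;
    afterwards the same relaxation carries the response back to zero.
    Continuous everywhere.
    """

    latency: float = 300.0
    peak_time: float = 450.0
    peak_amp: float = 0.3
    delay_amp: float = 0.12
    decay: float = 80.0
    sustain_end: float = 1250.0

    def __post_init__(self) -> None:
        if not self.latency < self.peak_time:
            raise ParameterError("kernel latency must precede peak_time")
        if self.peak_amp < 0 or self.delay_amp < 0:
            raise ParameterError("kernel amplitudes must be >= 0")
        if self.decay <= 0:
            raise ParameterError("kernel decay must be > 0")


@dataclass(frozen=True)
class TrackerSpec:
    """Noise model of one tracker front-end."""

    rate: float = 30.0          # Hz
    noise_sd: float = 0.05      # per-eye, per-sample gaze noise (deg)
    dropout_prob: float = 0.0   # per-sample probability of an invalid flag

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ParameterError("tracker rate must be > 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ParameterError("dropout_prob must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def default_trackers() -> dict[str, TrackerSpec]:
    """Infrared-like ("ET") and webcam-like ("WC") tracker defaults.

    ET: low sample noise but random pupil-detection dropouts at a rate
    that discards roughly a third of trials under the 15-invalid-sample
    rule.  WC: no dropouts, but three times the sample noise.
    """
    return {
        "ET": TrackerSpec(rate=30.0, noise_sd=0.05, dropout_prob=0.2),
        "WC": TrackerSpec(rate=30.0, noise_sd=0.15, dropout_prob=0.0),
    }


@dataclass
class SimulationParams:
    """Cohort-level study design and noise parameters."""

    n_subjects: int = 28
    n_trials: int = 100
    p_target: float = 0.20
    mask_ms: float = 2000.0
    stim_ms: float = 2000.0
    string_len: int = 11
    target_kernel: ResponseKernel = field(
        default_factory=lambda: ResponseKernel(peak_amp=0.3, delay_amp=0.12))
    distractor_kernel: ResponseKernel = field(
        default_factory=lambda: ResponseKernel(peak_amp=0.05, delay_amp=0.02))
    subject_sd: float = 0.5     # sigma of the log-normal amplitude factor
    trackers: dict[str, TrackerSpec] = field(default_factory=default_trackers)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_target < 1.0:
            raise ParameterError("p_target must lie strictly between 0 and 1")
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ParameterError("n_subjects and n_trials must be >= 1")
        if self.subject_sd < 0:
            raise ParameterError("subject_sd must be >= 0")


@dataclass
class CohortData:
    """A simulated cohort: shared-per-subject event logs, paired recordings,
    and the ground-truth amplitude table for parameter-recovery tests."""

    params: SimulationParams
    geometry: GeometryConfig
    events: dict[str, EventLog]                      # subject_id -> log
    recordings: dict[tuple[str, str], GazeRecording]  # (subject_id, tracker_id)
    ground_truth: pd.DataFrame

    @property
    def subject_ids(self) -> list[str]:
        return list(self.events)


def generate_paradigm(
    n_trials: int = 100,
    p_target: float = 0.20,
    mask_ms: float = 2000.0,
    stim_ms: float = 2000.0,
    string_len: int = 11,
    seed: int | np.random.Generator = 0,
) -> EventLog:
    """Build one oddball session schedule.

    Exactly ``round(n_trials * p_target)`` trials are targets, placed by
    a seeded shuffle; stimulus strings are random mixed-case letters,
    re-drawn if they spell a blacklisted English word.
    """
    if not 0.0 < p_target < 1.0:
        raise ParameterError("p_target must lie strictly between 0 and 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_target = int(round(n_trials * p_target))
    conditions = np.array(["distractor"] * (n_trials - n_target) + ["target"] * n_target)
    rng.shuffle(conditions)
    letters = np.array(list(string.ascii_letters))
    strings = []
    for _ in range(n_trials):
        while True:
            s = "".join(rng.choice(letters, size=string_len))
            if s.lower() not in WORD_BLACKLIST:
                break
        strings.append(s)
    trial_start = np.arange(n_trials) * (mask_ms + stim_ms)
    df = pd.DataFrame(
        {
            "trial_index": np.arange(1, n_trials + 1),
            "condition": conditions,
            "mask_onset": trial_start,
            "stimulus_onset": trial_start + mask_ms,
            "mask_duration": mask_ms,
            "stimulus_duration": stim_ms,
            "stimulus_string": strings,
        },
        columns=EVENT_COLUMNS,
    )
    return EventLog(df)


def kernel_curve(kernel: ResponseKernel, t_rel: np.ndarray) -> np.ndarray:
    """Evaluate the response kernel on a time grid (ms -> deg increment)."""
    t = np.asarray(t_rel, float)
    out = np.zeros_like(t)

    rise = (t >= kernel.latency) & (t <= kernel.peak_time)
    phase = (t[rise] - kernel.latency) / (kernel.peak_time - kernel.latency)
    out[rise] = kernel.peak_amp * 0.5 * (1.0 - np.cos(np.pi * phase))

    fall = (t > kernel.peak_time) & (t <= kernel.sustain_end)
    out[fall] = kernel.delay_amp + (kernel.peak_amp - kernel.delay_amp) * np.exp(
        -(t[fall] - kernel.peak_time) / kernel.decay
    )

    tail = t > kernel.sustain_end
    at_end = kernel.delay_amp + (kernel.peak_amp - kernel.delay_amp) * np.exp(
        -(kernel.sustain_end - kernel.peak_time) / kernel.decay
    )
    out[tail] = at_end * np.exp(-(t[tail] - kernel.sustain_end) / kernel.decay)
    return out


def _gamma_to_screen_x(gamma_deg: np.ndarray, geometry: GeometryConfig
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Invert the binocular geometry: vergence angle -> per-eye screen x (px).

    The simulated observer fixates a point on the screen-centre normal
    whose depth d satisfies gamma = 2 atan(ipd / 2d); the line of sight
    of each eye is intersected with the screen plane.
    """
    half = geometry.ipd / 2.0
    d = half / np.tan(np.radians(gamma_deg) / 2.0)
    x_mm = half * (geometry.viewing_distance / d - 1.0)   # left eye; right is -x_mm
    left_px = x_mm * geometry.px_per_mm + geometry.screen_w_px / 2.0
    right_px = -x_mm * geometry.px_per_mm + geometry.screen_w_px / 2.0
    return left_px, right_px


def simulate_subject(
    params: SimulationParams,
    subject_id: str,
    tracker_id: str,
    geometry: GeometryConfig,
    seed: int | np.random.SeedSequence,
    events: EventLog | None = None,
    amp_factor: float | None = None,
) -> tuple[GazeRecording, EventLog]:
    """Simulate one subject's session as seen by one tracker.

    The subject fixates the screen centre; each trial adds the
    condition's response kernel (scaled by the subject's amplitude
    factor) to the baseline vergence.  The resulting gamma(t) is
    inverted through the viewing geometry into per-eye gaze coordinates,
    Gaussian per-eye noise of ``noise_sd`` degrees (converted to pixels
    through the geometry) is added, and samples are dropped at
    ``dropout_prob`` by flagging both eyes invalid and blanking the
    coordinates.
    """
    if tracker_id not in params.trackers:
        raise ParameterError(f"unknown tracker {tracker_id!r}")
    spec = params.trackers[tracker_id]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_events, rng_subject, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3))
    if events is None:
        events = generate_paradigm(
            params.n_trials, params.p_target, params.mask_ms, params.stim_ms,
            params.string_len, rng_events,
        )
    if amp_factor is None:
        amp_factor = float(np.exp(rng_subject.normal(0.0, params.subject_sd)))

    step = 1000.0 / spec.rate
    session_ms = params.n_trials * (params.mask_ms + params.stim_ms)
    t = np.arange(int(np.floor(session_ms / step))) * step

    gamma_base = np.degrees(2.0 * np.arctan(geometry.ipd / (2.0 * geometry.viewing_distance)))
    gamma = np.full_like(t, gamma_base)
    kernels = {"target": params.target_kernel, "distractor": params.distractor_kernel}
    for row in events.trials.itertuples(index=False):
        onset = float(row.stimulus_onset)
        k = kernels[str(row.condition)]
        lo = np.searchsorted(t, onset + k.latency - 1e-9)
        hi = np.searchsorted(t, onset + params.stim_ms + 1e-9)
        gamma[lo:hi] += amp_factor * kernel_curve(k, t[lo:hi] - onset)

    left_px, right_px = _gamma_to_screen_x(gamma, geometry)
    center_y = geometry.screen_h_px / 2.0

    # degrees of gaze noise mapped to on-screen pixels at the viewing distance
    noise_px = (
        np.tan(np.radians(spec.noise_sd)) * geometry.viewing_distance * geometry.px_per_mm
    )
    n = len(t)
    left_x = left_px + rng_noise.normal(0.0, noise_px, n)
    right_x = right_px + rng_noise.normal(0.0, noise_px, n)
    left_y = center_y + rng_noise.normal(0.0, noise_px, n)
    right_y = center_y + rng_noise.normal(0.0, noise_px, n)

    valid = np.zeros(n, int)
    if spec.dropout_prob > 0:
        dropped = rng_noise.random(n) < spec.dropout_prob
        valid[dropped] = INVALID_CODE
        for arr in (left_x, left_y, right_x, right_y):
            arr[dropped] = np.nan

    df = pd.DataFrame(
        {
            "t": t,
            "left_x": left_x, "left_y": left_y,
            "right_x": right_x, "right_y": right_y,
            "valid_left": valid, "valid_right": valid,
        },
        columns=GAZE_COLUMNS,
    )
    return GazeRecording(subject_id, tracker_id, spec.rate, df), events


def simulate_cohort(
    params: SimulationParams, geometry: GeometryConfig | None = None
) -> CohortData:
    """Simulate the full cohort: each subject recorded by every tracker
    against one shared event log, plus a ground-truth amplitude table."""
    geometry = geometry or GeometryConfig()
    root = np.random.SeedSequence(params.seed)
    events: dict[str, EventLog] = {}
    recordings: dict[tuple[str, str], GazeRecording] = {}
    truth_rows = []
    for i, subj_ss in enumerate(root.spawn(params.n_subjects), start=1):
        subject_id = f"sub-{i:02d}"
        event_ss, amp_ss, *tracker_ss = subj_ss.spawn(2 + len(params.trackers))
        log = generate_paradigm(
            params.n_trials, params.p_target, params.mask_ms, params.stim_ms,
            params.string_len, np.random.default_rng(event_ss),
        )
        amp = float(np.exp(np.random.default_rng(amp_ss).normal(0.0, params.subject_sd)))
        events[subject_id] = log
        for (tracker_id, spec), t_ss in zip(params.trackers.items(), tracker_ss):
            rec, _ = simulate_subject(
                params, subject_id, tracker_id, geometry, t_ss,
                events=log, amp_factor=amp,
            )
            recordings[(subject_id, tracker_id)] = rec
        truth_rows.append(
            {
                "subject_id": subject_id,
                "amp_factor": amp,
                "target_peak_amp": amp * params.target_kernel.peak_amp,
                "distractor_peak_amp": amp * params.distractor_kernel.peak_amp,
            }
        )
    return CohortData(params, geometry, events, recordings, pd.DataFrame(truth_rows))


def write_cohort(cohort: CohortData, outdir: str | Path) -> Path:
    """Write a cohort as a directory tree of gaze/event CSVs plus
    ground_truth.csv and a manifest recording the full parameter set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for subject_id in cohort.subject_ids:
        sdir = outdir / subject_id
        sdir.mkdir(exist_ok=True)
        write_event_log(cohort.events[subject_id], sdir / "events.csv")
        for tracker_id in cohort.params.trackers:
            write_gaze_csv(
                cohort.recordings[(subject_id, tracker_id)],
                sdir / f"gaze_{tracker_id}.csv",
            )
    cohort.ground_truth.to_csv(outdir / "ground_truth.csv", index=False, float_format="%.10g")
    manifest = {
        "seed": cohort.params.seed,
        "n_subjects": cohort.params.n_subjects,
        "n_trials": cohort.params.n_trials,
        "p_target": cohort.params.p_target,
        "trackers": {
            tid: {"rate": s.rate, "noise_sd": s.noise_sd, "dropout_prob": s.dropout_prob}
            for tid, s in cohort.params.trackers.items()
        },
        "geometry": cohort.geometry.to_dict(),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir
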