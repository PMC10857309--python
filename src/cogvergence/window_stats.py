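"""Windowed response measures, modulation indices, and group comparisons.

Response strength is summarised as the mean of V(t) over fixed
post-onset windows: the *initial* response 0-200 ms, the *peak*
response 400-433 ms, and the *delay* response 600-1250 ms.  The
target/distractor contrast is condensed per subject into the modulation
index

    mi = (T - D) / (T + D) ,

where T (D) is the mean over target (distractor) trials of the
trial-wise V mean in the 300-600 ms window.  mi is positive when the
target response is stronger, scale-invariant, and unbounded as
T + D -> 0 — observed |mi| values above 1 are therefore expected, not
errors.  When |T + D| is numerically zero the index is undefined and
propagated as NaN.

Windows are closed intervals intersected with the sample grid; at 30 Hz
the 33-ms-wide peak window can contain a single grid point, which is
legitimate (the window width equals one sampling interval).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DataError, WindowError
from .vergence import ModulationCurve, window_mask

log = logging.getLogger(__name__)

WINDOW_NAMES = ("initial", "peak", "delay")


@dataclass(frozen=True)
class WindowDefinition:
    """Analysis windows (ms, relative to stimulus onset, closed intervals)."""

    initial: tuple[float, float] = (0.0, 200.0)
    peak: tuple[float, float] = (400.0, 433.0)
    delay: tuple[float, float] = (600.0, 1250.0)
    mi_window: tuple[float, float] = (300.0, 600.0)

    def __post_init__(self) -> None:
        for name in (*WINDOW_NAMES, "mi_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise DataError(f"window {name} must satisfy start < end")

    def named(self) -> dict[str, tuple[float, float]]:
        return {name: getattr(self, name) for name in WINDOW_NAMES}


@dataclass
class SubjectSummary:
    """Per-subject, per-tracker windowed response summary.

    ``window_means[condition][window]`` and ``window_sds`` hold the mean
    and across-trial SD of trial-wise window means; T, D and mi follow
    the modulation-index definition.  ``mi`` is NaN when undefined, with
    the cause in ``reason``.
    """

    subject_id: str
    tracker_id: str
    n_target: int
    n_distractor: int
    window_means: dict = field(default_factory=dict)
    window_sds: dict = field(default_factory=dict)
    T: float = math.nan
    D: float = math.nan
    mi: float = math.nan
    reason: str = ""


def window_mean(curve: ModulationCurve, window: tuple[float, float]) -> float:
    """Arithmetic mean of v over grid points with start <= t <= end."""
    mask = window_mask(curve.t_rel, window)
    if not mask.any():
        raise WindowError(f"window {window} contains no grid point")
    return float(curve.v[mask].mean())


def modulation_index(T: float, D: float) -> float:
    """(T - D)/(T + D); NaN (with a logged warning) when T + D is ~0."""
    if abs(T + D) < 1e-12:
        log.warning("modulation index undefined: T + D = %.3g", T + D)
        return math.nan
    return (T - D) / (T + D)


def subject_modulation_index(
    target_curves: Sequence[ModulationCurve],
    distractor_curves: Sequence[ModulationCurve],
    windows: WindowDefinition = WindowDefinition(),
) -> SubjectSummary:
    """Summarise one subject/tracker from its retained single-trial curves."""
    ref = (list(target_curves) + list(distractor_curves) or [None])[0]
    summary = SubjectSummary(
        subject_id=getattr(ref, "subject_id", ""),
        tracker_id=getattr(ref, "tracker_id", ""),
        n_target=len(target_curves),
        n_distractor=len(distractor_curves),
    )
    by_cond = {"target": target_curves, "distractor": distractor_curves}
    for cond, curves in by_cond.items():
        summary.window_means[cond] = {}
        summary.window_sds[cond] = {}
        for name, win in windows.named().items():
            vals = np.array([window_mean(c, win) for c in curves])
            summary.window_means[cond][name] = float(vals.mean()) if len(vals) else math.nan
            summary.window_sds[cond][name] = float(vals.std(ddof=1)) if len(vals) > 1 else math.nan
    missing = [cond for cond, curves in by_cond.items() if not curves]
    if missing:
        summary.reason = f"no retained trials for condition(s): {', '.join(missing)}"
        return summary
    summary.T = float(np.mean([window_mean(c, windows.mi_window) for c in target_curves]))
    summary.D = float(np.mean([window_mean(c, windows.mi_window) for c in distractor_curves]))
    summary.mi = modulation_index(summary.T, summary.D)
    if math.isnan(summary.mi):
        summary.reason = "mi undefined (T + D ~ 0)"
    return summary


def response_slope(curve: ModulationCurve, window: tuple[float, float]) -> float:
    """OLS slope of curve values against time (per ms) over the window."""
    mask = window_mask(curve.t_rel, window)
    if mask.sum() < 2:
        raise WindowError(f"window {window} holds fewer than 2 grid points")
    res = stats.linregress(curve.t_rel[mask], curve.v[mask])
    return float(res.slope)


def two_tailed_t(
    a: Sequence[float], b: Sequence[float], paired: bool = False,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-tailed t-test; Welch by default for unpaired samples.

    Degenerate inputs (zero variance in both samples with equal means)
    return (0.0, 1.0) rather than NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each sample needs n >= 2")
    if paired:
        if len(a) != len(b):
            raise DataError("paired samples must have equal length")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t) and np.isclose(a.mean(), b.mean()):
        return 0.0, 1.0
    return t, p


@dataclass
class QuadrantCounts:
    """2x2 tally of per-subject modulation-index signs across two trackers."""

    both_positive: int = 0
    first_only: int = 0
    second_only: int = 0
    neither: int = 0
    n_missing: int = 0

    @property
    def n(self) -> int:
        return self.both_positive + self.first_only + self.second_only + self.neither

    def fraction_positive(self) -> tuple[float, float]:
        if self.n == 0:
            return math.nan, math.nan
        return (
            (self.both_positive + self.first_only) / self.n,
            (self.both_positive + self.second_only) / self.n,
        )


def sign_quadrant_counts(mi_pairs: Sequence[tuple[float, float]]) -> QuadrantCounts:
    """Classify (mi_tracker1, mi_tracker2) pairs by sign; zero counts as non-positive.

    Pairs with a NaN entry are tallied as missing and kept out of the 2x2
    table and the positive fractions.
    """
    out = QuadrantCounts()
    for m1, m2 in mi_pairs:
        if math.isnan(m1) or math.isnan(m2):
            out.n_missing += 1
        elif m1 > 0 and m2 > 0:
            out.both_positive += 1
        elif m1 > 0:
            out.first_only += 1
        elif m2 > 0:
            out.second_only += 1
        else:
            out.neither += 1
    return out
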