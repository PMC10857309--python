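"""Binocular geometry and the relative vergence modulation V(t).

The vergence angle gamma is the angle between the two lines of sight.
With the eyes at (+-ipd/2, 0) on the line normal to the screen centre and
azimuths measured in a common head-centred frame (positive = rightward),

    gamma = azimuth_left - azimuth_right ,

so that two eyes fixating a common near point give gamma > 0 and gamma
grows with convergence (nearer fixation).  For symmetric fixation at
distance d this reduces to the closed form gamma = 2*atan(ipd/(2 d)).

Because absolute vergence offsets differ across subjects and trackers,
the per-trial statistic of interest is the *relative vergence
modulation*

    V(t) = (gamma(t) - gamma_0) / max_w |gamma(t) - gamma_0| ,

where gamma_0 is the vergence at stimulus onset and the maximum runs
over the examined time window w of the trial.  V is dimensionless, zero
at onset, and reaches |V| = 1 somewhere in w on every non-flat trial.
Trial-wise V(t) curves are averaged within condition (target,
distractor) to give mean response curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError, DataError
from .gaze_io import GeometryConfig

#: tolerance (ms) when intersecting float time grids with window bounds
GRID_TOL = 1e-6


def gaze_to_azimuth(
    gaze_x: float | np.ndarray, eye_offset: float, geometry: GeometryConfig
) -> float | np.ndarray:
    """Horizontal gaze direction of one eye, in degrees.

    ``gaze_x`` is the on-screen gaze abscissa in pixels; ``eye_offset``
    the eye's signed horizontal position (mm) relative to the screen
    centre normal (left eye -ipd/2, right eye +ipd/2).  Positive azimuth
    is rightward in the common frame.
    """
    gaze_x = np.asarray(gaze_x, float)
    x_mm = (gaze_x - geometry.screen_w_px / 2.0) * geometry.screen_w_mm / geometry.screen_w_px
    az = np.degrees(np.arctan((x_mm - eye_offset) / geometry.viewing_distance))
    return az if az.ndim else float(az)


def vergence_angle(
    left_azimuth: float | np.ndarray, right_azimuth: float | np.ndarray
) -> float | np.ndarray:
    """gamma = left azimuth - right azimuth (degrees, convergence positive)."""
    out = np.asarray(left_azimuth, float) - np.asarray(right_azimuth, float)
    return out if out.ndim else float(out)


def gamma_from_gaze(
    left_x: np.ndarray, right_x: np.ndarray, geometry: GeometryConfig
) -> np.ndarray:
    """Vergence-angle series from the two eyes' on-screen gaze abscissae."""
    half = geometry.ipd / 2.0
    return vergence_angle(
        gaze_to_azimuth(left_x, -half, geometry),
        gaze_to_azimuth(right_x, +half, geometry),
    )


def symmetric_fixation_gamma(distance: float | np.ndarray, ipd: float) -> np.ndarray:
    """Closed-form gamma for both eyes fixating straight ahead at ``distance`` mm."""
    return np.degrees(2.0 * np.arctan(ipd / (2.0 * np.asarray(distance, float))))


@dataclass
class ModulationCurve:
    """A single-trial or condition-averaged V(t) curve.

    For averages, ``v`` is the pointwise mean of the member curves,
    ``gamma0`` / ``norm_max`` the means of the members' values, and
    ``n_trials`` the member count.
    """

    t_rel: np.ndarray
    v: np.ndarray
    gamma0: float
    norm_max: float
    condition: str
    n_trials: int = 1
    subject_id: str = ""
    tracker_id: str = ""
    trial_index: int = -1

    def __post_init__(self) -> None:
        self.t_rel = np.asarray(self.t_rel, float)
        self.v = np.asarray(self.v, float)
        if self.t_rel.shape != self.v.shape:
            raise AlignmentError("t_rel and v must have the same length")


def window_mask(t_rel: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Boolean mask of grid points inside the closed interval ``window``."""
    lo, hi = window
    return (t_rel >= lo - GRID_TOL) & (t_rel <= hi + GRID_TOL)


def relative_modulation(
    gamma: np.ndarray,
    t_rel: np.ndarray,
    onset_index: int,
    norm_window: tuple[float, float] = (0.0, 2000.0),
    **meta,
) -> ModulationCurve:
    """Normalise a trial's vergence series into V(t).

    gamma0 is the single sample at ``onset_index``; the normaliser is
    max |gamma - gamma0| over grid points inside ``norm_window``.  A
    perfectly flat trial (normaliser 0) yields V == 0 with norm_max
    recorded as 0, keeping the trial in condition averages.
    """
    gamma = np.asarray(gamma, float)
    t_rel = np.asarray(t_rel, float)
    mask = window_mask(t_rel, norm_window)
    if not mask.any():
        raise DataError("norm_window contains no grid point")
    if not np.isfinite(gamma[mask]).all():
        raise DataError("non-finite vergence inside the normalisation window")
    gamma0 = float(gamma[onset_index])
    d = gamma - gamma0
    norm_max = float(np.max(np.abs(d[mask])))
    v = np.zeros_like(d) if norm_max == 0.0 else d / norm_max
    return ModulationCurve(t_rel, v, gamma0, norm_max, meta.pop("condition", ""), 1, **meta)


def condition_average(curves: Sequence[ModulationCurve], condition: str) -> ModulationCurve:
    """Pointwise mean of same-condition single-trial curves sharing one grid."""
    if not curves:
        raise DataError("cannot average an empty set of curves")
    ref = curves[0]
    for c in curves:
        if c.condition != condition:
            raise DataError(f"curve condition {c.condition!r} != {condition!r}")
        if c.t_rel.shape != ref.t_rel.shape or np.max(np.abs(c.t_rel - ref.t_rel)) > GRID_TOL:
            raise AlignmentError("curves do not share a common time grid")
    n = sum(c.n_trials for c in curves)
    v = np.mean([c.v for c in curves], axis=0)
    return ModulationCurve(
        ref.t_rel.copy(), v,
        float(np.mean([c.gamma0 for c in curves])),
        float(np.mean([c.norm_max for c in curves])),
        condition, n,
        subject_id=ref.subject_id, tracker_id=ref.tracker_id,
    )


def delta_gamma(curve: ModulationCurve) -> np.ndarray:
    """Recover the unnormalised baseline-subtracted series gamma(t) - gamma0 (deg)."""
    return curve.v * curve.norm_max
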