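"""Fascicle kinematics: velocities, muscle length and windowed peak values.

Sign convention: fascicle *shortening* velocity is positive, so force-velocity
data populate the conventional descending Hill limb.  The iso-velocity window
is the angular phase (default 80 -> 50 deg knee flexion) shared by all
isokinetic speeds, located in time by linear interpolation of the knee-angle
crossings during extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamometry import TorqueTrace


class TrialError(ValueError):
    """The trial does not cover the requested analysis window."""


@dataclass
class FascicleTimeSeries:
    """Time-stamped fascicle length (mm) and pennation (deg) for one trial."""

    time: np.ndarray
    fascicle_length: np.ndarray
    pennation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fascicle_length = np.asarray(self.fascicle_length, dtype=float)
        if self.pennation is not None:
            self.pennation = np.asarray(self.pennation, dtype=float)
        if self.time.shape != self.fascicle_length.shape:
            raise ValueError("time and fascicle_length must have equal length")
        if np.any(np.diff(self.time) < 0):
            raise ValueError("time must be non-decreasing")
        if np.any(self.fascicle_length <= 0):
            raise ValueError("fascicle length must be positive throughout")


@dataclass
class IsoVelocityWindow:
    """Time window in which the dynamometer moves at its set speed."""

    start_angle: float
    end_angle: float
    start_time: float
    end_time: float


def fascicle_velocity(series: FascicleTimeSeries) -> np.ndarray:
    """Shortening velocity (mm/s, positive = shortening) by central difference.

    v(t_i) = -(L(t_{i+1}) - L(t_{i-1})) / (t_{i+1} - t_{i-1}); the first and
    last samples use one-sided differences.
    """
    t = series.time
    L = series.fascicle_length
    if t.size < 3:
        raise ValueError("central differences need at least three samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    v = np.empty_like(L)
    v[1:-1] = -(L[2:] - L[:-2]) / (t[2:] - t[:-2])
    v[0] = -(L[1] - L[0]) / (t[1] - t[0])
    v[-1] = -(L[-1] - L[-2]) / (t[-1] - t[-2])
    return v


def muscle_length(
    fascicle_length: np.ndarray | float, pennation_deg: np.ndarray | float
) -> np.ndarray | float:
    """Muscle-belly length along the line of action: Lm = Lf * cos(pennation)."""
    pen = np.asarray(pennation_deg, dtype=float)
    if np.any(pen < 0) or np.any(pen >= 90.0):
        raise ValueError("pennation must lie in [0, 90) degrees")
    out = np.asarray(fascicle_length, dtype=float) * np.cos(np.radians(pen))
    return out if out.shape else float(out)


def _first_downward_crossing(time: np.ndarray, angle: np.ndarray, level: float) -> float:
    """Time of the first downward (extension) crossing of an angle level."""
    a0, a1 = angle[:-1], angle[1:]
    hits = np.nonzero((a0 >= level) & (a1 < level))[0]
    if hits.size == 0:
        if np.any(np.isclose(angle, level)):
            idx = int(np.nonzero(np.isclose(angle, level))[0][0])
            return float(time[idx])
        raise TrialError(f"knee angle never crosses {level} deg during extension")
    i = int(hits[0])
    frac = (a0[i] - level) / (a0[i] - a1[i])
    return float(time[i] + frac * (time[i + 1] - time[i]))


def isovelocity_window(
    trace: TorqueTrace, start_angle: float = 80.0, end_angle: float = 50.0
) -> IsoVelocityWindow:
    """Locate the common iso-velocity phase (default 80 -> 50 deg flexion)."""
    t_start = _first_downward_crossing(trace.time, trace.angle, start_angle)
    t_end = _first_downward_crossing(trace.time, trace.angle, end_angle)
    if not t_end > t_start:
        raise TrialError("iso-velocity window has non-positive duration")
    return IsoVelocityWindow(start_angle, end_angle, t_start, t_end)


def peak_in_window(
    time: np.ndarray,
    force: np.ndarray,
    velocity: np.ndarray,
    window: IsoVelocityWindow,
) -> tuple[float, float]:
    """Peak force (N) and peak shortening velocity within the window.

    The two maxima are taken independently - they need not be simultaneous.
    """
    time = np.asarray(time, dtype=float)
    mask = (time >= window.start_time) & (time <= window.end_time)
    if not np.any(mask):
        raise TrialError("no samples fall inside the iso-velocity window")
    return float(np.max(np.asarray(force)[mask])), float(
        np.max(np.asarray(velocity)[mask])
    )


def resample_to(
    time_src: np.ndarray, values: np.ndarray, time_dst: np.ndarray
) -> np.ndarray:
    """Linear-interpolation resampling onto a shared (torque) timebase."""
    return np.interp(time_dst, np.asarray(time_src, float), np.asarray(values, float))
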