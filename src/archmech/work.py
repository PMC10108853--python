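"""Joint and muscle work over the common iso-velocity phase.

Joint work integrates torque over joint angle (trapezoid on the sampled
(angle, torque) pairs, angle in radians) across the 80 -> 50 deg window, with
the window endpoints obtained by linear interpolation at exactly the boundary
angles.  Muscle work integrates muscle force over muscle-length change (mm
converted to m) across the same time window.  Extension torque is positive
and work is positive during extension / shortening under tension.
"""

from __future__ import annotations

import numpy as np

from .dynamometry import TorqueTrace
from .kinematics import IsoVelocityWindow, TrialError


def _window_samples(
    time: np.ndarray, window: IsoVelocityWindow, *channels: np.ndarray
) -> list[np.ndarray]:
    """Samples strictly inside the window plus interpolated exact endpoints."""
    t0, t1 = window.start_time, window.end_time
    if t0 < time[0] - 1e-12 or t1 > time[-1] + 1e-12:
        raise TrialError("series does not cover the iso-velocity window")
    inner = (time > t0) & (time < t1)
    t_sel = np.concatenate([[t0], time[inner], [t1]])
    out = [t_sel]
    for ch in channels:
        ch = np.asarray(ch, dtype=float)
        out.append(np.concatenate([
            [np.interp(t0, time, ch)], ch[inner], [np.interp(t1, time, ch)]
        ]))
    return out


def joint_work(trace: TorqueTrace, window: IsoVelocityWindow) -> float:
    """Joint work (J): trapezoidal integral of torque over joint angle."""
    _, torque, angle = _window_samples(trace.time, window, trace.torque, trace.angle)
    theta = np.radians(angle)
    # angle decreases during extension; positive extension torque -> positive work
    return float(-np.trapezoid(torque, theta))


def muscle_work(
    time: np.ndarray,
    force: np.ndarray,
    muscle_length_mm: np.ndarray,
    window: IsoVelocityWindow,
) -> float:
    """Muscle work (J): trapezoidal integral of force over length change (m)."""
    time = np.asarray(time, dtype=float)
    force = np.asarray(force, dtype=float)
    muscle_length_mm = np.asarray(muscle_length_mm, dtype=float)
    if not (time.shape == force.shape == muscle_length_mm.shape):
        raise ValueError("time, force and muscle length series must be aligned")
    _, f_sel, l_sel = _window_samples(time, window, force, muscle_length_mm)
    length_m = l_sel * 1e-3
    # shortening (decreasing length) under tension -> positive work
    return float(-np.trapezoid(f_sel, length_m))
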