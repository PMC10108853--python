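"""Torque conditioning and conversion to knee-extension and muscle force.

The dynamometer records knee-extension torque against time and knee-flexion
angle (degrees, 0 = full extension).  Processing follows the standard chain
for isokinetic strength data: zero-phase low-pass filtering, subtraction of
the torque recorded during a passive movement (gravity + passive structures),
division by an angle-dependent moment arm to obtain knee-extension force, and
scaling by the muscle's PCSA fraction to obtain the force of a single
synergist (here the vastus lateralis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


class SignalError(ValueError):
    """Trace too short / malformed for the requested signal operation."""


class ModelError(ValueError):
    """Moment-arm or share model evaluated outside its valid domain."""


@dataclass
class TorqueTrace:
    """One dynamometer trial: time (s), knee-flexion angle (deg), torque (N m).

    ``mode`` is ``"isometric"``, ``"isokinetic"`` or ``"passive"``;
    ``nominal`` holds the target angle (deg) or speed (deg/s) of the trial.
    """

    time: np.ndarray
    angle: np.ndarray
    torque: np.ndarray
    mode: str = "isometric"
    nominal: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        if not (self.time.shape == self.angle.shape == self.torque.shape):
            raise ValueError("time, angle and torque must have equal length")
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("a trace needs at least two samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def peak_torque(self) -> float:
        return float(np.max(self.torque))


@dataclass
class MomentArmModel:
    """Knee-extension moment arm (m) as a polynomial in knee-flexion angle (deg).

    The default is a single-peaked quadratic smoothed over in vivo
    patellar-tendon moment-arm data (peak ~41 mm near 40 deg flexion,
    ~30 mm at deep flexion), positive over the whole 0-110 deg range of
    motion used in knee-extensor testing.
    """

    coefficients: tuple[float, ...] = (0.041, 40.0, -2.24e-6)
    valid_range: tuple[float, float] = (0.0, 110.0)

    # coefficients = (peak value m, peak angle deg, quadratic coefficient m/deg^2)

    def __call__(self, angle_deg: np.ndarray | float) -> np.ndarray | float:
        angle = np.asarray(angle_deg, dtype=float)
        lo, hi = self.valid_range
        if np.any(angle < lo - 1e-9) or np.any(angle > hi + 1e-9):
            raise ModelError(
                f"angle outside moment-arm validity range [{lo}, {hi}] deg"
            )
        peak, theta0, c2 = self.coefficients
        ma = peak + c2 * (angle - theta0) ** 2
        if np.any(ma <= 0):
            raise ModelError("moment arm model returned a non-positive value")
        return ma if ma.shape else float(ma)


@dataclass
class MuscleShareModel:
    """Fraction of knee-extension force attributed to one muscle (by PCSA).

    Default 0.35 for the vastus lateralis, the ratio implied by cohort means
    of VL fascicle force to knee-extension force (1856/5295 ~ 0.3506).
    """

    pcsa_share: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 < self.pcsa_share < 1.0:
            raise ValueError("pcsa_share must lie strictly in (0, 1)")


def filter_torque(trace: TorqueTrace, cutoff: float = 20.0, order: int = 2) -> TorqueTrace:
    """Zero-phase (forward-backward) Butterworth low-pass of the torque channel.

    Defaults: second order, 20 Hz cut-off.  Because the filter runs in both
    directions the effective magnitude response is |H|^2, i.e. gain 1/2 at
    the cut-off frequency.
    """
    fs = trace.sampling_rate
    if fs <= 2.0 * cutoff:
        raise SignalError(
            f"sampling rate {fs:.1f} Hz must exceed twice the {cutoff} Hz cutoff"
        )
    b, a = signal.butter(order, cutoff, btype="low", fs=fs)
    padlen = 3 * max(len(a), len(b))
    if trace.torque.size <= padlen:
        raise SignalError(
            f"trace of {trace.torque.size} samples shorter than filter warm-up ({padlen})"
        )
    filtered = signal.filtfilt(b, a, trace.torque, padtype="odd", padlen=padlen)
    return replace(trace, torque=filtered)


def correct_passive(active: TorqueTrace, passive: TorqueTrace) -> TorqueTrace:
    """Subtract the passive (gravity + passive-structure) torque, angle-matched.

    The passive trace is interpolated at the *angles* visited by the active
    trial (not time-matched), so the same recorded passive movement corrects
    isometric and isokinetic efforts alike.
    """
    order = np.argsort(passive.angle, kind="stable")
    pa = passive.angle[order]
    pt = passive.torque[order]
    # collapse duplicate angles (e.g. hold phases) to their mean torque
    ua, inv = np.unique(pa, return_inverse=True)
    if ua.size < pa.size:
        sums = np.bincount(inv, weights=pt)
        counts = np.bincount(inv)
        pa, pt = ua, sums / counts
    amin, amax = pa[0], pa[-1]
    eps = 1e-9
    if np.any(active.angle < amin - eps) or np.any(active.angle > amax + eps):
        raise ValueError(
            "active trial visits angles outside the passive trial's coverage "
            f"[{amin:.1f}, {amax:.1f}] deg"
        )
    corrected = active.torque - np.interp(active.angle, pa, pt)
    return replace(active, torque=corrected)


def knee_extension_force(
    torque: np.ndarray | float,
    angle: np.ndarray | float,
    ma: MomentArmModel,
) -> np.ndarray | float:
    """Knee-extension force (N) = torque / moment arm at the same angle."""
    return np.asarray(torque, dtype=float) / np.asarray(ma(angle), dtype=float)


def vastus_lateralis_force(
    knee_force: np.ndarray | float, share: MuscleShareModel
) -> np.ndarray | float:
    """Single-muscle force as the PCSA fraction of knee-extension force."""
    return share.pcsa_share * np.asarray(knee_force, dtype=float)


def select_best_attempt(trials: list[TorqueTrace]) -> TorqueTrace:
    """Return the attempt with the highest peak torque (ties: first attempt)."""
    if not trials:
        raise ValueError("select_best_attempt needs at least one trial")
    peaks = [t.peak_torque() for t in trials]
    return trials[int(np.argmax(peaks))]
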