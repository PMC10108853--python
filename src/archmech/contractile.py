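"""Hill-type force-length and force-velocity models and their fitting.

The force-length relation is a skewed bell,

    F(L) = force_max * exp(-| ((L/L0)^b - 1) / s |^rho),    rho = 2 by default,

with L0 the optimal fascicle length, b the skewness and s the width of the
curve.  The force-velocity relation is the classic Hill hyperbola written
with the dimensionless curvature G,

    F(v) = force_max * (1 - v/vmax) / (1 + G * v/vmax),

with force_max fixed from the force-length fit, vmax unconstrained (positive)
and G constrained to the physiological band 3 < G < 9.  Fits are plain
nonlinear least squares with fixed, data-driven starting values, so they are
deterministic given the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

G_BOUNDS = (3.0 + 1e-6, 9.0 - 1e-6)


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge or data are degenerate."""


@dataclass
class ForceLengthParams:
    force_max: float  # N
    L0: float         # mm
    b: float          # skewness (dimensionless)
    s: float          # width (dimensionless)
    rho: float = 2.0  # exponent on the normalised deviation

    def __post_init__(self) -> None:
        if self.force_max <= 0 or self.L0 <= 0 or self.s <= 0:
            raise ValueError("force_max, L0 and s must be positive")


@dataclass
class ForceVelocityParams:
    force_max: float  # N, carried over from the force-length fit
    vmax: float       # same units as the velocities fitted (L0/s in the pipeline)
    G: float          # curvature (dimensionless)
    at_bound: bool = False  # G landed on a box bound during fitting

    def __post_init__(self) -> None:
        if self.vmax <= 0:
            raise ValueError("vmax must be positive")


@dataclass
class ForceSummary:
    """Per-participant force parameters derived from both fitted curves."""

    force_max: float      # N, theoretical maximum (force-length fit)
    force_iso400: float   # N, measured peak force in the 400 deg/s trial
    G: float
    force_slope: float    # normalised force per unit velocity (L0/s in the pipeline)
    L0: float             # mm
    vmax: float           # L0/s in the pipeline


def eval_force_length(L: np.ndarray | float, p: ForceLengthParams) -> np.ndarray | float:
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("fascicle length must be positive")
    z = np.abs(((L / p.L0) ** p.b - 1.0) / p.s)
    out = p.force_max * np.exp(-(z**p.rho))
    return out if out.shape else float(out)


def fit_force_length(
    lengths: np.ndarray,
    forces: np.ndarray,
    init: ForceLengthParams | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    rho: float = 2.0,
) -> ForceLengthParams:
    """Least-squares fit of (force_max, L0, b, s) to (L, F) points.

    Initialisation is data-driven and fixed: L0 at the length of the largest
    observed force, force_max at 1.05x that force, b = 1, s = 0.5.
    """
    L = np.asarray(lengths, dtype=float)
    F = np.asarray(forces, dtype=float)
    if L.size != F.size:
        raise ValueError("length and force arrays must match")
    if L.size < 4:
        raise ValueError("need at least 4 (L, F) points for a 4-parameter fit")
    if init is None:
        imax = int(np.argmax(F))
        x0 = np.array([1.05 * F[imax], L[imax], 1.0, 0.5])
    else:
        x0 = np.array([init.force_max, init.L0, init.b, init.s])
    if bounds is None:
        lo = np.array([1e-6, 1e-6, 0.1, 1e-3])
        hi = np.array([np.inf, np.inf, 10.0, 10.0])
    else:
        lo, hi = bounds
    x0 = np.clip(x0, lo, hi)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = ForceLengthParams(*x, rho=rho)
        return eval_force_length(L, p) - F

    sol = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
    )
    if not sol.success:
        raise FitError(f"force-length fit did not converge: {sol.message}")
    return ForceLengthParams(*sol.x, rho=rho)


def eval_force_velocity(
    v: np.ndarray | float, p: ForceVelocityParams
) -> np.ndarray | float:
    v = np.asarray(v, dtype=float)
    if np.any(v < 0) or np.any(v > p.vmax):
        raise ValueError("velocity outside the fitted range [0, vmax]")
    x = v / p.vmax
    out = p.force_max * (1.0 - x) / (1.0 + p.G * x)
    return out if out.shape else float(out)


def fit_force_velocity(
    velocities: np.ndarray,
    forces: np.ndarray,
    force_max: float,
    init: tuple[float, float] | None = None,
) -> ForceVelocityParams:
    """Least-squares fit of (vmax, G) with force_max fixed.

    G is box-constrained to (3, 9); vmax is positive and otherwise free.
    A solution on a G bound is logged, not an error.
    """
    v = np.asarray(velocities, dtype=float)
    F = np.asarray(forces, dtype=float)
    if v.size != F.size or v.size < 2:
        raise ValueError("need at least 2 matched (v, F) points")
    if np.all(F >= force_max):
        raise FitError("all forces at or above force_max: no descending limb to fit")
    vmax0 = 2.0 * float(np.max(v)) if init is None else init[0]
    g0 = 6.0 if init is None else init[1]
    lo = np.array([float(np.max(v)) * (1 + 1e-9), G_BOUNDS[0]])
    hi = np.array([np.inf, G_BOUNDS[1]])
    x0 = np.clip(np.array([vmax0, g0]), lo, hi)

    def residuals(x: np.ndarray) -> np.ndarray:
        vmax, G = x
        xx = v / vmax
        return force_max * (1.0 - xx) / (1.0 + G * xx) - F

    sol = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
    )
    if not sol.success:
        raise FitError(f"force-velocity fit did not converge: {sol.message}")
    vmax, G = sol.x
    at_bound = bool(
        np.isclose(G, G_BOUNDS[0], atol=1e-9) or np.isclose(G, G_BOUNDS[1], atol=1e-9)
    )
    if at_bound:
        logger.warning("force-velocity curvature G landed on a bound: G = %.6f", G)
    return ForceVelocityParams(force_max=force_max, vmax=vmax, G=G, at_bound=at_bound)


def force_slope(
    fv: ForceVelocityParams, v_slow: float, v_fast: float
) -> float:
    """Normalised force drop per unit velocity between two fitted velocities.

    slope = (F(v_fast) - F(v_slow)) / force_max / (v_fast - v_slow); negative
    for the descending Hill limb.  Velocity units follow ``fv.vmax``.
    """
    if not v_slow < v_fast:
        raise ValueError("v_slow must be below v_fast")
    if v_fast > fv.vmax:
        raise ValueError("v_fast exceeds the fitted vmax; extrapolation refused")
    f_slow = eval_force_velocity(v_slow, fv) / fv.force_max
    f_fast = eval_force_velocity(v_fast, fv) / fv.force_max
    return float((f_fast - f_slow) / (v_fast - v_slow))


def summarise_forces(
    fl: ForceLengthParams,
    fv: ForceVelocityParams,
    peaks_by_speed: dict[float, tuple[float, float]],
) -> ForceSummary:
    """Assemble the per-participant force parameter set.

    ``peaks_by_speed`` maps isokinetic speed (deg/s) to the measured
    (peak velocity, peak force) pair; force_iso400 is the *measured* peak
    force of the fastest condition, while the slope uses the fitted curve at
    the measured slowest/fastest velocities.
    """
    speeds = sorted(peaks_by_speed)
    if not speeds:
        raise ValueError("no isokinetic peaks provided")
    fastest, slowest = speeds[-1], speeds[0]
    if fastest < 400.0 - 1e-9:
        raise ValueError("missing the 400 deg/s isokinetic trial")
    v_slow = peaks_by_speed[slowest][0]
    v_fast = peaks_by_speed[fastest][0]
    slope = force_slope(fv, v_slow, min(v_fast, fv.vmax * (1 - 1e-12)))
    return ForceSummary(
        force_max=fl.force_max,
        force_iso400=peaks_by_speed[fastest][1],
        G=fv.G,
        force_slope=slope,
        L0=fl.L0,
        vmax=fv.vmax,
    )
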