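"""Synthetic cohort of virtual participants with known muscle properties.

Each virtual participant owns a ground-truth Hill-type muscle (force-length
bell: force_max, L0, b, s; force-velocity hyperbola: vmax, G) plus the
architectural state linking knee angle to fascicle geometry.  The generator
then simulates every recording the analysis pipeline consumes:

* six isometric maximal efforts (100-50 deg knee flexion, 10 deg steps),
* five isokinetic extensions (50/100/200/300/400 deg/s over 110 -> 0 deg),
* one passive movement (gravity + passive torque),
* fascicle length / pennation time series synchronised with the torque,
* dual-probe and panoramic ultrasound scenes for the three architecture
  conditions (REST_0, REST_60, MVC_60).

Kinematic model.  Under full activation the fascicle length tracks knee
angle linearly, L(theta) = L0 * (1 + c*(theta - theta_opt)) with gearing
c = 0.008 L0/deg and the optimum crossed at theta_opt = 70 deg - inside the
80-50 deg iso-velocity window.  During an isokinetic extension the fascicle
therefore shortens at constant velocity c*L0*omega, and the simulated active
torque, force_max * f_L(L) * f_V(v) * moment_arm(theta), peaks exactly at L0
with that velocity: the measured (peak velocity, peak force) pairs lie on
the ground-truth force-velocity curve, closing the estimation loop.

Noise model.  Torque noise is white (electrical); fascicle length and
pennation noise is band-limited drift (white noise low-passed at
``noise_corner_hz``, rescaled to the requested sd), emulating the strongly
frame-to-frame correlated errors of ultrasound tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.stats import norm, truncnorm

from .contractile import (
    ForceLengthParams,
    ForceVelocityParams,
    eval_force_length,
    eval_force_velocity,
)
from .dynamometry import MomentArmModel, TorqueTrace
from .geometry import ArchitectureMeasure, GeometryError, ProbeFrame
from .kinematics import FascicleTimeSeries


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


# Default parameter distributions: (mean, sd, lower, upper) of truncated
# normals, set from printed cohort statistics of in vivo vastus lateralis
# studies (force_max 5295 +/- 1504 N, L0 105 +/- 17 mm, G 6.1 +/- 2.7,
# vmax 17.5 +/- 10.5 L0/s) with physiological truncation bounds.
DEFAULT_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    "force_max": (5295.0, 1504.0, 2200.0, 10000.0),
    "L0": (105.0, 17.0, 60.0, 160.0),
    "b": (1.5, 0.08, 1.35, 1.65),
    "s": (1.55, 0.08, 1.45, 1.7),
    "vmax": (17.5, 4.5, 10.0, 24.0),
    "G": (6.1, 2.7, 3.3, 8.8),
    "thickness_mvc60": (23.7, 3.0, 15.0, 35.0),
}

# fixed architectural couplings (fractions of L0 / MVC thickness)
REST0_LENGTH_RATIO = 0.7838   # resting fascicle length at 0 deg, in L0
REST_SLOPE = 0.00605          # d(rest length)/d(angle), in L0 per deg
# nominal cohort force-velocity curve used only for the load-dependent gearing
REF_G = 6.1
REF_VMAX = 17.5
REST60_THICK_RATIO = 21.3 / 23.7
REST0_THICK_RATIO = 21.2 / 23.7
THICKNESS_FORCE_R = 0.65      # built-in thickness <-> force_max coupling


@dataclass
class SimulationConfig:
    n_participants: int = 21
    seed: int = 0
    sampling_rate: float = 1000.0     # Hz, dynamometer channels
    fascicle_rate: float = 100.0      # Hz, ultrasound fascicle series
    noise_torque_sd: float = 2.0      # N m, white
    noise_length_sd: float = 1.0      # mm, band-limited drift
    noise_pennation_sd: float = 0.5   # deg, band-limited drift
    noise_corner_hz: float = 0.15     # drift bandwidth (multi-second tracking drift)
    isometric_angles: tuple[float, ...] = (100.0, 90.0, 80.0, 70.0, 60.0, 50.0)
    isokinetic_speeds: tuple[float, ...] = (50.0, 100.0, 200.0, 300.0, 400.0)
    parameter_distributions: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DISTRIBUTIONS)
    )
    pcsa_share: float = 0.35
    gearing: float = 0.008            # L0 per deg, fascicle-to-joint (at 200 deg/s load)
    gear_gain: float = 0.4            # series-elastic load dependence of the gearing
    apo_tilt_deg: float = 0.25        # deep-aponeurosis inclination in dual-probe scans
    theta_opt: float = 70.0           # deg knee flexion where L = L0 under MVC
    angular_accel: float = 8000.0     # deg/s^2, dynamometer ramp
    moment_arm: MomentArmModel = field(default_factory=MomentArmModel)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        if self.sampling_rate <= 0 or self.fascicle_rate <= 0:
            raise ConfigurationError("sampling rates must be positive")
        for name in ("noise_torque_sd", "noise_length_sd", "noise_pennation_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0 < self.pcsa_share < 1:
            raise ConfigurationError("pcsa_share must lie in (0, 1)")


@dataclass
class GroundTruthMuscle:
    participant_id: str
    force_max_true: float   # N, knee-extension level
    L0_true: float          # mm
    b_true: float
    s_true: float
    vmax_true: float        # L0/s
    G_true: float
    pcsa_share: float
    rest0_arch: ArchitectureMeasure
    rest60_arch: ArchitectureMeasure
    mvc60_arch: ArchitectureMeasure

    def __post_init__(self) -> None:
        if min(self.force_max_true, self.L0_true, self.vmax_true, self.s_true) <= 0:
            raise ValueError("force_max, L0, vmax and s must be positive")
        if not 3.0 < self.G_true < 9.0:
            raise ValueError("G must lie strictly in (3, 9)")
        if not 0.0 < self.pcsa_share < 1.0:
            raise ValueError("pcsa_share must lie in (0, 1)")

    @property
    def fl_params(self) -> ForceLengthParams:
        return ForceLengthParams(self.force_max_true, self.L0_true, self.b_true, self.s_true)

    def fv_params(self) -> ForceVelocityParams:
        return ForceVelocityParams(self.force_max_true, self.vmax_true, self.G_true)


@dataclass
class TrialRecording:
    participant_id: str
    mode: str                       # isometric | isokinetic | passive
    nominal: float | None           # angle (deg) or speed (deg/s)
    torque_trace: TorqueTrace
    fascicle_series: FascicleTimeSeries


@dataclass
class ProbeGeometry:
    """Placement of the dual-probe holder used for REST_60 / MVC_60 scans."""

    gap_mm: float = 10.0
    angulation_deg: float = 5.0
    field_width: float = 60.0
    field_depth: float = 40.0


def passive_torque(angle_deg: np.ndarray | float) -> np.ndarray | float:
    """Smooth passive + limb-gravity torque (N m) as a function of knee angle."""
    th = np.asarray(angle_deg, dtype=float)
    out = 4.0 * np.cos(np.radians(th)) + 2.0 * np.exp(-th / 30.0)
    return out if out.shape else float(out)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _drift_noise(rng: np.random.Generator, n: int, sd: float, fs: float, corner: float) -> np.ndarray:
    """Band-limited (low-passed white) noise with stationary process sd ``sd``.

    The scale uses the theoretical variance of the filtered process (not the
    per-trial sample variance, which would turn slow drift into steep ramps
    in short trials).
    """
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    fc = min(corner, 0.45 * fs)
    pad = int(max(200, 4 * fs / fc))  # wash out filter start-up over >= 4 correlation times
    white = rng.standard_normal(n + 2 * pad)
    b, a = signal.butter(2, fc, btype="low", fs=fs)
    smooth = signal.filtfilt(b, a, white)[pad:-pad]
    # stationary variance of zero-phase butter2 applied to unit white noise
    f = np.linspace(0.0, fs / 2, 4096)
    h2 = 1.0 / (1.0 + (f / fc) ** 4)  # |H|^2 of one pass
    process_var = (2.0 / fs) * np.trapezoid(h2**2, f)
    return smooth * (sd / np.sqrt(process_var))


def _gearing_at(cfg: SimulationConfig, omega: float) -> float:
    """Fascicle-to-joint gearing (L0/deg) at one isokinetic load level.

    Series elasticity makes fascicles shorten more per joint degree at higher
    force: the gearing scales linearly with the nominal cohort force-velocity
    factor, referenced to the 200 deg/s condition.  omega = 0 gives the
    quasi-static (isometric/MVC) gearing.
    """

    def fv_ref(w: float) -> float:
        x = cfg.gearing * w / REF_VMAX
        return (1.0 - x) / (1.0 + REF_G * x)

    return cfg.gearing * (1.0 + cfg.gear_gain * (fv_ref(omega) - fv_ref(200.0)))


class _Muscle:
    """Forward-model helper bound to one participant's ground truth."""

    def __init__(self, truth: GroundTruthMuscle, cfg: SimulationConfig):
        self.truth = truth
        self.cfg = cfg

    def active_length(self, theta: np.ndarray, gearing: float) -> np.ndarray:
        t = self.truth
        return t.L0_true * (1.0 + gearing * (np.asarray(theta, float) - self.cfg.theta_opt))

    def rest_length(self, theta: np.ndarray) -> np.ndarray:
        return self.truth.L0_true * (REST0_LENGTH_RATIO + REST_SLOPE * np.asarray(theta, float))

    def fl(self, L: np.ndarray) -> np.ndarray:
        return np.asarray(eval_force_length(L, self.truth.fl_params)) / self.truth.force_max_true

    def fv(self, v_l0s: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(v_l0s, float), 0.0, None) / self.truth.vmax_true
        return (1.0 - x) / (1.0 + self.truth.G_true * x)

    def pennation_of(self, L: np.ndarray, activation: np.ndarray | float) -> np.ndarray:
        th_mvc = self.truth.mvc60_arch.thickness
        th_rest = self.truth.rest60_arch.thickness
        th = th_rest + np.asarray(activation, float) * (th_mvc - th_rest)
        return np.degrees(np.arcsin(np.clip(th / np.asarray(L, float), 0.0, 0.999)))


def _sample_truths(cfg: SimulationConfig) -> list[GroundTruthMuscle]:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    dists = cfg.parameter_distributions

    def tn_ppf(u: np.ndarray, key: str) -> np.ndarray:
        mean, sd, lo, hi = dists[key]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.ppf(u, a, b, loc=mean, scale=sd)

    n = cfg.n_participants
    u = rng.uniform(size=(7, n))
    force_max = tn_ppf(u[0], "force_max")
    L0 = tn_ppf(u[1], "L0")
    b_par = tn_ppf(u[2], "b")
    s_par = tn_ppf(u[3], "s")
    vmax = tn_ppf(u[4], "vmax")
    G = tn_ppf(u[5], "G")
    # MVC thickness shares a latent factor with force_max (thicker = stronger)
    z_force = norm.ppf(u[0])
    z_new = norm.ppf(u[6])
    z_th = THICKNESS_FORCE_R * z_force + np.sqrt(1 - THICKNESS_FORCE_R**2) * z_new
    th_mvc = tn_ppf(norm.cdf(z_th), "thickness_mvc60")

    truths = []
    c_static = _gearing_at(cfg, 0.0)
    for i in range(n):
        lf_mvc60 = L0[i] * (1.0 + c_static * (60.0 - cfg.theta_opt))
        lf_rest60 = L0[i] * (REST0_LENGTH_RATIO + REST_SLOPE * 60.0)
        lf_rest0 = L0[i] * REST0_LENGTH_RATIO
        th60 = th_mvc[i] * REST60_THICK_RATIO
        th0 = th_mvc[i] * REST0_THICK_RATIO

        def arch(cond: str, lf: float, th: float, tilt: float = 0.0) -> ArchitectureMeasure:
            # pennation is referenced to the deep aponeurosis, which in the
            # dual-probe scans is inclined by `tilt` deg to the superficial one
            return ArchitectureMeasure(
                condition=cond,
                fascicle_length=lf,
                pennation=float(np.degrees(np.arcsin(th / lf)) + tilt),
                thickness=th,
            )

        tilt = cfg.apo_tilt_deg
        truths.append(
            GroundTruthMuscle(
                participant_id=f"P{i + 1:02d}",
                force_max_true=float(force_max[i]),
                L0_true=float(L0[i]),
                b_true=float(b_par[i]),
                s_true=float(s_par[i]),
                vmax_true=float(vmax[i]),
                G_true=float(G[i]),
                pcsa_share=cfg.pcsa_share,
                rest0_arch=arch("REST_0", lf_rest0, th0),
                rest60_arch=arch("REST_60", lf_rest60, th60, tilt),
                mvc60_arch=arch("MVC_60", lf_mvc60, th_mvc[i], tilt),
            )
        )
    return truths


def _isokinetic_profile(
    omega: float, accel: float, t: np.ndarray, t_move: float
) -> tuple[np.ndarray, np.ndarray]:
    """Jerk-limited dynamometer profile 110 -> 0 deg. Returns (theta, omega(t)).

    Velocity ramps follow a smoothstep (C1-continuous omega), as servo-driven
    dynamometers do; each ramp lasts omega/accel and covers omega^2/(2*accel)
    degrees, exactly like a trapezoidal profile of the same peak acceleration.
    """
    t_acc = omega / accel
    ang_acc = 0.5 * omega * t_acc
    t_const = (110.0 - 2 * ang_acc) / omega
    tau = np.asarray(t, float) - t_move
    theta = np.full_like(tau, 110.0)
    w = np.zeros_like(tau)

    def s2(x: np.ndarray) -> np.ndarray:
        # integral of smoothstep: s2(1) = 1/2
        return x**3 - 0.5 * x**4

    ph1 = (tau >= 0) & (tau < t_acc)
    x1 = tau[ph1] / t_acc
    theta[ph1] = 110.0 - omega * t_acc * s2(x1)
    w[ph1] = omega * _smoothstep(x1)
    ph2 = (tau >= t_acc) & (tau < t_acc + t_const)
    theta[ph2] = 110.0 - ang_acc - omega * (tau[ph2] - t_acc)
    w[ph2] = omega
    t3 = t_acc + t_const
    ph3 = (tau >= t3) & (tau < t3 + t_acc)
    x3 = (tau[ph3] - t3) / t_acc
    theta[ph3] = 110.0 - ang_acc - omega * t_const - omega * t_acc * (x3 - s2(x3))
    w[ph3] = omega * (1.0 - _smoothstep(x3))
    theta[tau >= t3 + t_acc] = 0.0
    w[tau >= t3 + t_acc] = 0.0
    return theta, w


def _simulate_participant(
    truth: GroundTruthMuscle, cfg: SimulationConfig, rng: np.random.Generator
) -> list[TrialRecording]:
    m = _Muscle(truth, cfg)
    ma = cfg.moment_arm
    fs, ffs = cfg.sampling_rate, cfg.fascicle_rate
    trials: list[TrialRecording] = []

    def make_series(tt: np.ndarray, L: np.ndarray, act: np.ndarray) -> FascicleTimeSeries:
        n_f = int(np.floor(tt[-1] * ffs)) + 1
        t_f = np.arange(n_f) / ffs
        L_f = np.interp(t_f, tt, L)
        act_f = np.interp(t_f, tt, act)
        pen_f = m.pennation_of(L_f, act_f)
        L_f = L_f + _drift_noise(rng, n_f, cfg.noise_length_sd, ffs, cfg.noise_corner_hz)
        pen_f = pen_f + _drift_noise(rng, n_f, cfg.noise_pennation_sd, ffs, cfg.noise_corner_hz)
        return FascicleTimeSeries(t_f, np.maximum(L_f, 1.0), np.clip(pen_f, 0.0, 89.0))

    def add_noise(tau: np.ndarray) -> np.ndarray:
        if cfg.noise_torque_sd > 0:
            tau = tau + cfg.noise_torque_sd * rng.standard_normal(tau.size)
        return tau

    c_static = _gearing_at(cfg, 0.0)

    # --- isometric trials -------------------------------------------------
    for theta in cfg.isometric_angles:
        t = np.arange(int(6.0 * fs)) / fs
        act = _smoothstep((t - 0.5) / 3.0)
        L_act = float(m.active_length(theta, c_static))
        L_rest = float(m.rest_length(theta))
        L = L_rest + act * (L_act - L_rest)
        force = act * truth.force_max_true * m.fl(L)
        tau = force * float(ma(theta)) + passive_torque(theta)
        trace = TorqueTrace(t, np.full_like(t, float(theta)), add_noise(tau),
                            mode="isometric", nominal=float(theta))
        trials.append(TrialRecording(truth.participant_id, "isometric", float(theta),
                                     trace, make_series(t, L, act)))

    # --- isokinetic trials ------------------------------------------------
    for omega in cfg.isokinetic_speeds:
        t_move = 1.0
        t_acc = omega / cfg.angular_accel
        t_total = t_move + 110.0 / omega + t_acc + 0.3
        t = np.arange(int(t_total * fs)) / fs
        theta, w = _isokinetic_profile(omega, cfg.angular_accel, t, t_move)
        act = _smoothstep(t / (0.8 * t_move))
        moving = t >= t_move
        act[moving] = 1.0
        c_w = _gearing_at(cfg, omega)
        L_act = m.active_length(theta, c_w)
        L_rest110 = float(m.rest_length(110.0))
        L = np.where(moving, L_act,
                     L_rest110 + act * (float(m.active_length(110.0, c_w)) - L_rest110))
        v_l0s = c_w * w  # shortening velocity in L0/s
        force = act * truth.force_max_true * m.fl(L) * m.fv(v_l0s)
        tau = force * np.asarray(ma(theta)) + passive_torque(theta)
        trace = TorqueTrace(t, theta, add_noise(tau), mode="isokinetic", nominal=float(omega))
        trials.append(TrialRecording(truth.participant_id, "isokinetic", float(omega),
                                     trace, make_series(t, L, act)))

    # --- passive movement -------------------------------------------------
    speed = 20.0
    t_total = 0.3 + 110.0 / speed + 0.3
    t = np.arange(int(t_total * fs)) / fs
    theta = np.clip(110.0 - speed * (t - 0.3), 0.0, 110.0)
    tau = np.asarray(passive_torque(theta), dtype=float)
    L = m.rest_length(theta)
    trace = TorqueTrace(t, theta, add_noise(tau), mode="passive", nominal=None)
    trials.append(TrialRecording(truth.participant_id, "passive", None,
                                 trace, make_series(t, L, np.zeros_like(t))))
    return trials


def generate_cohort(
    config: SimulationConfig,
) -> list[tuple[GroundTruthMuscle, list[TrialRecording]]]:
    """Simulate the full cohort. Deterministic given ``config.seed``."""
    truths = _sample_truths(config)
    cohort = []
    for i, truth in enumerate(truths):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202, i]))
        cohort.append((truth, _simulate_participant(truth, config, rng)))
    return cohort


# --- ultrasound scene construction ---------------------------------------

def generate_probe_scene(
    arch: ArchitectureMeasure, probe_geometry: ProbeGeometry | None = None
) -> dict:
    """Dual-probe scene whose exact reconstruction returns ``arch``.

    The muscle frame has the superficial aponeurosis horizontal at
    y = thickness.  The deep aponeurosis crosses y = 0 at the centre of the
    distal field and is inclined by whatever angle reconciles the triple
    (length, pennation, thickness): pennation is referenced to the deep
    aponeurosis, so tilt = pennation - asin(thickness/length), zero for a
    sin-consistent triple.  A straight fascicle inserts on the deep
    aponeurosis at the field centre and exits the distal field of view
    before reaching the superficial aponeurosis, so reconstruction requires
    linear extrapolation.  The proximal probe (rotated by the holder's
    angulation) contributes superficial-aponeurosis points only.  Returns
    local-frame point lists per probe plus the rigid probe frames.
    """
    pg = probe_geometry or ProbeGeometry()
    t = arch.thickness
    if not 0.0 < arch.pennation < 90.0:
        raise ValueError("pennation must lie strictly between 0 and 90 deg")
    if t >= pg.field_depth:
        raise GeometryError("muscle thicker than the probe's field depth")
    sin_global = t / arch.fascicle_length
    if not 0.0 < sin_global < 1.0:
        raise GeometryError("fascicle shorter than the inter-aponeurosis distance")
    theta = float(np.arcsin(sin_global))         # fascicle angle, global frame
    tilt = np.radians(arch.pennation) - theta    # deep-aponeurosis inclination
    if tilt < -1e-9 or tilt > np.radians(20.0):
        raise GeometryError(
            "pennation/thickness/length triple implies an implausible "
            "aponeurosis inclination"
        )

    x_c = pg.field_width / 2.0
    d = np.array([np.cos(theta), np.sin(theta)])
    # fascicle visible inside the distal field only
    reach = min((pg.field_width - 5.0 - x_c) / d[0], (t - 1e-9) / d[1])
    n_pts = 6
    fasc = np.array([x_c, 0.0]) + np.linspace(0.0, reach, n_pts)[:, None] * d
    xs = np.linspace(5.0, pg.field_width - 5.0, 6)  # symmetric about x_c
    deep = np.column_stack([xs, -(xs - x_c) * np.tan(tilt)])
    sup_distal = np.column_stack([xs, np.full_like(xs, t)])
    x_prox = pg.field_width + pg.gap_mm
    xs_p = np.linspace(x_prox + 5.0, x_prox + pg.field_width - 5.0, 6)
    sup_prox = np.column_stack([xs_p, np.full_like(xs_p, t)])

    frames = {
        "distal": ProbeFrame("distal", origin=(0.0, 0.0), rotation_deg=0.0,
                             field_width=pg.field_width, field_depth=pg.field_depth),
        "proximal": ProbeFrame("proximal", origin=(x_prox, 0.0),
                               rotation_deg=pg.angulation_deg,
                               field_width=pg.field_width, field_depth=pg.field_depth),
    }
    segments = {
        "distal": {
            "fascicle": frames["distal"].to_local(fasc),
            "superficial_apo": frames["distal"].to_local(sup_distal),
            "deep_apo": frames["distal"].to_local(deep),
        },
        "proximal": {
            "superficial_apo": frames["proximal"].to_local(sup_prox),
        },
    }
    return {"segments": segments, "frames": frames, "truth": arch}


def generate_panoramic_scene(arch: ArchitectureMeasure, n_fragments: int = 5) -> dict:
    """Panoramic-scan scene (fragment orientations + aponeurosis points).

    Fragments in both regions share the straight-fascicle orientation implied
    by ``arch`` (pennation relative to a horizontal deep aponeurosis).
    """
    t = arch.thickness
    xs = np.linspace(0.0, 120.0, 9)
    deep = np.column_stack([xs, np.zeros_like(xs)])
    sup = np.column_stack([xs, np.full_like(xs, t)])
    frag = np.full(n_fragments, arch.pennation)
    return {
        "deep_fragments": frag.copy(),
        "superficial_fragments": frag.copy(),
        "deep_apo": deep,
        "superficial_apo": sup,
        "roi": (10.0, 110.0),
        "truth": arch,
    }


def generate_architecture_scenes(
    truth: GroundTruthMuscle, probe_geometry: ProbeGeometry | None = None
) -> dict[str, dict]:
    """All three measurement scenes for one participant."""
    return {
        "REST_0": generate_panoramic_scene(truth.rest0_arch),
        "REST_60": generate_probe_scene(truth.rest60_arch, probe_geometry),
        "MVC_60": generate_probe_scene(truth.mvc60_arch, probe_geometry),
    }
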