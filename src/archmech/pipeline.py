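"""End-to-end orchestration: trials + scenes -> architecture, fits, work, stats.

Per participant the chain is: select best attempt per condition, zero-phase
filter, angle-matched passive correction, torque -> knee-extension force via
the moment arm, fascicle state at the torque peak -> force-length points,
iso-velocity peaks -> force-velocity points, Hill fits, force summary, and
joint/muscle work over the common 80-50 deg phase.  Architecture scenes are
reconstructed with the geometry module (dual-probe fusion + extrapolation,
panoramic composite).  Cohort-level outputs are pandas tables ready for the
statistics stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry as geo
from .contractile import (
    ForceSummary,
    fit_force_length,
    fit_force_velocity,
    summarise_forces,
)
from .dynamometry import (
    MomentArmModel,
    MuscleShareModel,
    TorqueTrace,
    correct_passive,
    filter_torque,
    knee_extension_force,
    select_best_attempt,
    vastus_lateralis_force,
)
from .kinematics import (
    FascicleTimeSeries,
    fascicle_velocity,
    isovelocity_window,
    muscle_length,
    peak_in_window,
    resample_to,
)
from .synthetic import TrialRecording
from .work import joint_work, muscle_work


class OrchestrationError(RuntimeError):
    """A pipeline stage failed; the message names the stage and participant."""


@dataclass
class PipelineConfig:
    """Knobs of the processing chain (not of the synthetic generator)."""

    filter_cutoff_hz: float = 20.0
    filter_order: int = 2
    passive_cutoff_hz: float = 2.0   # passive sweep is quasi-static; match its bandwidth
    mvc_smooth_s: float = 0.5        # moving-average width for the isometric plateau
    moment_arm: MomentArmModel = field(default_factory=MomentArmModel)
    share: MuscleShareModel = field(default_factory=MuscleShareModel)
    window_start_angle: float = 80.0
    window_end_angle: float = 50.0
    rho: float = 2.0

    def to_dict(self) -> dict:
        return {
            "filter_cutoff_hz": self.filter_cutoff_hz,
            "filter_order": self.filter_order,
            "moment_arm_coefficients": list(self.moment_arm.coefficients),
            "moment_arm_valid_range": list(self.moment_arm.valid_range),
            "pcsa_share": self.share.pcsa_share,
            "window_start_angle": self.window_start_angle,
            "window_end_angle": self.window_end_angle,
            "rho": self.rho,
        }


@dataclass
class ParticipantResult:
    participant_id: str
    summary: ForceSummary
    architecture: dict[str, geo.ArchitectureMeasure]
    work: pd.DataFrame           # speed, joint_work_J, muscle_work_J
    fl_points: np.ndarray        # (L mm, F N)
    fv_points: np.ndarray        # (v L0/s, F N)


def measure_architecture(scene: dict, condition: str) -> geo.ArchitectureMeasure:
    """Reconstruct one architecture condition from a synthetic or real scene."""
    if "segments" in scene:  # dual-probe route
        frames = scene["frames"]
        seg_lists = {pid: list(feats.values()) for pid, feats in scene["segments"].items()}
        keys = {pid: list(feats.keys()) for pid, feats in scene["segments"].items()}
        fused = geo.fuse_probe_frames(seg_lists, frames)
        feats = {
            pid: dict(zip(keys[pid], arrays)) for pid, arrays in fused.items()
        }
        fasc = feats["distal"]["fascicle"]
        deep = feats["distal"]["deep_apo"]
        sup_candidates = [feats["distal"]["superficial_apo"]]
        if "proximal" in feats and "superficial_apo" in feats["proximal"]:
            sup_candidates.append(feats["proximal"]["superficial_apo"])
        lengths, pennations = [], []
        for sup in sup_candidates:
            try:
                L, pen = geo.extrapolate_fascicle_length(fasc, sup, deep)
            except geo.GeometryError:
                continue
            lengths.append(L)
            pennations.append(pen)
        if not lengths:
            raise geo.ReconstructionError("no superficial aponeurosis candidate worked")
        best = int(np.argmin(lengths))
        length = geo.shortest_candidate_length(lengths)
        x_deep = feats["distal"]["deep_apo"][:, 0]
        thickness = geo.muscle_thickness(
            feats["distal"]["superficial_apo"], deep, (x_deep.min(), x_deep.max())
        )
        return geo.ArchitectureMeasure(condition, length, pennations[best], thickness)
    # panoramic route
    meas = geo.composite_fascicle_panoramic(
        scene["superficial_fragments"], scene["deep_fragments"],
        scene["superficial_apo"], scene["deep_apo"], scene["roi"],
    )
    return geo.ArchitectureMeasure(condition, meas.fascicle_length, meas.pennation,
                                   meas.thickness)


def _group_trials(trials: list[TrialRecording]) -> dict[tuple[str, float | None], list[TrialRecording]]:
    groups: dict[tuple[str, float | None], list[TrialRecording]] = {}
    for tr in trials:
        groups.setdefault((tr.mode, tr.nominal), []).append(tr)
    return groups


def process_participant(
    trials: list[TrialRecording],
    scenes: dict[str, dict] | None,
    config: PipelineConfig | None = None,
) -> ParticipantResult:
    cfg = config or PipelineConfig()
    groups = _group_trials(trials)
    pid = trials[0].participant_id

    passives = [tr for (mode, _), grp in groups.items() if mode == "passive" for tr in grp]
    if not passives:
        raise OrchestrationError(f"dynamometry/{pid}: no passive trial recorded")
    # the passive movement is quasi-static: filter at its own (low) bandwidth
    passive = filter_torque(passives[0].torque_trace, cfg.passive_cutoff_hz, cfg.filter_order)

    def corrected_force(rec: TrialRecording) -> tuple[TorqueTrace, np.ndarray]:
        filt = filter_torque(rec.torque_trace, cfg.filter_cutoff_hz, cfg.filter_order)
        corr = correct_passive(filt, passive)
        force = knee_extension_force(corr.torque, corr.angle, cfg.moment_arm)
        return corr, np.asarray(force)

    # --- force-length points from isometric efforts -----------------------
    fl_points = []
    for (mode, nominal), grp in sorted(groups.items(), key=lambda kv: str(kv[0])):
        if mode != "isometric":
            continue
        best = _best_of(grp, passive, cfg)
        corr, force = corrected_force(best)
        # MVC force = peak of a short moving average over the held plateau
        n_avg = max(1, int(round(cfg.mvc_smooth_s * corr.sampling_rate)))
        if n_avg > 1:
            kernel = np.ones(n_avg) / n_avg
            smooth = np.convolve(force, kernel, mode="same")
            # exclude edges where the average window is truncated
            half = n_avg // 2
            core = slice(half, len(smooth) - half)
            i_peak = int(np.argmax(smooth[core])) + half
            f_point = float(smooth[i_peak])
        else:
            i_peak = int(np.argmax(force))
            f_point = float(force[i_peak])
        t_peak = corr.time[i_peak]
        L_peak = float(np.interp(t_peak, best.fascicle_series.time,
                                 best.fascicle_series.fascicle_length))
        fl_points.append((L_peak, f_point))
    if len(fl_points) < 4:
        raise OrchestrationError(f"contractile/{pid}: fewer than 4 isometric conditions")
    fl_points = np.array(sorted(fl_points))
    fl = fit_force_length(fl_points[:, 0], fl_points[:, 1], rho=cfg.rho)

    # --- force-velocity points and work from isokinetic efforts -----------
    fv_rows = []
    work_rows = []
    for (mode, nominal), grp in sorted(groups.items(), key=lambda kv: str(kv[0])):
        if mode != "isokinetic":
            continue
        best = _best_of(grp, passive, cfg)
        corr, force = corrected_force(best)
        window = isovelocity_window(corr, cfg.window_start_angle, cfg.window_end_angle)
        fs_series = best.fascicle_series
        vel = fascicle_velocity(fs_series)
        _, v_peak = peak_in_window(fs_series.time, np.zeros_like(fs_series.time), vel, window)
        f_peak, _ = peak_in_window(corr.time, force, np.zeros_like(corr.time), window)
        fv_rows.append((float(nominal), v_peak / fl.L0, f_peak))

        w_joint = joint_work(corr, window)
        pen = fs_series.pennation if fs_series.pennation is not None else np.zeros_like(fs_series.time)
        lm = muscle_length(fs_series.fascicle_length, pen)
        lm_t = resample_to(fs_series.time, lm, corr.time)
        vl_force = vastus_lateralis_force(force, cfg.share)
        w_muscle = muscle_work(corr.time, np.asarray(vl_force), lm_t, window)
        work_rows.append({"participant": pid, "speed_deg_s": float(nominal),
                          "joint_work_J": w_joint, "muscle_work_J": w_muscle})
    if not fv_rows:
        raise OrchestrationError(f"contractile/{pid}: no isokinetic trials")
    fv_rows.sort()
    fv_points = np.array([(v, f) for _, v, f in fv_rows])
    fv = fit_force_velocity(fv_points[:, 0], fv_points[:, 1], force_max=fl.force_max)
    peaks_by_speed = {sp: (v, f) for sp, v, f in fv_rows}
    summary = summarise_forces(fl, fv, peaks_by_speed)

    architecture = {}
    if scenes:
        for condition, scene in scenes.items():
            architecture[condition] = measure_architecture(scene, condition)

    return ParticipantResult(
        participant_id=pid,
        summary=summary,
        architecture=architecture,
        work=pd.DataFrame(work_rows),
        fl_points=fl_points,
        fv_points=fv_points,
    )


def _best_of(grp: list[TrialRecording], passive: TorqueTrace, cfg: PipelineConfig) -> TrialRecording:
    """Best of the recorded attempts = highest peak corrected torque."""
    if len(grp) == 1:
        return grp[0]
    corrected = []
    for rec in grp:
        filt = filter_torque(rec.torque_trace, cfg.filter_cutoff_hz, cfg.filter_order)
        corrected.append(correct_passive(filt, passive))
    peaks = [tr.peak_torque() for tr in corrected]
    select_best_attempt(corrected)  # validates non-empty, same rule
    return grp[int(np.argmax(peaks))]


def cohort_table(results: list[ParticipantResult]) -> pd.DataFrame:
    """One row per participant: architecture, force and work variables."""
    rows = []
    for res in results:
        row: dict[str, float | str] = {"participant": res.participant_id}
        for cond, arch in res.architecture.items():
            key = cond.lower()
            row[f"fascicle_length_{key}_mm"] = arch.fascicle_length
            row[f"pennation_{key}_deg"] = arch.pennation
            row[f"thickness_{key}_mm"] = arch.thickness
        s = res.summary
        row.update({
            "force_max_N": s.force_max, "force_iso400_N": s.force_iso400,
            "G": s.G, "force_slope": s.force_slope, "L0_mm": s.L0,
            "vmax_L0_s": s.vmax,
        })
        for _, wrow in res.work.iterrows():
            sp = int(wrow["speed_deg_s"])
            row[f"joint_work_{sp}_J"] = wrow["joint_work_J"]
            row[f"muscle_work_{sp}_J"] = wrow["muscle_work_J"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant")


def process_cohort(
    cohort: list[tuple],
    config: PipelineConfig | None = None,
    scenes_by_participant: dict[str, dict[str, dict]] | None = None,
) -> tuple[list[ParticipantResult], pd.DataFrame]:
    """Run the full chain on a synthetic cohort (truth, trials) list."""
    results = []
    for truth, trials in cohort:
        scenes = None
        if scenes_by_participant is not None:
            scenes = scenes_by_participant.get(truth.participant_id)
        try:
            results.append(process_participant(trials, scenes, config))
        except (ValueError, RuntimeError) as err:
            raise OrchestrationError(
                f"pipeline failed for {truth.participant_id}: {err}"
            ) from err
    return results, cohort_table(results)
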