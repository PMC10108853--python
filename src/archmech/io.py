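"""File interchange and on-disk orchestration.

CSV is the interchange format throughout: one file per dynamometer trial
(``time_s, angle_deg, torque_Nm`` plus optional ``fascicle_length_mm,
pennation_deg`` resampled onto the torque timebase), one segmentation CSV
per dual-probe scan (``frame_id, probe_id, feature, point_index, x_mm,
y_mm``) with a probes JSON, and a cohort manifest JSON tying everything
together.  Angles are stored in degrees; radians exist only inside
computations.  A per-participant supplementary-style wide table can be read
through a codebook mapping file columns onto pipeline variable names.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamometry import TorqueTrace
from .geometry import ProbeFrame
from .kinematics import FascicleTimeSeries, resample_to
from .pipeline import PipelineConfig, process_cohort
from .synthetic import (
    GroundTruthMuscle,
    SimulationConfig,
    TrialRecording,
    generate_architecture_scenes,
    generate_cohort,
)

TRIAL_COLUMNS = ("time_s", "angle_deg", "torque_Nm")
OPTIONAL_COLUMNS = ("fascicle_length_mm", "pennation_deg")


class SchemaError(ValueError):
    """A file does not match the documented column schema."""


def write_trial_csv(path: str | Path, rec: TrialRecording) -> None:
    trace = rec.torque_trace
    df = pd.DataFrame({
        "time_s": trace.time, "angle_deg": trace.angle, "torque_Nm": trace.torque,
    })
    fs = rec.fascicle_series
    df["fascicle_length_mm"] = resample_to(fs.time, fs.fascicle_length, trace.time)
    if fs.pennation is not None:
        df["pennation_deg"] = resample_to(fs.time, fs.pennation, trace.time)
    # default (shortest-repr) float formatting round-trips exactly
    df.to_csv(path, index=False)


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    """Typed, schema-checked trial table (may include fascicle columns)."""
    df = pd.read_csv(path, encoding="utf-8")
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if np.any(np.diff(df["time_s"].to_numpy(float)) <= 0):
        raise SchemaError(f"{path}: time_s must be strictly increasing")
    return df


def trial_from_frame(df: pd.DataFrame, mode: str, nominal: float | None,
                     participant_id: str) -> TrialRecording:
    trace = TorqueTrace(
        df["time_s"].to_numpy(float), df["angle_deg"].to_numpy(float),
        df["torque_Nm"].to_numpy(float), mode=mode, nominal=nominal,
    )
    if "fascicle_length_mm" in df.columns:
        pen = df["pennation_deg"].to_numpy(float) if "pennation_deg" in df.columns else None
        series = FascicleTimeSeries(trace.time, df["fascicle_length_mm"].to_numpy(float), pen)
    else:
        series = FascicleTimeSeries(trace.time, np.full_like(trace.time, 1.0), None)
    return TrialRecording(participant_id, mode, nominal, trace, series)


def _trial_filename(rec: TrialRecording) -> str:
    if rec.mode == "isometric":
        return f"iso_{int(rec.nominal):03d}.csv"
    if rec.mode == "isokinetic":
        return f"isok_{int(rec.nominal):03d}.csv"
    return "passive.csv"


def write_cohort(
    out_dir: str | Path,
    cohort: list[tuple[GroundTruthMuscle, list[TrialRecording]]],
    config: SimulationConfig,
) -> Path:
    """One CSV per trial plus a manifest JSON holding ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "participants": {},
    }
    for truth, trials in cohort:
        pdir = out / truth.participant_id
        pdir.mkdir(exist_ok=True)
        files = []
        for rec in trials:
            name = _trial_filename(rec)
            write_trial_csv(pdir / name, rec)
            files.append({"file": name, "mode": rec.mode, "nominal": rec.nominal})
        manifest["participants"][truth.participant_id] = {
            "trials": files,
            "ground_truth": {
                "force_max_N": truth.force_max_true, "L0_mm": truth.L0_true,
                "b": truth.b_true, "s": truth.s_true,
                "vmax_L0_s": truth.vmax_true, "G": truth.G_true,
                "pcsa_share": truth.pcsa_share,
            },
            "architecture": {
                arch.condition: {
                    "fascicle_length_mm": arch.fascicle_length,
                    "pennation_deg": arch.pennation,
                    "thickness_mm": arch.thickness,
                }
                for arch in (truth.rest0_arch, truth.rest60_arch, truth.mvc60_arch)
            },
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def read_cohort_trials(data_dir: str | Path) -> dict[str, list[TrialRecording]]:
    data = Path(data_dir)
    manifest_path = data / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"no manifest.json under {data}")
    manifest = json.loads(manifest_path.read_text())
    out: dict[str, list[TrialRecording]] = {}
    for pid, info in manifest["participants"].items():
        trials = []
        for entry in info["trials"]:
            df = read_trial_csv(data / pid / entry["file"])
            trials.append(trial_from_frame(df, entry["mode"], entry["nominal"], pid))
        out[pid] = trials
    return out


# --- segmentation CSV for dual-probe scenes -------------------------------

def write_scene_csv(path: str | Path, probes_path: str | Path, scene: dict) -> None:
    rows = []
    for probe_id, feats in scene["segments"].items():
        for feature, pts in feats.items():
            for i, (x, y) in enumerate(np.asarray(pts)):
                rows.append({"frame_id": 0, "probe_id": probe_id, "feature": feature,
                             "point_index": i, "x_mm": x, "y_mm": y})
    pd.DataFrame(rows).to_csv(path, index=False)
    probes = {
        pid: {"origin": list(f.origin), "rotation_deg": f.rotation_deg,
              "field_width": f.field_width, "field_depth": f.field_depth}
        for pid, f in scene["frames"].items()
    }
    Path(probes_path).write_text(json.dumps(probes, indent=1))


def read_scene_csv(path: str | Path, probes_path: str | Path) -> dict:
    df = pd.read_csv(path)
    required = {"probe_id", "feature", "point_index", "x_mm", "y_mm"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing segmentation columns {sorted(missing)}")
    probes = json.loads(Path(probes_path).read_text())
    segments: dict[str, dict[str, np.ndarray]] = {}
    for (pid, feature), sub in df.groupby(["probe_id", "feature"]):
        sub = sub.sort_values("point_index")
        segments.setdefault(pid, {})[feature] = sub[["x_mm", "y_mm"]].to_numpy(float)
    frames = {
        pid: ProbeFrame(pid, origin=tuple(spec["origin"]),
                        rotation_deg=spec["rotation_deg"],
                        field_width=spec["field_width"], field_depth=spec["field_depth"])
        for pid, spec in probes.items()
    }
    return {"segments": segments, "frames": frames}


# --- supplementary-style wide table ---------------------------------------

REQUIRED_VARIABLES = ("participant",)


def read_supplementary_table(path: str | Path, codebook: dict[str, str]) -> pd.DataFrame:
    """Load a per-participant wide table through a codebook column mapping.

    ``codebook`` maps file column names to pipeline variable names.  Unmapped
    columns are preserved under their original names (with a warning list
    attached to ``DataFrame.attrs``); a missing required variable raises a
    mapping error naming the candidates.  Delimited text and xlsx
    spreadsheets are both accepted.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    renamed = df.rename(columns=codebook)
    mapped = set(codebook.values())
    for var in REQUIRED_VARIABLES:
        if var not in renamed.columns:
            raise SchemaError(
                f"required variable {var!r} not present after mapping; "
                f"file columns: {sorted(df.columns)}"
            )
    renamed.attrs["unmapped_columns"] = [c for c in renamed.columns
                                         if c not in mapped and c not in REQUIRED_VARIABLES]
    return renamed.set_index("participant")


# --- full on-disk run ------------------------------------------------------

def config_hash(sim: SimulationConfig, pipe: PipelineConfig) -> str:
    payload = json.dumps(
        {"sim": {k: v for k, v in sorted(vars(sim).items())
                 if isinstance(v, (int, float, str, tuple, list))},
         "pipe": pipe.to_dict()},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    sim_config: SimulationConfig,
    out_dir: str | Path,
    pipe_config: PipelineConfig | None = None,
) -> dict:
    """Simulate, process and persist a full cohort run; returns the bundle.

    Writes cohort summary CSV, per-participant fits JSON and a manifest with
    the config hash and seed; identical configs reproduce identical outputs.
    """
    pipe = pipe_config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(sim_config)
    scenes = {t.participant_id: generate_architecture_scenes(t) for t, _ in cohort}
    results, table = process_cohort(cohort, pipe, scenes)
    table.to_csv(out / "cohort.csv", float_format="%.10g")
    fits = {
        r.participant_id: {
            "force_max_N": r.summary.force_max, "L0_mm": r.summary.L0,
            "G": r.summary.G, "vmax_L0_s": r.summary.vmax,
            "force_iso400_N": r.summary.force_iso400,
            "force_slope": r.summary.force_slope,
        }
        for r in results
    }
    (out / "fits.json").write_text(json.dumps(fits, indent=1, sort_keys=True))
    manifest = {
        "seed": sim_config.seed,
        "n_participants": sim_config.n_participants,
        "config_hash": config_hash(sim_config, pipe),
        "pipeline": pipe.to_dict(),
        "outputs": ["cohort.csv", "fits.json"],
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"results": results, "table": table, "manifest": manifest, "cohort": cohort}
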