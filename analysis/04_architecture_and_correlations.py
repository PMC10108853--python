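"""Reconstruct architecture scans and correlate them with force and work.

For each participant the three measurement conditions are reconstructed from
their ultrasound scenes (panoramic composite for REST_0 with the knee
extended; dual-probe fusion + linear extrapolation for REST_60 and MVC_60),
then the Pearson correlation matrix between architecture and the force/work
variables is computed with the conventional strength bands (|r| >= 0.7
strong, 0.4-0.7 moderate, < 0.4 weak) and a normality screen per variable.

Writes results/cohort.csv, results/cohort_summary.csv, results/correlations.csv.
Run after 02 and 03:  python analysis/04_architecture_and_correlations.py
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from archmech.geometry import ArchitectureMeasure
from archmech.pipeline import measure_architecture
from archmech.stats import cohort_summary, correlation_table, normality_screen, pearson_matrix
from archmech.synthetic import generate_panoramic_scene, generate_probe_scene

manifest = json.loads((ROOT / "scratch" / "cohort" / "manifest.json").read_text())
forces = pd.read_csv(ROOT / "results" / "force_parameters.csv").set_index("participant")
work = pd.read_csv(ROOT / "results" / "work.csv")

rows = []
for pid, info in sorted(manifest["participants"].items()):
    row = {"participant": pid}
    for cond, vals in info["architecture"].items():
        arch = ArchitectureMeasure(cond, vals["fascicle_length_mm"],
                                   vals["pennation_deg"], vals["thickness_mm"])
        scene = (generate_panoramic_scene(arch) if cond == "REST_0"
                 else generate_probe_scene(arch))
        meas = measure_architecture(scene, cond)
        key = cond.lower()
        row[f"fascicle_length_{key}_mm"] = meas.fascicle_length
        row[f"pennation_{key}_deg"] = meas.pennation
        row[f"thickness_{key}_mm"] = meas.thickness
    rows.append(row)

arch_df = pd.DataFrame(rows).set_index("participant")
wide_work = work.pivot(index="participant", columns="speed_deg_s", values="joint_work_J")
wide_work.columns = [f"joint_work_{int(c)}_J" for c in wide_work.columns]
cohort = arch_df.join(forces).join(wide_work)

out_dir = ROOT / "results"
cohort.to_csv(out_dir / "cohort.csv")
cohort_summary(cohort).to_csv(out_dir / "cohort_summary.csv")

arch_vars = [c for c in arch_df.columns]
force_vars = ["force_max_N", "force_iso400_N", "G", "force_slope_per_L0_s"]
pairs = [(a, f) for a in arch_vars for f in force_vars]
pairs += [(a, w) for a in arch_vars if a.startswith("fascicle_length")
          for w in wide_work.columns]
corr = correlation_table(pearson_matrix(cohort, pairs))
corr.to_csv(out_dir / "correlations.csv", index=False)

print(f"cohort table: {cohort.shape[0]} participants x {cohort.shape[1]} variables")
print("normality screen (Lilliefors p), architecture variables:")
for var in arch_vars[:3]:
    stat, p = normality_screen(cohort[var].to_numpy())
    print(f"  {var:32s} D = {stat:.3f}, p = {p:.2f}")
sig = corr[corr.significant]
print(f"{len(sig)}/{len(corr)} correlations significant at alpha = 0.05; strongest:")
print(sig.reindex(sig.r.abs().sort_values(ascending=False).index)
      .head(5)[["var_x", "var_y", "r", "p", "strength"]].to_string(index=False))
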