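"""Condition the torque signals and fit the per-participant Hill curves.

Reads the simulated trials from scratch/cohort/, runs the dynamometry chain
(20 Hz zero-phase filter, angle-matched passive correction, moment-arm
conversion), extracts force-length points from the isometric efforts and
iso-velocity peaks from the isokinetic efforts, fits the force-length bell
and the force-velocity hyperbola, and writes the per-participant force
parameters to results/force_parameters.csv.

Run after 01:  python analysis/02_fit_contractile_curves.py
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from archmech.io import read_cohort_trials
from archmech.pipeline import PipelineConfig, process_participant

trials_by_pid = read_cohort_trials(ROOT / "scratch" / "cohort")
rows = []
for pid, trials in sorted(trials_by_pid.items()):
    res = process_participant(trials, None, PipelineConfig())
    s = res.summary
    rows.append({
        "participant": pid, "force_max_N": s.force_max, "L0_mm": s.L0,
        "G": s.G, "vmax_L0_s": s.vmax, "force_iso400_N": s.force_iso400,
        "force_slope_per_L0_s": s.force_slope,
    })

df = pd.DataFrame(rows).set_index("participant")
out = ROOT / "results" / "force_parameters.csv"
out.parent.mkdir(exist_ok=True)
df.to_csv(out)
print(f"fitted {len(df)} participants -> {out}")
print("cohort mean +/- sd:")
print((df.mean().round(2).astype(str) + " +/- " + df.std(ddof=1).round(2).astype(str)).to_string())
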