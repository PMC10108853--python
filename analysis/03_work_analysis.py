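"""Joint and muscle work over the common iso-velocity phase (80-50 deg).

Reads the simulated trials, integrates joint torque over joint angle and
vastus lateralis force over muscle-length change within the window shared by
all isokinetic speeds, and writes results/work.csv (one row per participant
and speed) plus a speed-level summary.

Run after 01:  python analysis/03_work_analysis.py
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from archmech.io import read_cohort_trials
from archmech.pipeline import PipelineConfig, process_participant

trials_by_pid = read_cohort_trials(ROOT / "scratch" / "cohort")
frames = []
for pid, trials in sorted(trials_by_pid.items()):
    res = process_participant(trials, None, PipelineConfig())
    frames.append(res.work)

work = pd.concat(frames, ignore_index=True)
out = ROOT / "results" / "work.csv"
out.parent.mkdir(exist_ok=True)
work.to_csv(out, index=False)

by_speed = work.groupby("speed_deg_s")[["joint_work_J", "muscle_work_J"]].agg(["mean", "std"])
print(f"wrote {len(work)} rows -> {out}")
print(by_speed.round(1).to_string())
jw = work.groupby("speed_deg_s")["joint_work_J"].mean()
mw = work.groupby("speed_deg_s")["muscle_work_J"].mean()
print(f"joint work range {jw.min():.0f}-{jw.max():.0f} J; "
      f"muscle work range {mw.min():.0f}-{mw.max():.0f} J over the five speeds")
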