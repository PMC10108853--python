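"""Scatter figures for the architecture-force relationships.

Renders regression scatter plots (least-squares line, 95% confidence band,
Pearson r) for the thickness/fascicle-length vs force relationships on the
simulated cohort. Figures are image files, so they go under scratch/figures/.

Run after 04:  python analysis/06_figures.py
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from archmech.plots import regression_scatter

cohort = pd.read_csv(ROOT / "results" / "cohort.csv").set_index("participant")
out = ROOT / "scratch" / "figures"
out.mkdir(parents=True, exist_ok=True)

pairs = [
    ("thickness_rest_60_mm", "force_max_N"),
    ("fascicle_length_rest_60_mm", "force_iso400_N"),
    ("fascicle_length_rest_60_mm", "joint_work_100_J"),
    ("pennation_mvc_60_deg", "force_max_N"),
]
for var_x, var_y in pairs:
    path = out / f"{var_x}__{var_y}.png"
    regression_scatter(cohort, var_x, var_y, path)
    print(f"wrote {path}")
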