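"""Simulate the virtual study cohort and persist every recording.

Generates 21 virtual participants with known ground-truth muscle properties
and writes their dynamometer trials (6 isometric angles, 5 isokinetic
speeds, 1 passive movement) as per-trial CSVs plus a ground-truth manifest.
Raw trial files are bulky, so they go under scratch/cohort/; downstream
scripts read them back from there.

Run from the repository root:  python analysis/01_simulate_cohort.py [seed]
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from archmech.io import write_cohort
from archmech.synthetic import SimulationConfig, generate_cohort

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
cfg = SimulationConfig(n_participants=21, seed=seed)
cohort = generate_cohort(cfg)
out = write_cohort(ROOT / "scratch" / "cohort", cohort, cfg)

n_trials = sum(len(trials) for _, trials in cohort)
print(f"simulated {len(cohort)} participants, {n_trials} trials -> {out}")
print("ground truth ranges:")
for name, vals in {
    "force_max_N": [t.force_max_true for t, _ in cohort],
    "L0_mm": [t.L0_true for t, _ in cohort],
    "G": [t.G_true for t, _ in cohort],
    "vmax_L0_s": [t.vmax_true for t, _ in cohort],
}.items():
    print(f"  {name:12s} {min(vals):8.2f} .. {max(vals):8.2f}")
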