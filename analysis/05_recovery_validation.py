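"""Parameter-recovery validation: how well does the pipeline invert itself?

Runs the full chain on (i) a noiseless cohort, where every participant's
force_max, L0, vmax and G must come back to better than 0.1% relative, and
(ii) a ladder of measurement-noise levels, where the curvature error should
grow monotonically with noise.  Writes results/recovery.csv.

Self-contained (does not need 01-04):  python analysis/05_recovery_validation.py
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import numpy as np
import pandas as pd

from archmech.pipeline import PipelineConfig, process_cohort
from archmech.synthetic import SimulationConfig, generate_cohort

rows = []

# noiseless closed loop, full cohort
cfg = SimulationConfig(n_participants=21, seed=1, noise_torque_sd=0.0,
                       noise_length_sd=0.0, noise_pennation_sd=0.0)
cohort = generate_cohort(cfg)
results, _ = process_cohort(cohort, PipelineConfig(), None)
for (truth, _), res in zip(cohort, results):
    s = res.summary
    rows.append({
        "mode": "noiseless", "participant": truth.participant_id,
        "rel_err_force_max": abs(s.force_max - truth.force_max_true) / truth.force_max_true,
        "rel_err_L0": abs(s.L0 - truth.L0_true) / truth.L0_true,
        "rel_err_vmax": abs(s.vmax - truth.vmax_true) / truth.vmax_true,
        "rel_err_G": abs(s.G - truth.G_true) / truth.G_true,
        "abs_err_G": abs(s.G - truth.G_true),
    })
noiseless = pd.DataFrame(rows)
worst = noiseless[[c for c in noiseless.columns if c.startswith("rel")]].max().max()
print(f"noiseless closed loop, n = 21: worst relative error {worst:.2e} "
      f"({'OK' if worst < 1e-3 else 'FAILED'} vs 1e-3)")

# noise ladder (torque sd N m, fascicle sd mm), 40 replicates each
for tsd, lsd in [(0.5, 0.25), (2.0, 1.0), (6.0, 3.0)]:
    errs = []
    for rep in range(40):
        c = SimulationConfig(n_participants=2, seed=60_000 + rep,
                             noise_torque_sd=tsd, noise_length_sd=lsd,
                             noise_pennation_sd=0.5)
        ch = generate_cohort(c)
        r, _ = process_cohort(ch[:1], PipelineConfig(), None)
        errs.append(abs(r[0].summary.G - ch[0][0].G_true))
    rows.append({"mode": f"noise_t{tsd}_l{lsd}", "participant": "median",
                 "abs_err_G": float(np.median(errs))})
    print(f"noise (torque {tsd} N m, fascicle {lsd} mm): "
          f"median |G_hat - G| = {np.median(errs):.3f} over 40 replicates")

pd.DataFrame(rows).to_csv(ROOT / "results" / "recovery.csv", index=False)
print("-> results/recovery.csv")
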