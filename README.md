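# archmech

**Linking in vivo muscle architecture to force production** — a tested,
reusable pipeline for vastus lateralis mechanics: isokinetic dynamometry
conditioning, ultrasound fascicle-geometry reconstruction, Hill-type
force–length / force–velocity fitting, joint and muscle work, and cohort
correlation statistics. Because raw torque and ultrasound traces for such
studies are rarely deposited, the package ships a first-class synthetic-cohort
generator with known ground truth, so every stage of the analysis is
verifiable end-to-end by closed-loop parameter recovery.

## Who this is for

Muscle physiologists and biomechanists who estimate fascicle-level contractile
properties from dynamometer + ultrasound experiments and want a transparent,
testable implementation of the full chain — or who want to study, by
simulation, how measurement noise and protocol choices propagate into derived
parameters such as the force–velocity curvature.

## The model

Isometric knee-extension forces at six knee angles (100°–50° flexion) are fit
with a skewed force–length bell

```
F(L) = F_max · exp( −| ((L/L0)^b − 1) / s |² )
```

where `L0` is the optimal fascicle length, `b` the skewness and `s` the width.
Peak fascicle velocities and forces from five isokinetic speeds
(50–400 °·s⁻¹), measured in the iso-velocity phase common to all speeds
(80°–50° flexion), are fit with the Hill hyperbola

```
F(v) = F_max · (1 − v/v_max) / (1 + G · v/v_max)
```

with `F_max` fixed from the force–length fit, `v_max` free (in L0·s⁻¹) and
the curvature constrained to 3 < G < 9. Forces come from torque via a
knee-angle-dependent moment arm and a PCSA share (0.35 for the vastus
lateralis); fascicle geometry comes from panoramic-scan composite fascicles
or dual-probe scans fused by rigid transforms with linear extrapolation to
the superficial aponeurosis.

## Worked example

```python
from archmech.pipeline import PipelineConfig, process_cohort
from archmech.synthetic import SimulationConfig, generate_cohort

cfg = SimulationConfig(n_participants=2, seed=7, noise_torque_sd=0.0,
                       noise_length_sd=0.0, noise_pennation_sd=0.0)
cohort = generate_cohort(cfg)          # (ground truth, 12 trials) per participant
results, table = process_cohort(cohort, PipelineConfig())
truth = cohort[0][0]
s = results[0].summary
print(f"G   true {truth.G_true:.3f}  estimated {s.G:.3f}")
print(f"vmax true {truth.vmax_true:.2f} estimated {s.vmax:.2f} L0/s")
```

prints (noiseless closed loop — estimates match the ground truth to better
than 0.1 %):

```
G   true 3.665  estimated 3.664
vmax true 17.04 estimated 17.04 L0/s
```

The `analysis/` scripts run the whole study-scale workflow on a simulated
21-participant cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py          # trials -> scratch/cohort/
python analysis/02_fit_contractile_curves.py   # -> results/force_parameters.csv
python analysis/03_work_analysis.py            # -> results/work.csv
python analysis/04_architecture_and_correlations.py  # -> results/correlations.csv
python analysis/05_recovery_validation.py      # -> results/recovery.csv
```

At realistic noise (2 N·m torque, 1 mm fascicle) the cohort means come out at
e.g. `force_max ≈ 5700 N`, `L0 ≈ 105 mm`, `G ≈ 5.8`, `vmax ≈ 16 L0/s`
(seed 1), with joint work falling from ≈97 J at 50 °·s⁻¹ to ≈46 J at
400 °·s⁻¹ and muscle thickness moderately correlated with maximum force
(r ≈ 0.64) — while fascicle length and pennation do not correlate
significantly with the force parameters, mirroring what such cohorts show.

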