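# Methods

This note documents the models, the synthetic forward model, the numerical
choices, and the known limits of the `archmech` pipeline. The package is an
analysis pipeline for in vivo vastus lateralis mechanics: it turns
dynamometer torque traces and segmented ultrasound geometry into fascicle
architecture, Hill-type contractile parameters, mechanical work, and cohort
correlation statistics.

## Processing chain

Per participant:

1. **Filtering.** Torque is low-passed with a second-order Butterworth
   filter run forward and backward (zero phase), cut-off 20 Hz. The two-pass
   magnitude response is |H|², i.e. gain ½ exactly at the cut-off. Edges use
   odd-reflection padding of three filter lengths. The passive-movement
   trace is filtered at 2 Hz instead: it is a quasi-static sweep whose
   signal content lies well below 1 Hz, and matching the filter to the
   signal band keeps sensor noise in the passive curve from re-entering
   every corrected trial through the angle interpolation.
2. **Passive/gravity correction.** The passive torque–angle curve is
   interpolated at the angles visited by each active trial and subtracted
   (angle-matched, not time-matched), removing limb gravity and passive
   structures in one step.
3. **Force conversion.** Knee-extension force = torque / moment arm. The
   moment arm is a single-peaked quadratic in knee-flexion angle
   (peak 41 mm at 40° flexion, ≈30 mm at deep flexion), a smoothed
   representation of in vivo patellar-tendon moment-arm data; it is
   configurable. Vastus lateralis force = 0.35 × knee-extension force, the
   PCSA fraction implied by the ratio of published cohort means of VL
   fascicle force to knee-extension force (1856/5295 ≈ 0.35).
4. **Force–length points.** Isometric MVC force is read as the peak of a
   0.5 s moving average of the corrected force — the standard plateau
   estimate, which is unbiased for a held contraction while suppressing the
   upward bias that an instantaneous-peak reading takes from noise.
   Fascicle length is interpolated at the same instant.
5. **Force–velocity points.** In each isokinetic trial the iso-velocity
   window is located by linear interpolation of the 80° and 50° knee-angle
   crossings. Fascicle velocity is the raw central difference of the tracked
   fascicle length (shortening positive); the window peaks of force and of
   velocity are extracted independently.
6. **Fits.** The force–length bell
   `F = F_max exp(−|((L/L0)^b − 1)/s|^ρ)` (ρ = 2, configurable) is fit by
   nonlinear least squares over (F_max, L0, b, s); initialisation is fixed
   and data-driven (L0 at the largest observed force, F_max at 1.05× that
   force, b = 1, s = 0.5), so fits are deterministic. The Hill hyperbola is
   then fit over (v_max, G) with F_max held fixed, velocities expressed in
   L0·s⁻¹ (L0 from the force–length fit), G box-constrained to
   (3 + 1e−6, 9 − 1e−6) (bound hits are logged, not errors) and v_max free
   above the largest observed velocity. Both fits use `scipy`'s
   trust-region-reflective least squares at tight tolerances (1e−15).
7. **Derived force parameters.** `force_iso400` is the *measured* window
   peak force of the 400 °·s⁻¹ trial; `force_slope` is the drop of the
   fitted normalised force between the measured slowest and fastest peak
   velocities, per L0·s⁻¹. The printed literature unit for this slope
   (per cm·s⁻¹) is not mutually consistent with the printed cohort
   magnitudes; per L0·s⁻¹ is the reading under which the numbers cohere,
   and is what this pipeline reports.
8. **Work.** Joint work is the trapezoidal integral of torque over joint
   angle (radians) across exactly 80°→50°, window endpoints interpolated;
   muscle work is the trapezoidal integral of VL force over muscle-length
   change (Lf·cos pennation, metres) in the same time window. Extension and
   shortening-under-tension count positive.
9. **Geometry.** Dual-probe scans: per-probe point lists are fused into the
   distal probe frame by rigid transforms; aponeuroses and the fascicle are
   represented by total-least-squares lines; the fascicle is extended from
   its deep insertion (the endpoint nearest the deep aponeurosis line — a
   frame-independent criterion) to the superficial aponeurosis line, with
   the shortest candidate retained when several fields of view provide one.
   Panoramic scans: dominant fragment orientations in the deep and
   superficial regions are joined by an orientation-interpolating curve
   (inclination varies linearly with depth between the two regional
   orientations — end tangents equal the dominant orientations; for equal
   orientations this is exactly the straight fascicle t/sin θ). Thickness is
   the mean perpendicular distance between the aponeurosis lines across the
   region of interest. Pennation is always measured against the deep
   aponeurosis. All geometry is planar.
10. **Statistics.** Pearson correlations with two-sided p, dof = n − 2,
    α = 0.05, no multiple-testing correction (a Holm-adjusted column is
    emitted alongside, clearly an extra); strength classes on |r|:
    ≥ 0.7 strong, 0.4–0.7 moderate, < 0.4 weak. The normality screen is a
    Kolmogorov–Smirnov test with estimated mean/sd, i.e. the Lilliefors
    variant, reported but never used to switch methods silently.

## The synthetic cohort

Each virtual participant owns ground-truth parameters drawn from truncated
normals calibrated to published cohort statistics: F_max ~ 5295 ± 1504 N,
L0 ~ 105 ± 17 mm, G ~ 6.1 ± 2.7 in (3.3, 8.8), v_max ~ 17.5 ± 4.5 L0·s⁻¹ in
(10, 24), b ~ 1.5 ± 0.08 in (1.35, 1.65), s ~ 1.55 ± 0.08 in (1.45, 1.7),
MVC thickness ~ 23.7 ± 3.0 mm sharing a latent factor with F_max (r = 0.65,
thicker = stronger). Two calibrations deserve comment:

* **v_max spread.** The published ±10.5 L0·s⁻¹ spread of v_max largely
  reflects estimation noise of a far-extrapolated parameter, not true
  physiology: with the five test speeds reaching only ≈3 L0·s⁻¹, a true
  v_max of 40 L0·s⁻¹ is practically unidentifiable. True values are
  therefore drawn with a tighter spread inside the range the protocol can
  resolve; the *estimated* spread produced by the noisy pipeline is wider,
  as in real studies.
* **Force–length width.** b and s are kept at the broad end of
  physiological reports so that the force transient through the optimum
  during the fastest trial stays within the 20 Hz measurement bandwidth the
  protocol itself prescribes; a very narrow force–length curve would make
  the filtered force peak unrepresentative at 400 °·s⁻¹ for any analysis
  pipeline honouring that filter.

**Kinematics.** Under full activation fascicle length tracks knee angle
linearly, `L(θ) = L0·(1 + c·(θ − 70°))`, with the optimum crossed at 70°
flexion — inside the 80–50° window. The gearing c (0.008 L0/deg at the
200 °·s⁻¹ load) increases with force level (first-order series-elastic
model, gain 0.4 on the nominal force–velocity factor): at higher loads the
tendon stretches more, so fascicles shorten more per joint degree. During an
isokinetic extension the fascicle therefore shortens at constant velocity
c·L0·ω, and the simulated active force — F_max · f_L(L) · f_V(v), scaled by
the moment arm — peaks exactly at L0 with that velocity, so the measured
(peak velocity, peak force) pairs lie exactly on the ground-truth Hill
curve. This is what makes closed-loop recovery a sharp test: on a noiseless
cohort the pipeline recovers F_max, L0, v_max and G to better than 0.1 %
relative for every participant across the whole parameter box.

The dynamometer follows a jerk-limited velocity profile (smoothstep ramps at
8000 °·s⁻² peak acceleration); resting fascicle length rises linearly with
flexion angle (82.3 mm at 0° to ≈120 mm at 60°, in units of L0); passive
torque is a smooth cosine-plus-exponential of knee angle, identical in the
passive trial and in every active trial, so angle-matched subtraction removes
it exactly. Isometric trials ramp activation over 3 s (smoothstep) and hold;
sampling defaults are 1000 Hz for torque and 100 Hz for the fascicle series —
ultrasound systems used for fast isokinetic work run at 60–120 fps, and the
75 ms iso-velocity window at 400 °·s⁻¹ requires it.

**Scenes.** For each architecture condition the generator emits coordinate-
level ultrasound scenes that reconstruct exactly to the stored ground truth:
panoramic fragment orientations with parallel aponeuroses for REST_0, and
dual-probe scenes (5° inter-probe angulation, configurable gap) for REST_60
and MVC_60 in which the deep aponeurosis is inclined to the superficial one
by the small angle that reconciles the (length, pennation, thickness) triple
— published cohort triples are not sin-consistent with parallel aponeuroses,
and a fraction-of-a-degree inclination (default 0.25°) is anatomically
realistic. The fascicle inserts at the centre of the distal field of view
and exits it before reaching the superficial aponeurosis, so reconstruction
must extrapolate, as with real scans.

**Noise.** Torque noise is white (electrical sensor noise; the pipeline's
20 Hz filter then shapes it). Fascicle length and pennation noise is
band-limited drift — white noise low-passed at 0.15 Hz and scaled to the
requested stationary sd (1 mm / 0.5° by default) — emulating the
slowly-accumulating, frame-to-frame-correlated errors of ultrasound fascicle
tracking. The spectral choice matters: the pipeline differentiates the
fascicle series with a raw central difference and takes window peaks, so a
1 mm *white* error per frame would produce ≈20 mm·s⁻¹ velocity noise at any
realistic frame rate and swamp the slow-speed force–velocity points; tracked
fascicle outputs do not look like that, because tracking software integrates
frame-to-frame flow and its error is drift. Under the drift model the
curvature parameter is recovered with median |Ĝ − G| ≈ 0.4 at the default
noise (200 single-participant replicates), and the error shrinks
monotonically as the noise ladder is lowered.

**What the generator does not emulate.** Activation dynamics (plateau values
only), fascicle curvature and 3-D probe misalignment, history dependence of
force, tendon-state estimation, inter-muscle load sharing beyond a fixed
PCSA share, and any B-mode image content (scenes are coordinate-level).
Passing tests therefore demonstrate the correctness of the analysis chain
and its noise robustness — not that these physiological complications are
harmless in real data.

## Known quantitative limits

Three cohort-level outputs sit systematically away from published reference
values, and the discrepancies are informative rather than bugs: with
force_max ≈ 5295 N, force_iso400/force_max ≈ 0.39 and measured velocities of
0.45–3 L0·s⁻¹, the Hill curve fixes (i) the mean force_slope near −0.17 to
−0.18 per L0·s⁻¹ (steeper published values require the estimation-noise-wide
v_max spread excluded above), and (ii) a slow-to-fast joint-work ratio near
2.3, so matching the fast-speed work leaves the slow-speed work ≈20 % high
relative to a published 43–76 J range whose internal ratio (≈1.8) is
shallower than its own printed G and v_max imply. The acceptance script
reports what the pipeline actually computes.

## Numerical notes

* Zero-phase filtering of a quadratic (the moment-arm modulation) is exact in
  the window interior; the residual closed-loop bias (~1e−4 relative on the
  fastest trial's peak force) comes from the quartic term of the
  force–length bell through the filter and stays below the 0.1 % recovery
  budget over the whole parameter box.
* Degenerate inputs raise typed errors: parallel fascicle/aponeurosis lines,
  crossing aponeuroses, zero-width ROIs, constant samples in the normality
  screen, zero-variance correlation variables, all-above-F_max
  force–velocity data.
* Ties: equal-peak attempts keep the first; equal force maxima in a window
  keep the earliest sample; the first downward crossing defines the window
  when the angle ripples.
* All angles are degrees in files and interfaces; radians appear only inside
  computations. Seeded `numpy` Generators make every simulation
  reproducible; identical configs give byte-identical outputs.
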