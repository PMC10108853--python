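"""Synthetic cohort generator: determinism, scenes, closed-loop consistency."""

import numpy as np
import pytest

from archmech.geometry import ArchitectureMeasure
from archmech.pipeline import PipelineConfig, measure_architecture, process_cohort
from archmech.synthetic import (
    ConfigurationError,
    ProbeGeometry,
    SimulationConfig,
    generate_architecture_scenes,
    generate_cohort,
    generate_probe_scene,
    passive_torque,
)


class TestConfigValidation:
    def test_defaults_match_study_protocol(self):
        cfg = SimulationConfig()
        assert cfg.n_participants == 21
        assert cfg.isometric_angles == (100.0, 90.0, 80.0, 70.0, 60.0, 50.0)
        assert cfg.isokinetic_speeds == (50.0, 100.0, 200.0, 300.0, 400.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_participants": 1},
            {"sampling_rate": 0.0},
            {"fascicle_rate": -10.0},
            {"noise_torque_sd": -1.0},
            {"pcsa_share": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_gives_identical_cohorts(self):
        cfg = SimulationConfig(n_participants=2, seed=7)
        c1 = generate_cohort(cfg)
        c2 = generate_cohort(SimulationConfig(n_participants=2, seed=7))
        for (t1, tr1), (t2, tr2) in zip(c1, c2):
            assert t1.force_max_true == t2.force_max_true
            assert t1.G_true == t2.G_true
            for a, b in zip(tr1, tr2):
                np.testing.assert_array_equal(a.torque_trace.torque, b.torque_trace.torque)
                np.testing.assert_array_equal(
                    a.fascicle_series.fascicle_length, b.fascicle_series.fascicle_length
                )

    def test_different_seeds_differ(self):
        a = generate_cohort(SimulationConfig(n_participants=2, seed=1))
        b = generate_cohort(SimulationConfig(n_participants=2, seed=2))
        assert a[0][0].force_max_true != b[0][0].force_max_true


class TestTrialStructure:
    def test_trial_inventory_per_participant(self, noiseless_cohort):
        for truth, trials in noiseless_cohort:
            modes = [t.mode for t in trials]
            assert modes.count("isometric") == 6
            assert modes.count("isokinetic") == 5
            assert modes.count("passive") == 1

    def test_time_increasing_and_lengths_positive(self, noiseless_cohort):
        for _, trials in noiseless_cohort:
            for tr in trials:
                assert np.all(np.diff(tr.torque_trace.time) > 0)
                assert np.all(tr.fascicle_series.fascicle_length > 0)

    def test_isokinetic_covers_full_range_of_motion(self, noiseless_cohort):
        for _, trials in noiseless_cohort:
            for tr in trials:
                if tr.mode == "isokinetic":
                    assert tr.torque_trace.angle.max() == pytest.approx(110.0)
                    assert tr.torque_trace.angle.min() == pytest.approx(0.0)

    def test_passive_trial_equals_passive_model(self, noiseless_cohort):
        _, trials = noiseless_cohort[0]
        passive = [t for t in trials if t.mode == "passive"][0]
        expected = passive_torque(passive.torque_trace.angle)
        np.testing.assert_allclose(passive.torque_trace.torque, expected, atol=1e-12)


class TestClosedLoopRecovery:
    def test_noiseless_single_participant_recovery(self, noiseless_cohort):
        """Full pipeline inverts the forward model to < 1e-3 without noise."""
        results, _ = process_cohort(noiseless_cohort[:1], PipelineConfig(), None)
        truth = noiseless_cohort[0][0]
        s = results[0].summary
        assert abs(s.force_max - truth.force_max_true) / truth.force_max_true < 1e-3
        assert abs(s.L0 - truth.L0_true) / truth.L0_true < 1e-3
        assert abs(s.vmax - truth.vmax_true) / truth.vmax_true < 1e-3
        assert abs(s.G - truth.G_true) / truth.G_true < 1e-3

    def test_estimator_bias_shrinks_with_noise(self):
        """Monte-Carlo consistency: G error grows monotonically over a noise ladder."""
        meds = []
        for level, (tsd, lsd) in enumerate([(0.0, 0.0), (2.0, 1.0), (8.0, 4.0)]):
            errs = []
            for rep in range(12):
                cfg = SimulationConfig(
                    n_participants=2, seed=500 + 50 * level + rep,
                    noise_torque_sd=tsd, noise_length_sd=lsd,
                    noise_pennation_sd=0.5 * (lsd > 0),
                )
                cohort = generate_cohort(cfg)
                results, _ = process_cohort(cohort[:1], PipelineConfig(), None)
                errs.append(abs(results[0].summary.G - cohort[0][0].G_true))
            meds.append(float(np.median(errs)))
        assert meds[0] < meds[1] < meds[2]
        assert meds[0] < 1e-2


class TestCohortStatistics:
    def test_cohort_mean_curvature_emulates_study(self):
        cfg = SimulationConfig(n_participants=21, seed=3)
        cohort = generate_cohort(cfg)
        g = np.array([t.G_true for t, _ in cohort])
        # printed cohort statistic: G = 6.1 +/- 2.7 (n = 21)
        assert abs(g.mean() - 6.1) < 2 * 2.7 / np.sqrt(21)

    def test_ground_truth_invariants(self, noiseless_cohort):
        for truth, _ in noiseless_cohort:
            assert 3.0 < truth.G_true < 9.0
            assert truth.vmax_true > 0
            assert 0 < truth.pcsa_share < 1
            for arch in (truth.rest0_arch, truth.rest60_arch, truth.mvc60_arch):
                assert isinstance(arch, ArchitectureMeasure)


class TestProbeScene:
    def test_right_triangle_reconstruction(self):
        arch = ArchitectureMeasure("MVC_60", 40.0, 30.0, 20.0)
        scene = generate_probe_scene(arch)
        meas = measure_architecture(scene, "MVC_60")
        assert meas.fascicle_length == pytest.approx(40.0, abs=1e-9)
        assert meas.pennation == pytest.approx(30.0, abs=1e-9)
        assert meas.thickness == pytest.approx(20.0, abs=1e-9)

    def test_identity_probe_transforms_give_global_coordinates(self):
        arch = ArchitectureMeasure("REST_60", 100.0, 12.0, 20.79)
        scene = generate_probe_scene(arch, ProbeGeometry(angulation_deg=0.0))
        frames = scene["frames"]
        local = scene["segments"]["distal"]["deep_apo"]
        assert np.allclose(frames["distal"].to_common(local), local)

    def test_reconstruction_invariant_to_probe_placement(self, rng):
        arch = ArchitectureMeasure("MVC_60", 95.0, 14.5, 23.78)
        base = measure_architecture(generate_probe_scene(arch), "MVC_60")
        for _ in range(100):
            pg = ProbeGeometry(
                gap_mm=rng.uniform(2, 30), angulation_deg=rng.uniform(-10, 10)
            )
            meas = measure_architecture(generate_probe_scene(arch, pg), "MVC_60")
            assert abs(meas.fascicle_length - base.fascicle_length) < 1e-9
            assert abs(meas.pennation - base.pennation) < 1e-9

    def test_scene_consistency_with_truth_across_cohort(self, noiseless_cohort):
        for truth, _ in noiseless_cohort:
            scenes = generate_architecture_scenes(truth)
            for cond, arch_true in (
                ("REST_0", truth.rest0_arch),
                ("REST_60", truth.rest60_arch),
                ("MVC_60", truth.mvc60_arch),
            ):
                meas = measure_architecture(scenes[cond], cond)
                assert meas.fascicle_length == pytest.approx(
                    arch_true.fascicle_length, rel=1e-9
                )
                assert meas.pennation == pytest.approx(arch_true.pennation, abs=1e-9)
                assert meas.thickness == pytest.approx(arch_true.thickness, rel=1e-9)
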