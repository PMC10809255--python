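import numpy as np
import pytest
from scipy.stats import spearmanr

from dyesorb.geometry import center_of_mass_series, trajectory_metrics
from dyesorb.states import ClassifierConfig, segments_from_metrics
from dyesorb.synthetic import (
    DimerInterval,
    Script,
    SimConfig,
    StateInterval,
    build_dye_template,
    frame_aligned_intervals,
    make_table1_fixture,
    simulate_smd_trace,
    simulate_trajectory,
)


class TestDyeTemplate:
    def test_site_counts_and_charge(self):
        coords, masses, charges, core = build_dye_template(64, 30)
        assert coords.shape == (64, 3)
        assert core.size == 30
        assert charges.sum() == pytest.approx(1.0)
        assert np.all(masses > 0)

    def test_core_is_planar(self):
        coords, _, _, core = build_dye_template(64, 30)
        assert np.allclose(coords[core, 2], coords[core, 2][0])

    def test_body_frame_centered_on_com(self):
        coords, masses, _, _ = build_dye_template(64, 30)
        com = (masses[:, None] * coords).sum(0) / masses.sum()
        np.testing.assert_allclose(com, 0.0, atol=1e-12)


class TestDeterminism:
    def test_scripted_identical_seeds(self):
        script = Script(states={0: [StateInterval(1.0, 3.0, "A")]})
        cfg = SimConfig(n_dye=2, duration=5.0, timestep=0.05, script=script,
                        noise_sd=0.5, seed=9)
        t1, _, _ = simulate_trajectory(cfg)
        t2, _, _ = simulate_trajectory(cfg)
        assert np.array_equal(t1.coords, t2.coords)

    def test_emergent_identical_seeds(self):
        cfg = SimConfig(n_dye=2, dye_site_count=16, core_site_count=8,
                        duration=1.0, timestep=0.01, seed=4)
        t1, _, _ = simulate_trajectory(cfg)
        t2, _, _ = simulate_trajectory(cfg)
        assert np.array_equal(t1.coords, t2.coords)

    def test_different_seed_differs(self):
        cfg = SimConfig(n_dye=2, dye_site_count=16, core_site_count=8,
                        duration=1.0, timestep=0.01, seed=4)
        t1, _, _ = simulate_trajectory(cfg)
        t2, _, _ = simulate_trajectory(SimConfig(**{**cfg.__dict__, "seed": 5}))
        assert not np.array_equal(t1.coords, t2.coords)


class TestScriptedMode:
    def test_classifier_reproduces_script(self):
        script = Script(states={1: [StateInterval(5.0, 15.0, "A")]})
        cfg = SimConfig(n_dye=3, duration=20.0, timestep=0.02, script=script, seed=0)
        traj, top, gt = simulate_trajectory(cfg)
        metrics = trajectory_metrics(traj, np_diameter=40.0)
        segs = segments_from_metrics(metrics, ClassifierConfig())
        assert len(segs) == 1
        seg = segs[0]
        (lo, hi, label, _), = frame_aligned_intervals(
            [iv for iv in gt.states[1] if iv.label != "FREE"], traj.times
        )
        assert (seg.dye, seg.label) == ("R6G_2", "A")
        assert (seg.start, seg.end) == (lo, hi)

    def test_ground_truth_partitions_time(self):
        script = Script(
            states={0: [StateInterval(2.0, 4.0, "T"), StateInterval(8.0, 14.0, "A")]},
            dimers=[DimerInterval(1, 2, 5.0, 10.0, location="solute")],
        )
        cfg = SimConfig(n_dye=3, duration=20.0, timestep=0.02, script=script, seed=0)
        _, _, gt = simulate_trajectory(cfg)
        for d in range(3):
            ivs = sorted(gt.states[d], key=lambda s: s.start)
            assert ivs[0].start == 0.0
            assert ivs[-1].end == pytest.approx(20.0)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end == pytest.approx(b.start)

    def test_overlapping_script_intervals_rejected(self):
        script = Script(states={0: [StateInterval(1.0, 5.0, "A"),
                                    StateInterval(4.0, 6.0, "T")]})
        cfg = SimConfig(n_dye=1, duration=10.0, timestep=0.05, script=script, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            simulate_trajectory(cfg)


class TestEmergentMode:
    def test_pure_diffusion_has_no_bound_states(self):
        cfg = SimConfig(n_dye=3, dye_site_count=16, core_site_count=8, nps=[],
                        attraction_kt=1e-9, stacking_depth=0.0, duration=5.0,
                        timestep=0.01, confinement_radius=None, noise_sd=0.0,
                        seed=1)
        _, _, gt = simulate_trajectory(cfg)
        assert gt.dimers == []
        for ivs in gt.states.values():
            assert all(iv.label == "FREE" for iv in ivs)

    def test_free_dye_msd_matches_diffusion_constant(self):
        """Mean squared displacement of free dyes follows 6·D_t·τ."""
        cfg = SimConfig(n_dye=20, dye_site_count=8, core_site_count=4, nps=[],
                        attraction_kt=1e-9, stacking_depth=0.0, duration=10.0,
                        timestep=0.01, confinement_radius=None, substeps=1,
                        seed=7)
        traj, top, _ = simulate_trajectory(cfg)
        coms = np.stack(
            [center_of_mass_series(top, traj.coords, f"R6G_{d + 1}")
             for d in range(cfg.n_dye)]
        )
        for lag in (20, 100):
            disp = coms[:, lag:, :] - coms[:, :-lag, :]
            msd = float((disp**2).sum(-1).mean())
            expected = 6.0 * cfg.d_t * lag * cfg.timestep
            assert msd == pytest.approx(expected, rel=0.10)

    def test_unstable_timestep_rejected(self):
        cfg = SimConfig(n_dye=2, dye_site_count=8, core_site_count=4, nps=[],
                        attraction_kt=1e-9, stacking_depth=0.0, duration=0.5,
                        timestep=0.05, confinement_radius=5.0, substeps=1,
                        seed=0)
        with pytest.raises(ValueError, match="unstable"):
            simulate_trajectory(cfg)

    def test_dimer_count_rises_with_stacking_depth(self):
        """Rank test: deeper stacking wells produce more dimer events."""
        depths = [0.0, 2.0, 4.0, 6.0]
        xs, ys = [], []
        for depth in depths:
            for seed in range(10):
                cfg = SimConfig(n_dye=3, dye_site_count=16, core_site_count=8,
                                nps=[], attraction_kt=1e-9, stacking_depth=depth,
                                duration=6.0, timestep=0.01,
                                confinement_radius=12.0, seed=seed)
                _, _, gt = simulate_trajectory(cfg)
                xs.append(depth)
                ys.append(len(gt.dimers))
        rho, p = spearmanr(xs, ys)
        assert rho > 0
        assert p < 0.01
        # and the well-less control produces none at all
        assert sum(y for x, y in zip(xs, ys) if x == 0.0) == 0


class TestPullingGenerator:
    def test_zero_wells_flat_force(self):
        trace, truth = simulate_smd_trace([], k=278.0, noise_sd=0.0, seed=0)
        assert truth.smd_total_depth_ev == 0.0
        assert np.all(trace.force == 0.0)
        assert trace.displacement[-1] > trace.displacement[0]

    def test_single_well_energy_balance(self):
        trace, truth = simulate_smd_trace([1.0], k=278.0, noise_sd=0.0, seed=0)
        # the sawtooth's spring energy equals the scripted well depth
        e = trace.force.max() ** 2 / (2 * 278.0) * 6.241509e-4
        assert e == pytest.approx(truth.smd_total_depth_ev, rel=0.01)

    def test_overlapping_wells_rejected(self):
        with pytest.raises(ValueError, match="verlapping"):
            simulate_smd_trace([1.0, 1.0], positions_A=[0.0, 1.0], k=278.0)

    def test_seeded_noise_reproducible(self):
        a, _ = simulate_smd_trace([0.5], noise_sd=10.0, seed=3)
        b, _ = simulate_smd_trace([0.5], noise_sd=10.0, seed=3)
        assert np.array_equal(a.force, b.force)


class TestCompositionFixtures:
    def test_reference_rows(self):
        spec = make_table1_fixture("40qSNP7")
        assert spec.atoms_per_snp == 3141
        assert spec.n_na_per_snp == 51
        spec = make_table1_fixture("20qSNP12")
        assert spec.n_snp == 3
        assert spec.atoms_per_snp == 421

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            make_table1_fixture("99xSNP0")
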