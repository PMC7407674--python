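"""KMC engine: initialization, moves, Metropolis, criteria, trajectories."""

import numpy as np
import pytest
from scipy import stats

from cgassoc.cg_model import rotate_about
from cgassoc.forcefield import (
    HybridForceField,
    PhysicsParams,
    StatPotentialTable,
    contact_distances,
)
from cgassoc.kmc_engine import (
    AssociationCriteria,
    DiffusionParams,
    InitializationError,
    SimulationConfig,
    check_association,
    diffusion_move,
    metropolis_accept,
    random_initial_configuration,
    run_ensemble,
    run_trajectory,
)


def small_config(**kwargs):
    defaults = dict(box_edge=60.0, n_steps=50, n_trajectories=5, base_seed=0,
                    record_rmsd=False)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestDiffusionParams:
    def test_stokes_einstein_magnitudes(self):
        """A 20 A protein diffuses ~10 A^2/ns and tumbles ~0.02 rad^2/ns."""
        d = DiffusionParams.stokes_einstein(20.0)
        assert d.d_trans == pytest.approx(12.3, rel=0.05)
        assert d.d_rot == pytest.approx(0.023, rel=0.05)

    def test_smaller_protein_diffuses_faster(self):
        assert (DiffusionParams.stokes_einstein(10.0).d_trans
                > DiffusionParams.stokes_einstein(30.0).d_trans)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            DiffusionParams(-1.0, 0.1)


class TestCriteriaValidation:
    def test_all_inactive_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            AssociationCriteria(min_native_contacts=None)

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(ValueError):
            AssociationCriteria(max_energy=np.inf)


class TestRandomInitialConfiguration:
    def test_centers_uniform_in_box(self, dimer6):
        """KS test per coordinate against uniform [0, box_edge)."""
        config = small_config(box_edge=100.0)
        rng = np.random.default_rng(0)
        centers = []
        for _ in range(2000):
            rec, lig = random_initial_configuration(dimer6.receptor, dimer6.ligand,
                                                    config, rng)
            centers.append(rec.center)
            centers.append(lig.center)
        centers = np.array(centers)
        for axis in range(3):
            p = stats.kstest(centers[:, axis] / 100.0, "uniform").pvalue
            assert p > 0.001

    def test_no_steric_clash(self, dimer6):
        config = small_config(box_edge=60.0)
        ff = HybridForceField()
        rng = np.random.default_rng(1)
        for _ in range(50):
            rec, lig = random_initial_configuration(dimer6.receptor, dimer6.ligand,
                                                    config, rng, ff)
            r = np.linalg.norm(
                (rec.positions[:, None] - lig.positions[None, :]
                 - 60.0 * np.round((rec.positions[:, None] - lig.positions[None, :]) / 60.0)),
                axis=-1,
            )
            sigma = ff.physics.sigma_matrix(rec.site_kinds, lig.site_kinds)
            assert np.all(r >= sigma)

    def test_deterministic_given_seed(self, dimer6):
        config = small_config()
        a = random_initial_configuration(dimer6.receptor, dimer6.ligand, config,
                                         np.random.default_rng(7))
        b = random_initial_configuration(dimer6.receptor, dimer6.ligand, config,
                                         np.random.default_rng(7))
        c = random_initial_configuration(dimer6.receptor, dimer6.ligand, config,
                                         np.random.default_rng(8))
        np.testing.assert_array_equal(a[0].positions, b[0].positions)
        np.testing.assert_array_equal(a[1].positions, b[1].positions)
        assert not np.array_equal(a[1].positions, c[1].positions)

    def test_impossible_box_raises(self, dimer6):
        config = small_config(box_edge=6.0, max_init_attempts=20)
        with pytest.raises(InitializationError):
            random_initial_configuration(dimer6.receptor, dimer6.ligand, config,
                                         np.random.default_rng(0))


class TestDiffusionMove:
    def test_zero_diffusion_is_identity(self, dimer6):
        frozen = DiffusionParams(0.0, 0.0)
        rng = np.random.default_rng(0)
        rec, lig = dimer6.receptor.copy(), dimer6.ligand.copy()
        pose_r, pose_l = diffusion_move(rec, lig, frozen, frozen, 1.0, rng, 100.0)
        np.testing.assert_allclose(pose_r[0], rec.rotation, atol=1e-12)
        np.testing.assert_allclose(pose_r[1], rec.center, atol=1e-12)
        np.testing.assert_allclose(pose_l[1], lig.center, atol=1e-12)

    def test_displacement_variance_calibrated(self, dimer6):
        """Per-axis displacement variance equals 2 D dt within 3% over 1e5 moves."""
        d = DiffusionParams(10.0, 0.05)
        dt = 1.0
        rng = np.random.default_rng(42)
        rec = dimer6.receptor.copy()
        lig = dimer6.ligand.copy()
        box = 1e6  # much larger than any step, so min-image recovers the raw step
        disp = np.empty((100_000, 3))
        for i in range(len(disp)):
            pose_r, _ = diffusion_move(rec, lig, d, d, dt, rng, box)
            step = pose_r[1] - rec.center
            disp[i] = step - box * np.round(step / box)
        var = disp.var(axis=0)
        np.testing.assert_allclose(var, 2 * d.d_trans * dt, rtol=0.03)

    def test_move_preserves_rigidity(self, dimer6):
        d = DiffusionParams(10.0, 0.05)
        rng = np.random.default_rng(3)
        rec, lig = dimer6.receptor.copy(), dimer6.ligand.copy()
        ref = np.linalg.norm(rec.positions[:, None] - rec.positions[None, :], axis=-1)
        for _ in range(20):
            pose_r, pose_l = diffusion_move(rec, lig, d, d, 1.0, rng, 100.0)
            rec.set_pose(*pose_r)
            lig.set_pose(*pose_l)
        now = np.linalg.norm(rec.positions[:, None] - rec.positions[None, :], axis=-1)
        np.testing.assert_allclose(now, ref, atol=1e-9)

    def test_centers_wrapped_into_box(self, dimer6):
        d = DiffusionParams(50.0, 0.05)
        rng = np.random.default_rng(4)
        rec, lig = dimer6.receptor.copy(), dimer6.ligand.copy()
        for _ in range(200):
            pose_r, pose_l = diffusion_move(rec, lig, d, d, 1.0, rng, 30.0)
            rec.set_pose(*pose_r)
            lig.set_pose(*pose_l)
            assert np.all((rec.center >= 0) & (rec.center < 30.0))
            assert np.all((lig.center >= 0) & (lig.center < 30.0))


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(5.0, 5.0 - i, rng) for i in range(20))

    def test_acceptance_frequency_at_one_kt(self):
        """Empirical acceptance at dE = 1 kT approaches exp(-1)."""
        rng = np.random.default_rng(1)
        n = 200_000
        acc = sum(metropolis_accept(0.0, 1.0, rng) for _ in range(n)) / n
        assert acc == pytest.approx(np.exp(-1.0), abs=0.005)

    def test_two_state_boltzmann_occupancy(self):
        """A long Metropolis chain on two states reproduces exp(-dE)."""
        de = 1.5
        rng = np.random.default_rng(2)
        state, visits = 0, np.zeros(2)
        for _ in range(200_000):
            new = 1 - state
            if metropolis_accept(state * de, new * de, rng):
                state = new
            visits[state] += 1
        ratio = visits[1] / visits[0]
        expected = np.exp(-de)
        assert ratio == pytest.approx(expected, rel=0.05)


class TestCheckAssociation:
    def test_native_pose_is_associated(self, dimer6):
        ok, diag = check_association(dimer6.receptor, dimer6.ligand, dimer6.contacts,
                                     AssociationCriteria())
        assert ok
        assert diag["native_contacts"] == dimer6.contacts.n_contacts
        assert diag["contact_fraction"] == pytest.approx(100.0)

    def test_displaced_ligand_is_not(self, dimer6):
        lig = dimer6.ligand.copy()
        lig.translate([0, 50.0, 0])
        ok, diag = check_association(dimer6.receptor, lig, dimer6.contacts,
                                     AssociationCriteria())
        assert not ok
        assert diag["native_contacts"] == 0

    @pytest.mark.parametrize("delta,expected_restored,expected_assoc", [
        (0.15, 2, False),   # tilt leaving exactly 2 contacts within tolerance
        (0.06, 3, True),    # gentler tilt leaves exactly 3
    ])
    def test_threshold_flips_between_two_and_three_contacts(
        self, dimer6, delta, expected_restored, expected_assoc
    ):
        """Constructed poses with exactly 2 vs 3 restored contacts flip the default criterion."""
        # rotate the ligand about the y axis through the first contact column so
        # pair k picks up an extra (7.6 k)^2 * delta under the root, delta = 2(1-cos)
        lig = dimer6.ligand.copy()
        angle = np.arccos(1.0 - delta / 2.0)
        rot = np.array([
            [np.cos(angle), 0.0, np.sin(angle)],
            [0.0, 1.0, 0.0],
            [-np.sin(angle), 0.0, np.cos(angle)],
        ])
        first_contact = dimer6.receptor.sc_positions[0]
        rotate_about(lig, rot, first_contact)

        # independent brute-force count of restored contacts
        r = contact_distances(dimer6.receptor, lig, dimer6.contacts)
        brute = int(np.sum(np.abs(r - dimer6.contacts.r0) < 2.0))
        assert brute == expected_restored

        ok, diag = check_association(dimer6.receptor, lig, dimer6.contacts,
                                     AssociationCriteria(min_native_contacts=3))
        assert diag["native_contacts"] == expected_restored
        assert ok is expected_assoc

    def test_energy_criterion_requires_energy(self, dimer6):
        crit = AssociationCriteria(min_native_contacts=None, max_energy=-1.0)
        with pytest.raises(ValueError, match="energy"):
            check_association(dimer6.receptor, dimer6.ligand, dimer6.contacts, crit)

    def test_conjunctive_criteria(self, dimer6):
        crit = AssociationCriteria(min_native_contacts=3, max_energy=-5.0)
        ok, _ = check_association(dimer6.receptor, dimer6.ligand, dimer6.contacts,
                                  crit, energy=-4.0)
        assert not ok  # contacts pass, energy fails
        ok, _ = check_association(dimer6.receptor, dimer6.ligand, dimer6.contacts,
                                  crit, energy=-6.0)
        assert ok


class TestRunTrajectory:
    def test_bitwise_reproducible(self, funnel_dimer):
        d = funnel_dimer
        ff = HybridForceField(omega=0.6, table=StatPotentialTable(np.full((20, 20), -2.0)))
        config = small_config(n_steps=40, record_rmsd=True)
        a = run_trajectory(d.receptor, d.ligand, ff, d.contacts, config, seed=11)
        b = run_trajectory(d.receptor, d.ligand, ff, d.contacts, config, seed=11)
        np.testing.assert_array_equal(a.energy_trace, b.energy_trace)
        np.testing.assert_array_equal(a.rmsd_trace, b.rmsd_trace)
        np.testing.assert_array_equal(a.final_ligand_pose[0], b.final_ligand_pose[0])
        np.testing.assert_array_equal(a.final_ligand_pose[1], b.final_ligand_pose[1])
        assert a.associated == b.associated

    def test_pure_diffusion_rarely_associates(self, dimer6):
        """With all interactions off, short trajectories in a large box stay apart."""
        ff = HybridForceField(omega=0.0, physics=PhysicsParams(w_alpha=0.0, epsilon_rep=0.0))
        # neutralize electrostatics by zeroing charges via omega=0 + w_alpha=0:
        # the toy carries charges, so keep the default table off and rely on
        # the large box to make association improbable.
        config = small_config(box_edge=100.0, n_steps=30, n_trajectories=30)
        result = run_ensemble(dimer6.receptor, dimer6.ligand, ff, dimer6.contacts, config)
        assert result.probability <= 0.1

    def test_native_start_would_associate_immediately(self, funnel_dimer):
        """check_association at step 0 catches configurations born associated."""
        d = funnel_dimer
        ff = HybridForceField()
        config = small_config(n_steps=5)
        record = run_trajectory(d.receptor, d.ligand, ff, d.contacts, config, seed=0)
        # random initial placements essentially never satisfy the criterion
        assert record.association_step is None or record.association_step >= 0

    def test_trace_lengths_and_termination(self, funnel_dimer):
        d = funnel_dimer
        ff = HybridForceField(omega=0.6, table=StatPotentialTable(np.full((20, 20), -8.0)))
        config = small_config(box_edge=30.0, n_steps=400, record_rmsd=True)
        for seed in range(8):
            r = run_trajectory(d.receptor, d.ligand, ff, d.contacts, config, seed=seed)
            if r.associated:
                assert r.association_step <= config.n_steps
                assert len(r.energy_trace) == r.association_step + 1
                break
        else:
            pytest.skip("no association in 8 seeds (unexpected but tolerated)")

    def test_diagnostics_recorded_when_requested(self, funnel_dimer):
        d = funnel_dimer
        ff = HybridForceField()
        config = small_config(n_steps=20, record_diagnostics=True,
                              terminate_on_association=False)
        r = run_trajectory(d.receptor, d.ligand, ff, d.contacts, config, seed=1)
        assert r.diagnostics is not None
        for key in ("native_contacts", "contact_fraction", "rmsd",
                    "interface_distance", "energy"):
            assert len(r.diagnostics[key]) == 21  # step 0 + 20 steps


def test_confined_attractive_dimer_associates_reliably():
    """Under tight confinement with an attractive interface, most long
    trajectories form the encounter complex."""
    n = 9
    from cgassoc.synthetic_fixtures import ToyDimerSpec, make_toy_dimer

    dimer = make_toy_dimer(ToyDimerSpec(
        n_residues=n, n_contacts=5, seed=1,
        receptor_types=tuple("LEU" if i % 2 == 0 else "SER" for i in range(n)),
        ligand_types=tuple("ILE" if i % 2 == 0 else "THR" for i in range(n)),
    ))
    ff = HybridForceField(omega=0.6, table=StatPotentialTable(np.full((20, 20), -0.5)))
    config = SimulationConfig(box_edge=25.0, n_steps=1500, n_trajectories=30,
                              base_seed=0, record_rmsd=False)
    result = run_ensemble(dimer.receptor, dimer.ligand, ff, dimer.contacts, config)
    assert result.probability >= 0.5


class TestRunEnsemble:
    def test_zero_trajectories_rejected(self, dimer6):
        with pytest.raises(ValueError):
            SimulationConfig(n_trajectories=0)

    def test_seeds_are_base_plus_index(self, funnel_dimer):
        d = funnel_dimer
        ff = HybridForceField()
        config = small_config(n_steps=5, n_trajectories=4, base_seed=100)
        result = run_ensemble(d.receptor, d.ligand, ff, d.contacts, config)
        assert [r.seed for r in result.records] == [100, 101, 102, 103]

    def test_probability_consistent_across_base_seeds(self, funnel_dimer):
        """Two independent ensembles agree within binomial sampling bounds."""
        d = funnel_dimer
        ff = HybridForceField(omega=0.6, table=StatPotentialTable(np.full((20, 20), -6.0)))
        n = 60
        probs = []
        for base in (0, 10_000):
            config = small_config(box_edge=35.0, n_steps=150, n_trajectories=n,
                                  base_seed=base)
            probs.append(run_ensemble(d.receptor, d.ligand, ff, d.contacts, config).probability)
        p_bar = np.mean(probs)
        bound = 4 * np.sqrt(max(p_bar * (1 - p_bar), 1e-4) / n) * np.sqrt(2)
        assert abs(probs[0] - probs[1]) <= bound

    def test_summary_tsv(self, funnel_dimer, tmp_path):
        from cgassoc.kmc_engine import write_ensemble_summary

        d = funnel_dimer
        config = small_config(n_steps=5, n_trajectories=3)
        result = run_ensemble(d.receptor, d.ligand, HybridForceField(), d.contacts, config)
        out = tmp_path / "summary.tsv"
        write_ensemble_summary(result, out)
        lines = out.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0].startswith("seed\t")
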