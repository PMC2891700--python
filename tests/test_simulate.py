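import numpy as np
import pytest

from cgfold import simulate as sim
from cgfold.analysis import radius_of_gyration
from cgfold.fixtures import default_bonded, table2_forcefield, toy_peptide
from cgfold.mapping import build_topology
from cgfold.simulate import (CosinePlanarity, Harmonic, SimulationConfig,
                             SimulationError, System, initial_state,
                             langevin_step, randomize_chain, run)
from cgfold.units import KB


@pytest.fixture(scope="module")
def mixed_system(softcore_mod, scheme_mod):
    seq = ["ALA", "TRP", "GLU", "LYS", "SER", "LEU", "ARG", "THR", "TYR",
           "VAL"]
    topo, X = toy_peptide(seq, "extended", scheme_mod)
    cfg = SimulationConfig(seed=11)
    system = System(topo, softcore_mod, default_bonded(), cfg,
                    reference_positions=X)
    return system, topo, X


@pytest.fixture(scope="module")
def scheme_mod():
    from cgfold.mapping import MappingScheme
    return MappingScheme.default()


@pytest.fixture(scope="module")
def softcore_mod():
    pots, _ = table2_forcefield()
    return pots


class TestComputeForces:
    def test_two_sites_beyond_cutoff(self, softcore_mod, scheme_mod):
        topo = build_topology(["GLY"] * 2, scheme_mod)
        topo.bonds, topo.bond_keys = [], []     # free particles
        topo._excl = set()
        system = System(topo, softcore_mod, default_bonded(),
                        SimulationConfig())
        X = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        F, E = system.compute_forces(X, use_neighbor_list=False)
        assert E["nonbonded"] == 0.0
        np.testing.assert_array_equal(F, 0.0)

    def test_force_at_grid_point_matches_table(self, softcore_mod, scheme_mod):
        topo = build_topology(["GLY"] * 2, scheme_mod)
        topo.bonds, topo.bond_keys = [], []
        topo._excl = set()
        system = System(topo, softcore_mod, default_bonded(),
                        SimulationConfig())
        table = softcore_mod[("backbone", "backbone")]
        i = np.argmin(np.abs(table.r - 0.54))
        d = table.r[i]
        X = np.array([[0.0, 0, 0], [d, 0, 0]])
        F, E = system.compute_forces(X, use_neighbor_list=False)
        assert F[1, 0] == pytest.approx(table.f[i], rel=1e-9)
        assert E["nonbonded"] == pytest.approx(table.V[i], rel=1e-9)

    def test_numerical_gradient_random_configuration(self, mixed_system, rng):
        system, topo, X = mixed_system
        Xr = X + 0.02 * rng.standard_normal(X.shape)
        F, _ = system.compute_forces(Xr, use_neighbor_list=False)
        h = 1e-6
        worst = 0.0
        for i in range(topo.n_sites):
            for d in range(3):
                Xp = Xr.copy()
                Xp[i, d] += h
                Xm = Xr.copy()
                Xm[i, d] -= h
                g = (system.potential_energy(Xp)
                     - system.potential_energy(Xm)) / (2 * h)
                worst = max(worst, abs(-g - F[i, d]))
        assert worst / np.abs(F).max() < 1e-4

    def test_total_force_zero(self, mixed_system, rng):
        system, topo, X = mixed_system
        Xr = X + 0.02 * rng.standard_normal(X.shape)
        F, _ = system.compute_forces(Xr, use_neighbor_list=False)
        assert np.abs(F.sum(axis=0)).max() < 1e-10 * np.abs(F).max()

    def test_excluded_pairs_no_nonbonded(self, softcore_mod, scheme_mod):
        # bring a 1-2 and a 1-3 pair into the attractive well: no energy
        topo = build_topology(["GLY"] * 3, scheme_mod)
        system = System(topo, softcore_mod, default_bonded(),
                        SimulationConfig())
        X = np.array([[0.0, 0, 0], [0.5, 0, 0], [1.0, 0, 0]])
        _, E = system.compute_forces(X, use_neighbor_list=False)
        assert E["nonbonded"] == 0.0

    def test_missing_pair_table_raises(self, scheme_mod, softcore_mod):
        topo = build_topology(["ALA"] * 4, scheme_mod)
        incomplete = {k: v for k, v in softcore_mod.items()
                      if k != ("apolar", "apolar")}
        with pytest.raises(SimulationError, match="missing pair table"):
            System(topo, incomplete, default_bonded(), SimulationConfig())

    def test_inner_wall_counter(self, softcore_mod, scheme_mod):
        topo = build_topology(["GLY"] * 2, scheme_mod)
        topo.bonds, topo.bond_keys = [], []
        topo._excl = set()
        system = System(topo, softcore_mod, default_bonded(),
                        SimulationConfig())
        X = np.array([[0.0, 0, 0], [0.02, 0, 0]])
        system.compute_forces(X, use_neighbor_list=False)
        assert system.tables.wall_hits > 0


class TestLangevinStep:
    def _free_system(self, softcore_mod, scheme_mod, gamma_inv):
        topo = build_topology(["GLY"], scheme_mod)
        system = System(topo, softcore_mod, default_bonded(),
                        SimulationConfig(inverse_friction=gamma_inv))
        return system

    def test_gamma_zero_free_flight(self, softcore_mod, scheme_mod):
        system = self._free_system(softcore_mod, scheme_mod, np.inf)
        state = initial_state(system, np.zeros((1, 3)))
        state.velocities = np.array([[1.0, 0.5, -0.25]])
        rng = np.random.default_rng(0)
        for _ in range(100):
            langevin_step(system, state, rng)
        dt = system.config.timestep
        np.testing.assert_allclose(state.positions,
                                   state.velocities * 100 * dt, atol=1e-12)

    def test_gamma_zero_energy_conservation(self, softcore_mod, scheme_mod):
        topo, X = toy_peptide(["GLY", "GLY"], "extended", scheme_mod)
        cfg = SimulationConfig(inverse_friction=np.inf, temperature=300,
                               seed=3)
        system = System(topo, softcore_mod, default_bonded(), cfg)
        traj = run(system, X, 100_000, stride=2000,
                   rng=np.random.default_rng(5))
        total = np.array([e["total"] for e in traj.energies[1:]])
        drift = np.abs(total - total[0]).max() / abs(total[0])
        assert drift < 1e-4

    def test_equipartition_single_site(self, softcore_mod, scheme_mod):
        # restrained free site: <x^2> per dof = kT/k_restraint
        topo = build_topology(["GLY"], scheme_mod)
        k_r, T = 200.0, 300.0
        cfg = SimulationConfig(temperature=T, restraint_ids=(0,),
                               restraint_k=k_r, inverse_friction=0.5, seed=9)
        system = System(topo, softcore_mod, default_bonded(), cfg,
                        reference_positions=np.zeros((1, 3)))
        rng = np.random.default_rng(77)
        state = initial_state(system, np.zeros((1, 3)), rng=rng)
        xs = []
        kes = []
        for step in range(60_000):
            langevin_step(system, state, rng)
            if step >= 10_000 and step % 10 == 0:
                xs.append(state.positions[0].copy())
                kes.append(state.kinetic_energy())
        xs = np.array(xs)
        x2 = (xs ** 2).mean(axis=0)
        expected = KB * T / k_r
        # 3 sigma with a conservative effective-sample estimate
        tau_steps = 1.0 / (cfg.gamma * cfg.timestep)
        n_eff = len(xs) * 10 / (2 * tau_steps)
        se = expected * np.sqrt(2.0 / n_eff)
        for comp in x2:
            assert abs(comp - expected) < 3 * se
        t_kin = 2 * np.mean(kes) / (3 * KB)
        assert t_kin == pytest.approx(T, rel=0.02)

    def test_non_finite_forces_abort(self, softcore_mod, scheme_mod):
        topo = build_topology(["GLY"], scheme_mod)
        system = System(topo, softcore_mod, default_bonded(),
                        SimulationConfig())
        state = initial_state(system, np.zeros((1, 3)))
        state.forces = np.array([[np.nan, 0, 0]])
        with pytest.raises(SimulationError, match="non-finite"):
            langevin_step(system, state, np.random.default_rng(0))


class TestRun:
    def test_zero_steps_initial_frame_only(self, mixed_system):
        system, topo, X = mixed_system
        traj = run(system, X, 0)
        assert len(traj.frames) == 1
        np.testing.assert_array_equal(traj.frames[0], X)

    def test_same_seed_identical(self, mixed_system):
        system, topo, X = mixed_system
        t1 = run(system, X, 500, stride=100, rng=np.random.default_rng(42))
        t2 = run(system, X, 500, stride=100, rng=np.random.default_rng(42))
        for a, b in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(a, b)

    def test_chain_compacts_at_low_temperature(self, softcore_mod, scheme_mod):
        topo, X = toy_peptide(["ALA"] * 15, "extended", scheme_mod)
        cfg = SimulationConfig(temperature=150.0, seed=7)
        system = System(topo, softcore_mod, default_bonded(), cfg)
        rg0 = radius_of_gyration(X, topo.masses())
        traj = run(system, X, 120_000, stride=5000,
                   rng=np.random.default_rng(7))
        rg_final = radius_of_gyration(traj.frames[-1], topo.masses())
        assert rg_final < rg0

    def test_restrained_backbone_stays_near_start(self, softcore_mod,
                                                  scheme_mod):
        topo, X = toy_peptide(["ALA"] * 8, "extended", scheme_mod)
        bb = tuple(topo.backbone_ids())
        cfg = SimulationConfig(temperature=300.0, seed=5, restraint_ids=bb,
                               restraint_k=1000.0)
        system = System(topo, softcore_mod, default_bonded(), cfg,
                        reference_positions=X)
        traj = run(system, X, 30_000, stride=3000,
                   rng=np.random.default_rng(2))
        disp = np.array(traj.frames)[:, list(bb), :] - X[list(bb)]
        rms = np.sqrt((disp[-3:] ** 2).sum(axis=-1).mean())
        # harmonic estimate: 3 kT / k per site, allow 3x
        bound = 3 * np.sqrt(3 * KB * 300.0 / 1000.0)
        assert rms < bound


class TestRandomizeChain:
    def test_seeds_differ(self, softcore_mod, scheme_mod):
        topo, X = toy_peptide(["ALA"] * 6, "extended", scheme_mod)
        system = System(topo, softcore_mod, default_bonded(),
                        SimulationConfig())
        a = randomize_chain(system, X, 700.0, 3000, seed=1)
        b = randomize_chain(system, X, 700.0, 3000, seed=2)
        assert np.sqrt(((a - b) ** 2).sum(axis=1).mean()) > 0

    def test_no_pair_below_inner_wall(self, softcore_mod, scheme_mod):
        topo, X = toy_peptide(["ALA"] * 6, "extended", scheme_mod)
        system = System(topo, softcore_mod, default_bonded(),
                        SimulationConfig())
        out = randomize_chain(system, X, 700.0, 5000, seed=3)
        excl = topo.exclusion_pairs()
        r_inner = system.tables.r[0]
        for i in range(topo.n_sites):
            for j in range(i + 1, topo.n_sites):
                if (i, j) in excl:
                    continue
                assert np.linalg.norm(out[i] - out[j]) > r_inner

    def test_high_t_expands_vs_low_t(self, softcore_mod, scheme_mod):
        topo, X = toy_peptide(["ALA"] * 10, "extended", scheme_mod)
        system = System(topo, softcore_mod, default_bonded(),
                        SimulationConfig(seed=3))
        masses = topo.masses()

        def mean_rg(T, seed):
            traj = run(system, X, 60_000, stride=2000, temperature=T,
                       rng=np.random.default_rng(seed))
            return np.mean([radius_of_gyration(f, masses)
                            for f in traj.frames[6:]])

        assert mean_rg(700.0, 4) > mean_rg(120.0, 4)


class TestThermostatMultiWell:
    def test_kinetic_temperature_on_toy_chain(self, mixed_system):
        system, topo, X = mixed_system
        T = 250.0
        rng = np.random.default_rng(13)
        state = initial_state(system, X, temperature=T, rng=rng)
        temps = []
        for step in range(30_000):
            langevin_step(system, state, rng, temperature=T)
            if step >= 5_000 and step % 20 == 0:
                temps.append(state.kinetic_temperature())
        assert np.mean(temps) == pytest.approx(T, rel=0.03)
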