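"""Mass-spring dynamics: force law, integration, statics, dissipation."""
import numpy as np
import pytest

import eyemodel as em
from eyemodel.errors import InvalidArgumentError
from eyemodel.masspring import unique_edges


def two_particle_system(gap=1.0, rest=1.0, k=100.0, d=0.0,
                        fixed=(False, False)):
    return em.MassSpringSystem(
        positions=np.array([[0.0, 0.0, 0.0], [gap, 0.0, 0.0]]),
        velocities=np.zeros((2, 3)), masses=np.ones(2),
        damping=np.full(2, d), springs=np.array([[0, 1]]),
        rest_lengths=np.array([rest]), stiffness=k,
        fixed=np.array(fixed))


def chain_system(n_springs, k=100.0, d=20.0):
    n = n_springs + 1
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n, dtype=float)
    fixed = np.zeros(n, bool)
    fixed[0] = True
    return em.MassSpringSystem(
        positions=pos, velocities=np.zeros((n, 3)), masses=np.ones(n),
        damping=np.full(n, d), springs=np.column_stack(
            [np.arange(n_springs), np.arange(1, n)]),
        rest_lengths=np.ones(n_springs), stiffness=k, fixed=fixed)


class TestBuildSystem:
    def test_counts_and_masses(self, lens_mesh):
        system = em.build_system(lens_mesh, total_mass=2.0)
        assert system.n_particles == 114
        assert len(system.springs) == len(unique_edges(lens_mesh.faces))
        assert system.masses.sum() == pytest.approx(2.0, abs=1e-12)

    def test_initial_net_force_zero(self, lens_mesh):
        system = em.build_system(lens_mesh)
        assert np.abs(em.spring_forces(system)).max() <= 1e-9

    def test_coincident_vertices_rejected(self, lens_mesh):
        bad = em.RevolvedMesh(
            np.vstack([lens_mesh.vertices[:1], lens_mesh.vertices]),
            np.array([[0, 1, 2]]), units="mm")
        with pytest.raises(InvalidArgumentError):
            em.build_system(bad)


class TestSpringForces:
    def test_rest_length_zero_force(self):
        f = em.spring_forces(two_particle_system())
        assert np.abs(f).max() == 0.0

    def test_stretched_hooke_equal_and_opposite(self):
        delta = 0.25
        system = two_particle_system(gap=1.0 + delta)
        f = em.spring_forces(system)
        assert f[0, 0] == pytest.approx(100.0 * delta)
        assert np.allclose(f[0], -f[1])

    def test_internal_forces_sum_to_zero_random_system(self):
        rng = np.random.default_rng(0)
        n = 30
        springs = np.array([[i, j] for i in range(n) for j in range(i + 1, n)
                            if rng.random() < 0.2])
        system = em.MassSpringSystem(
            positions=rng.normal(size=(n, 3)),
            velocities=np.zeros((n, 3)), masses=np.ones(n),
            damping=np.zeros(n), springs=springs,
            rest_lengths=rng.uniform(0.5, 2.0, len(springs)),
            stiffness=50.0)
        assert np.abs(em.spring_forces(system).sum(axis=0)).max() <= 1e-9


class TestStep:
    def test_quiescent_state_unchanged(self):
        system = two_particle_system()
        out = em.step(system, 1e-3)
        assert np.array_equal(out.positions, system.positions)
        assert np.array_equal(out.velocities, system.velocities)

    def test_constant_force_velocity_recursion(self):
        """Semi-implicit Euler: v_n = n dt f / m exactly for a free
        particle under constant force."""
        system = em.MassSpringSystem(
            positions=np.zeros((2, 3)) + [[0, 0, 0], [10, 0, 0]],
            velocities=np.zeros((2, 3)), masses=np.array([2.0, 1.0]),
            damping=np.zeros(2), springs=np.zeros((0, 2), dtype=int),
            rest_lengths=np.zeros(0), stiffness=100.0)
        system.f_ext[0] = [0.3, 0.0, 0.0]
        dt, n = 1e-3, 50
        for _ in range(n):
            system = em.step(system, dt)
        assert system.velocities[0, 0] == pytest.approx(n * dt * 0.3 / 2.0,
                                                        abs=1e-15)

    def test_stability_bound_enforced(self):
        system = two_particle_system()
        with pytest.raises(InvalidArgumentError):
            em.step(system, dt=1.0)  # bound is 2 sqrt(1/100) = 0.2

    def test_pinned_particles_bit_exact(self):
        system = two_particle_system(gap=1.5, fixed=(True, False))
        p0 = system.positions[0].copy()
        for _ in range(100):
            system = em.step(system, 1e-2)
        assert np.array_equal(system.positions[0], p0)
        assert np.array_equal(system.velocities[0], np.zeros(3))

    def test_single_spring_static_displacement(self):
        """Converged pulled end sits at rest length + F / k_s."""
        system = two_particle_system(d=20.0, fixed=(True, False))
        F = 0.5
        system.f_ext[1] = [F, 0.0, 0.0]
        final, _ = em.simulate(system, n_steps=20000, dt=0.01,
                               record_every=20000)
        assert final.positions[1, 0] == pytest.approx(1.0 + F / 100.0,
                                                      abs=1e-6)


class TestSimulate:
    def test_damped_kinetic_energy_decays(self, lens_mesh):
        system = em.build_system(lens_mesh, total_mass=1.0, stiffness=100.0,
                                 damping=1.0)
        rng = np.random.default_rng(0)
        system.positions += 0.05 * rng.normal(size=system.positions.shape)
        dt = 0.25 * system.stable_dt()
        ke = []
        for _ in range(4000):
            system = em.step(system, dt, in_place=True)
            ke.append(system.kinetic_energy())
        assert ke[-1] < 0.01 * max(ke)

    def test_mechanical_energy_non_increasing_with_damping(self, lens_mesh):
        system = em.build_system(lens_mesh, total_mass=1.0, stiffness=100.0,
                                 damping=0.5)
        rng = np.random.default_rng(1)
        system.positions += 0.02 * rng.normal(size=system.positions.shape)
        dt = 0.2 * system.stable_dt()
        energies = []
        for k in range(1000):
            system = em.step(system, dt, in_place=True)
            if k % 100 == 0:
                energies.append(system.kinetic_energy()
                                + system.elastic_energy())
        e = np.array(energies)
        assert np.all(np.diff(e) <= 1e-8 * max(e[0], 1.0))

    def test_momentum_conservation_free_system(self):
        system = two_particle_system(gap=1.3)  # stretched, undamped, free
        dt = 0.1 * system.stable_dt()
        drift = []
        for _ in range(500):
            system = em.step(system, dt, in_place=True)
            p = (system.masses[:, None] * system.velocities).sum(axis=0)
            drift.append(np.abs(p).max())
        v_scale = np.abs(system.velocities).max() or 1.0
        assert max(drift) <= 1e-10 * system.masses.sum() * v_scale * 500

    @pytest.mark.parametrize("n_springs", [2, 5, 10])
    def test_serial_chain_matches_analytic_statics(self, n_springs):
        """End load F on a chain: node i displaces by i * F / k_s."""
        system = chain_system(n_springs)
        F = 0.2
        system.f_ext[-1] = [F, 0.0, 0.0]
        final, _ = em.simulate(system, n_steps=40000, dt=0.01,
                               record_every=40000)
        disp = final.positions[:, 0] - np.arange(n_springs + 1)
        expect = np.arange(n_springs + 1) * F / 100.0
        scale = max(expect.max(), 1e-12)
        assert np.abs(disp - expect).max() / scale <= 1e-4

    def test_lens_stretch_and_compression_signs(self):
        """Outward polar pull lengthens the lens axis; inward push
        shortens it, with the equator ring pinned."""
        mesh = em.generate_biconvex_mesh(15, 16, 4.0, 10.0)
        equator = np.argsort(np.abs(mesh.vertices[:, 0]))[:16]
        extents = {}
        for sign in (+1.0, -1.0):
            system = em.build_system(mesh, total_mass=1.0, stiffness=100.0,
                                     damping=2.0, fixed=equator)
            f = np.zeros_like(system.positions)
            f[0, 0] = -0.5 * sign
            f[-1, 0] = 0.5 * sign
            dt = 0.2 * system.stable_dt()
            final, _ = em.simulate(system, n_steps=4000, dt=dt,
                                   record_every=4000, f_ext=f)
            extents[sign] = final.positions[-1, 0] - final.positions[0, 0]
        initial = mesh.vertices[-1, 0] - mesh.vertices[0, 0]
        assert extents[+1.0] > initial > extents[-1.0]
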