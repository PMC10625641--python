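"""Integrator contracts: velocity statistics, fluctuation-dissipation,
Boltzmann sampling, determinism and dissipativity."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import dnadyn as dd
from dnadyn.constants import base_pair_mass, kBT, node_inertia
from dnadyn.hydrodynamics import FrictionMatrix, SolventModel, self_mobility_block
from dnadyn.langevin import (
    GJFIntegrator,
    SimulationProtocol,
    draw_random_force,
    gjf_step,
    init_velocities,
    run_simulation,
)
from dnadyn.mechanics import MassMatrix
from dnadyn.model import State


def _free_nodes(n):
    """MassMatrix + diagonal FrictionMatrix for n independent bp-like nodes."""
    m = base_pair_mass("N")
    inert = node_inertia(m)
    mass = MassMatrix(np.tile(np.concatenate([[m] * 3, inert]), n))
    blk = self_mobility_block(1.1, SolventModel())
    friction = FrictionMatrix(np.tile(1.0 / np.diag(blk), n))
    return mass, friction


def _unit_state(n):
    return State(np.zeros((n, 3)), np.tile([0, 0, 0, 1.0], (n, 1)), np.zeros(6 * n))


class TestInitVelocities:
    def test_variance_matches_equipartition(self, rng):
        mass, _ = _free_nodes(20000)
        v = init_velocities(mass, 300.0, rng)
        var = (v**2).reshape(-1, 6)
        target = kBT() / mass.diagonal.reshape(-1, 6)
        ratio = var.mean(axis=0) / target[0]
        np.testing.assert_allclose(ratio, 1.0, atol=0.02)

    def test_zero_mean(self, rng):
        mass, _ = _free_nodes(20000)
        v = init_velocities(mass, 300.0, rng)
        se = np.std(v) / np.sqrt(v.size)
        assert abs(v.mean()) < 3 * se

    def test_zero_temperature(self, rng):
        mass, _ = _free_nodes(5)
        assert np.all(init_velocities(mass, 0.0, rng) == 0.0)


class TestRandomForce:
    def test_diagonal_covariance(self, rng):
        mass, friction = _free_nodes(2000)
        dt = 5.0  # ps
        draws = np.stack([draw_random_force(friction, dt, 300.0, rng) for _ in range(10)])
        var = (draws**2).reshape(-1, 6 * 2000).mean(axis=0).reshape(-1, 6)
        target = 2 * kBT() * friction.matrix.reshape(-1, 6) / (dt * 1e-3)
        np.testing.assert_allclose(var.mean(axis=0) / target.mean(axis=0), 1.0, atol=0.02)

    def test_cross_covariance(self, rng):
        z = np.array([[2.0, 0.8], [0.8, 1.0]])
        xi = np.linalg.inv(z)
        friction = FrictionMatrix(z, np.linalg.cholesky(xi))
        dt = 5.0
        draws = np.stack(
            [draw_random_force(friction, dt, 300.0, rng) for _ in range(120000)]
        )
        cov01 = np.mean(draws[:, 0] * draws[:, 1])
        target = 2 * kBT() * z[0, 1] / (dt * 1e-3)
        assert cov01 == pytest.approx(target, rel=0.05)

    def test_zero_temperature(self, rng):
        _, friction = _free_nodes(3)
        assert np.all(draw_random_force(friction, 5.0, 0.0, rng) == 0.0)


class TestGJFStep:
    def test_deterministic_velocity_decay(self, rng):
        """Zero force, T = 0: velocity decays by the exact GJF factor a."""
        n = 1
        m, gamma, dt = 1.0, 18.45, 5e-3
        mass = MassMatrix(np.full(6, m))
        friction = FrictionMatrix(np.full(6, gamma))
        st = _unit_state(n)
        st.velocities = np.full(6, 2.0)
        out = gjf_step(st, lambda s: np.zeros(6), mass, friction, 5.0, 0.0, rng)
        a = (1 - gamma * dt / (2 * m)) / (1 + gamma * dt / (2 * m))
        np.testing.assert_allclose(out.velocities, 2.0 * a, rtol=1e-12)

    @pytest.mark.parametrize("dt_ps", [5.0, 20.0])
    def test_harmonic_boltzmann_any_dt(self, dt_ps):
        """<x^2> = kBT/k within 2% at 5 and 20 ps - the GJF hallmark."""
        n, k, gamma = 1500, 10.0, 18.45
        mass = MassMatrix(np.ones(6 * n))
        friction = FrictionMatrix(np.full(6 * n, gamma))
        integ = GJFIntegrator(mass, friction, dt_ps)
        rng = np.random.default_rng(99)
        st = _unit_state(n)

        def force(s):
            f = np.zeros((n, 6))
            f[:, 0:3] = -k * s.positions
            return f.reshape(-1)

        fcur = None
        acc = []
        n_steps = 3500
        for i in range(n_steps):
            st, fcur = integ.step(st, force, 300.0, rng, f_current=fcur)
            if i > n_steps // 3:
                acc.append(np.mean(st.positions**2))
        assert np.mean(acc) / (kBT() / k) == pytest.approx(1.0, abs=0.02)

    def test_flat_potential_einstein_relation(self):
        """MSD slope 2D per DOF with D = kBT/zeta on a flat potential."""
        n, gamma = 4000, 18.45
        mass, _ = _free_nodes(n)
        friction = FrictionMatrix(np.full(6 * n, gamma))
        integ = GJFIntegrator(mass, friction, 5.0)
        rng = np.random.default_rng(17)
        st = _unit_state(n)
        zero = lambda s: np.zeros(6 * n)
        fcur = None
        ts, msd = [], []
        for i in range(120):
            st, fcur = integ.step(st, zero, 300.0, rng, f_current=fcur)
            if (i + 1) % 20 == 0:
                ts.append(st.time)
                msd.append(np.mean(st.positions[:, 0] ** 2))
        slope = np.polyfit(ts, msd, 1)[0]
        assert slope / (2 * kBT() / gamma) == pytest.approx(1.0, abs=0.05)

    def test_dissipative_at_zero_temperature(self):
        """T = 0: elastic + kinetic energy is non-increasing step to step."""
        from dnadyn.mechanics import apply_increment

        s = dd.build_duplex(8)
        rng = np.random.default_rng(3)
        st = apply_increment(s.reference_state(), rng.normal(scale=0.02, size=48))
        proto = SimulationProtocol(
            dt_ps=0.4, n_steps=400, temperature=0.0, rng_seed=1, output_stride=20
        )
        traj = run_simulation(s, st, proto)
        etot = traj.energies["elastic"] + traj.energies["kinetic"]
        assert np.all(np.diff(etot) <= 1e-9)


class TestRunSimulation:
    def test_same_seed_bitwise_identical(self):
        s = dd.build_duplex(6)
        proto = SimulationProtocol(dt_ps=0.4, n_steps=300, rng_seed=11, output_stride=50)
        t1 = run_simulation(s, s.reference_state(), proto)
        t2 = run_simulation(s, s.reference_state(), proto)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.quaternions, t2.quaternions)
        for k in t1.energies:
            np.testing.assert_array_equal(t1.energies[k], t2.energies[k])

    def test_different_seed_differs(self):
        s = dd.build_duplex(6)
        p1 = SimulationProtocol(dt_ps=0.4, n_steps=200, rng_seed=11, output_stride=50)
        p2 = SimulationProtocol(dt_ps=0.4, n_steps=200, rng_seed=12, output_stride=50)
        t1 = run_simulation(s, s.reference_state(), p1)
        t2 = run_simulation(s, s.reference_state(), p2)
        assert not np.array_equal(t1.positions[-1], t2.positions[-1])

    def test_timestamps_strictly_increasing(self, thermal_duplex):
        _, traj, _ = thermal_duplex
        assert np.all(np.diff(traj.times) > 0)

    def test_equipartition_elastic_energy(self, thermal_duplex):
        """Mean elastic energy = (internal DOFs / 2) kBT within 10%."""
        s, traj, burn = thermal_duplex
        n_int = 6 * s.n_nodes - 6
        mean_e = traj.energies["elastic"][burn:].mean()
        assert mean_e / (0.5 * n_int * kBT()) == pytest.approx(1.0, abs=0.10)

    def test_quaternions_stay_normalized(self, thermal_duplex):
        _, traj, _ = thermal_duplex
        norms = np.linalg.norm(traj.quaternions[-1], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_ion_schedule_lookup(self):
        from dnadyn.interactions import IonCondition

        proto = SimulationProtocol(
            dt_ps=5.0,
            n_steps=10,
            ion_schedule=[(1.0, IonCondition(mg_mM=25.0)), (2.0, IonCondition(mg_mM=5.0))],
        )
        assert proto.ion_at(0.5).mg_mM == 25.0
        assert proto.ion_at(1.5).mg_mM == 5.0
        assert proto.ion_at(99.0).mg_mM == 5.0  # last segment persists
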