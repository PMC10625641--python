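"""Step-parameter kernel, elastic forces, mass matrix and minimizer."""

import copy

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import dnadyn as dd
from dnadyn.constants import kBT
from dnadyn.interactions import IonCondition
from dnadyn.mechanics import (
    MinimizationError,
    StepGeometryError,
    apply_increment,
    assemble_elastic_forces,
    assemble_mass_matrix,
    compute_step_parameters,
    elastic_element_force,
    elastic_energy,
    static_minimize,
    step_parameters_of_state,
)


def _transformed(node, rot, shift):
    out = copy.deepcopy(node)
    out.position = rot.apply(node.position) + shift
    out.quaternion = (rot * Rotation.from_quat(node.quaternion)).as_quat()
    return out


class TestStepParameters:
    def test_pure_rise(self, duplex8):
        a = copy.deepcopy(duplex8.nodes[0])
        b = copy.deepcopy(duplex8.nodes[0])
        b.position = a.position + np.array([0.0, 0.0, 0.34])
        p = compute_step_parameters(a, b)
        np.testing.assert_allclose(p.as_array(), [0, 0, 0.34, 0, 0, 0], atol=1e-12)

    def test_ideal_duplex_step(self, duplex8):
        p = compute_step_parameters(duplex8.nodes[0], duplex8.nodes[1])
        np.testing.assert_allclose(p.as_array(), [0, 0, 0.34, 0, 0, 34.3], atol=1e-9)

    @given(seed=st.integers(0, 10_000))
    def test_rigid_transform_invariance(self, seed, duplex8):
        rng = np.random.default_rng(seed)
        rot = Rotation.random(rng=rng)
        shift = rng.normal(scale=10.0, size=3)
        a, b = duplex8.nodes[3], duplex8.nodes[4]
        p0 = compute_step_parameters(a, b).as_array()
        p1 = compute_step_parameters(
            _transformed(a, rot, shift), _transformed(b, rot, shift)
        ).as_array()
        np.testing.assert_allclose(p1, p0, atol=1e-10)

    def test_antiparallel_degenerate(self, duplex8):
        a = copy.deepcopy(duplex8.nodes[0])
        b = copy.deepcopy(duplex8.nodes[0])
        b.quaternion = (
            Rotation.from_euler("x", 180, degrees=True) * Rotation.from_quat(a.quaternion)
        ).as_quat()
        b.position = a.position + np.array([0.0, 0.0, 0.34])
        with pytest.raises(StepGeometryError):
            compute_step_parameters(a, b)

    def test_scaled_quaternion_still_proper(self, duplex8):
        # quaternions are normalized into proper triads; parameters stay finite
        a = copy.deepcopy(duplex8.nodes[0])
        a.quaternion = np.array([0.1, 0.2, 0.3, 0.4]) * 3.0
        p = compute_step_parameters(a, duplex8.nodes[1])
        assert np.isfinite(p.as_array()).all()


class TestMassMatrix:
    def test_total_mass_conserved(self, duplex8):
        m = assemble_mass_matrix(duplex8)
        assert m.total_mass() == pytest.approx(sum(n.mass for n in duplex8.nodes))

    def test_uniform_duplex_entries(self, duplex8):
        m = assemble_mass_matrix(duplex8)
        trans = m.diagonal.reshape(-1, 6)[:, 0:3]
        assert np.all(trans == trans[0, 0])

    def test_empty_structure(self):
        from dnadyn.model import Structure

        with pytest.raises(ValueError):
            assemble_mass_matrix(Structure([], []))


class TestElementForces:
    def test_zero_at_intrinsic_geometry(self, duplex8):
        st0 = duplex8.reference_state()
        f = elastic_element_force(duplex8.elements[0], st0, duplex8)
        np.testing.assert_allclose(f, 0.0, atol=1e-8)

    def test_restoring_axial_force(self, duplex8):
        st0 = duplex8.reference_state()
        delta = 1e-4
        st0.positions[1:, 2] += delta  # stretch the first step only
        f = elastic_element_force(duplex8.elements[0], st0, duplex8)
        k_rise = duplex8.elements[0].stiffness[2, 2]
        assert f[8] == pytest.approx(-k_rise * delta, rel=1e-3)  # node b, z force
        assert f[2] == pytest.approx(+k_rise * delta, rel=1e-3)

    def test_third_law_random_states(self, duplex8, rng):
        st0 = duplex8.reference_state()
        for _ in range(5):
            st = apply_increment(st0, rng.normal(scale=0.05, size=48))
            f = elastic_element_force(duplex8.elements[2], st, duplex8)
            np.testing.assert_allclose(f[0:3] + f[6:9], 0.0, atol=1e-9)


class TestAssembledForces:
    def test_unstressed_builders(self):
        for s in (dd.build_duplex(6), dd.build_bundle(2, "square", 16, 8)):
            f, e = assemble_elastic_forces(s, s.reference_state())
            assert np.max(np.abs(f)) < 1e-4
            assert e == pytest.approx(0.0, abs=1e-9)

    def test_rigid_rotation_invariance(self, duplex8):
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True)
        st = duplex8.reference_state()
        st.positions = rot.apply(st.positions)
        st.quaternions = (rot * st.rotations()).as_quat()
        f, e = assemble_elastic_forces(duplex8, st)
        assert np.max(np.abs(f)) < 1e-8
        assert e == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("scale", [0.02, 0.08])
    def test_gradient_consistency(self, duplex8, rng, scale):
        """Analytic-path forces match central differences of the energy."""
        st0 = duplex8.reference_state()
        h = 1e-6
        for _ in range(10):
            st = apply_increment(st0, rng.normal(scale=scale, size=48))
            f, _ = assemble_elastic_forces(duplex8, st)
            g = np.empty_like(f)
            for j in range(48):
                e = np.zeros(48)
                e[j] = h
                g[j] = (
                    elastic_energy(duplex8, apply_increment(st, e))
                    - elastic_energy(duplex8, apply_increment(st, -e))
                ) / (2 * h)
            assert np.max(np.abs(f + g)) / np.max(np.abs(g)) < 1e-5

    def test_zero_net_force_and_torque(self, duplex8, rng):
        st0 = duplex8.reference_state()
        for _ in range(10):
            st = apply_increment(st0, rng.normal(scale=0.1, size=48))
            f, _ = assemble_elastic_forces(duplex8, st)
            fr = f.reshape(-1, 6)
            np.testing.assert_allclose(fr[:, 0:3].sum(axis=0), 0.0, atol=1e-9)
            torque = fr[:, 3:6].sum(axis=0) + np.cross(
                st.positions, fr[:, 0:3]
            ).sum(axis=0)
            np.testing.assert_allclose(torque, 0.0, atol=1e-9)

    def test_energy_nonnegative_zero_iff_intrinsic(self, duplex8, rng):
        st0 = duplex8.reference_state()
        assert elastic_energy(duplex8, st0) == pytest.approx(0.0, abs=1e-12)
        st = apply_increment(st0, rng.normal(scale=0.05, size=48))
        assert elastic_energy(duplex8, st) > 0.0

    def test_switch_as_built_stress_free(self):
        s = dd.build_switch_toy(16, 1)
        f, e = assemble_elastic_forces(s, s.reference_state())
        assert np.max(np.abs(f)) < 1e-3
        assert e < 1e-8


class TestStepParametersOfState:
    def test_matches_per_element(self, duplex8, rng):
        st = apply_increment(duplex8.reference_state(), rng.normal(scale=0.05, size=48))
        batch = step_parameters_of_state(duplex8, st, ("step",))
        one = compute_step_parameters(
            _node_at(duplex8, st, 2), _node_at(duplex8, st, 3)
        ).as_array()
        np.testing.assert_allclose(batch[2], one, atol=1e-10)


def _node_at(structure, state, i):
    out = copy.deepcopy(structure.nodes[i])
    out.position = state.positions[i]
    out.quaternion = state.quaternions[i]
    return out


class TestStaticMinimize:
    def test_already_minimal(self, duplex8):
        st = static_minimize(duplex8, None, tol=1e-3)
        np.testing.assert_allclose(st.positions, duplex8.reference_state().positions)

    def test_perturbed_twist_relaxes(self):
        s = dd.build_duplex(6)
        st0 = s.reference_state()
        du = np.zeros(36)
        du[3 * 6 + 5] = np.radians(5.0)  # twist node 3 by 5 degrees
        st = apply_increment(st0, du)
        assert elastic_energy(s, st) > 0.1
        out = static_minimize(s, None, tol=1e-4, state=st)
        assert elastic_energy(s, out) < 1e-6

    def test_deterministic(self):
        s = dd.build_duplex(6)
        st0 = apply_increment(s.reference_state(), np.full(36, 0.01))
        a = static_minimize(s, None, tol=1e-4, state=st0)
        b = static_minimize(s, None, tol=1e-4, state=st0)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_unbound_repulsion_fails(self):
        from dnadyn.model import Structure

        d1 = dd.build_duplex(4)
        d2 = dd.build_duplex(4, origin=np.array([2.0, 0.0, 0.0]), id_offset=4)
        s = Structure(d1.nodes + d2.nodes, d1.elements + d2.elements)
        s.add_bonded_exclusions()
        with pytest.raises(MinimizationError):
            static_minimize(s, IonCondition(mg_mM=5.0), tol=1e-8, max_iter=150)
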