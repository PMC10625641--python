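"""Mass matrix, base-pair step geometry kernel and elastic internal forces.

The step-parameter kernel implements the CEHS/mid-step-triad construction
used by 3DNA: the relative rotation between two base-pair frames is split
into a bend of magnitude Gamma about the hinge axis (z_a x z_b) and a twist
about the mid-step z axis; tilt and roll are the components of the bend
vector on the mid-step x and y axes, and shift/slide/rise are the components
of the displacement in the mid-step frame.

Elastic element energies are E = 1/2 dq^T K dq in the deviation of the six
step parameters from the element's intrinsic geometry (angles wrapped to
(-180, 180] degrees, taken in radians for the energy).  Forces are obtained
by central differences in the six *relative-pose* coordinates of each
element, then mapped to the twelve nodal generalized forces through exact
kinematic relations - so Newton's third law and zero net force/torque hold
to machine precision by construction, independent of finite-difference
error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import _kernels
from .model import BasePairNode, Element, State, Structure

_FD_STEP = 1e-6  # nm / rad, central-difference step for element gradients
_EZ = np.array([0.0, 0.0, 1.0])
_ROT_P = Rotation.from_rotvec(_FD_STEP * np.eye(3)).as_matrix()
_ROT_M = Rotation.from_rotvec(-_FD_STEP * np.eye(3)).as_matrix()


class StepGeometryError(ValueError):
    """Raised when the step decomposition is degenerate (antiparallel frames)."""


@dataclass
class StepParameters:
    """Six relative rigid-body coordinates of a base-pair step."""

    shift: float  # nm
    slide: float  # nm
    rise: float  # nm
    tilt: float  # degrees
    roll: float  # degrees
    twist: float  # degrees

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist]
        )


@dataclass
class MassMatrix:
    """Diagonal 6N generalized mass matrix (m, m, m, I1, I2, I3 per node)."""

    diagonal: np.ndarray  # (6N,)

    @property
    def n_nodes(self) -> int:
        return self.diagonal.size // 6

    def total_mass(self) -> float:
        return float(self.diagonal.reshape(-1, 6)[:, 0].sum())


# ---------------------------------------------------------------------------
# step-parameter kernel (batched over element pairs)
# ---------------------------------------------------------------------------


def _normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    return v / np.linalg.norm(v, axis=axis, keepdims=True)


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty(np.broadcast(a, b).shape)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def _dot(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (
        a[..., 0] * b[..., 0] + a[..., 1] * b[..., 1] + a[..., 2] * b[..., 2]
    )


def _rodrigues(v: np.ndarray, axis: np.ndarray, cos_t, sin_t) -> np.ndarray:
    """Rotate vector(s) v about unit axis by the angle given as (cos, sin)."""
    c = cos_t[..., None]
    s = sin_t[..., None]
    return v * c + _cross(axis, v) * s + axis * (_dot(axis, v) * (1.0 - cos_t))[..., None]


def step_parameters_rel(r_rel: np.ndarray, d_loc: np.ndarray) -> np.ndarray:
    """Step parameters from relative pose(s), batched.

    ``r_rel``: (..., 3, 3) rotation of frame b expressed in frame a;
    ``d_loc``: (..., 3) displacement of b's origin in frame a coordinates.
    Returns (..., 6): shift, slide, rise [nm], tilt, roll, twist [deg].
    """
    r_rel = np.asarray(r_rel, dtype=float)
    d_loc = np.asarray(d_loc, dtype=float)
    z2 = r_rel[..., :, 2]
    cosg = np.clip(z2[..., 2], -1.0, 1.0)
    if np.any(cosg < -0.999999):
        raise StepGeometryError("antiparallel frames: step decomposition degenerate")

    # hinge axis ez x z2; fall back to ex when the z axes coincide
    hinge = np.empty(z2.shape)
    hinge[..., 0] = -z2[..., 1]
    hinge[..., 1] = z2[..., 0]
    hinge[..., 2] = 0.0
    hnorm = np.sqrt(hinge[..., 0] ** 2 + hinge[..., 1] ** 2)
    gamma = np.arctan2(hnorm, cosg)  # stable for small bends
    tiny = hnorm < 1e-12
    if np.any(tiny):
        hinge[tiny] = (1.0, 0.0, 0.0)
        hnorm = np.where(tiny, 1.0, hnorm)
    hinge /= hnorm[..., None]

    # rotate frame a by +gamma/2 and frame b by -gamma/2 about the hinge
    ch = np.cos(0.5 * gamma)
    sh = np.sin(0.5 * gamma)
    # x_a = R(hinge, +g/2) ex ; z_m = R(hinge, +g/2) ez, written out directly
    hx, hy = hinge[..., 0], hinge[..., 1]
    x_a = np.empty(z2.shape)
    x_a[..., 0] = ch + hx * hx * (1.0 - ch)
    x_a[..., 1] = hy * hx * (1.0 - ch)
    x_a[..., 2] = -hy * sh
    z_m = np.empty(z2.shape)
    z_m[..., 0] = hy * sh
    z_m[..., 1] = -hx * sh
    z_m[..., 2] = ch
    x_b = _rodrigues(r_rel[..., :, 0], hinge, ch, -sh)

    twist = np.arctan2(_dot(_cross(x_a, x_b), z_m), _dot(x_a, x_b))

    x_m = x_a + x_b
    x_norm = np.sqrt(_dot(x_m, x_m))
    if np.any(x_norm < 1e-6):
        raise StepGeometryError(
            "twist at 180 degrees: mid-step frame bisector degenerate"
        )
    x_m /= x_norm[..., None]
    y_m = _cross(z_m, x_m)

    deg = 180.0 / np.pi
    out = np.empty(z2.shape[:-1] + (6,))
    out[..., 0] = _dot(d_loc, x_m)
    out[..., 1] = _dot(d_loc, y_m)
    out[..., 2] = _dot(d_loc, z_m)
    out[..., 3] = gamma * _dot(hinge, x_m) * deg
    out[..., 4] = gamma * _dot(hinge, y_m) * deg
    out[..., 5] = twist * deg
    return out


def compute_step_parameters(node_a: BasePairNode, node_b: BasePairNode) -> StepParameters:
    """3DNA-convention step parameters between two base-pair frames."""
    ra = node_a.orientation
    rb = node_b.orientation
    for name, r in (("a", ra), ("b", rb)):
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError(f"frame {name} is not orthonormal")
    d_loc = ra.T @ (np.asarray(node_b.position) - np.asarray(node_a.position))
    r_rel = ra.T @ rb
    p = step_parameters_rel(r_rel, d_loc)
    return StepParameters(*p)


# ---------------------------------------------------------------------------
# compiled elastic element set
# ---------------------------------------------------------------------------


def _wrap_deg(angles: np.ndarray) -> np.ndarray:
    """Wrap angle deviations to (-180, 180] degrees."""
    return angles - 360.0 * np.floor((angles + 180.0) / 360.0)


class ElasticSet:
    """Structure's elastic elements compiled to flat arrays for fast assembly."""

    def __init__(self, structure: Structure):
        idx = structure.node_index()
        ia, ib, q0, kk = [], [], [], []
        sa, sb, s_k, s_rest = [], [], [], []
        for e in structure.elements:
            if e.kind in ("step", "crossover"):
                ia.append(idx[e.node_ids[0]])
                ib.append(idx[e.node_ids[1]])
                q0.append(np.asarray(e.intrinsic_geometry, dtype=float))
                kscaled = np.asarray(e.stiffness, dtype=float).copy()
                kk.append(kscaled)
            elif e.kind == "ssdna":
                sa.append(idx[e.node_ids[0]])
                sb.append(idx[e.node_ids[1]])
                s_k.append(float(np.asarray(e.stiffness)[2, 2]))
                s_rest.append(float(np.asarray(e.intrinsic_geometry)[2]))
        self.ia = np.array(ia, dtype=int)
        self.ib = np.array(ib, dtype=int)
        self.q0 = np.array(q0).reshape(-1, 6)
        self.kmat = np.array(kk).reshape(-1, 6, 6)
        self.ss_a = np.array(sa, dtype=int)
        self.ss_b = np.array(sb, dtype=int)
        self.ss_k = np.array(s_k)
        self.ss_rest = np.array(s_rest)
        self.n_step = self.ia.size
        self.n_nodes = structure.n_nodes

    # -- energy ----------------------------------------------------------

    def step_energies(self, r_rel: np.ndarray, d_loc: np.ndarray) -> np.ndarray:
        """Element energies for a batch sharing the compiled (q0, K) tables.

        ``r_rel``/``d_loc`` may carry extra leading batch axes of shape
        (..., n_step, 3, 3) / (..., n_step, 3).
        """
        q = step_parameters_rel(r_rel, d_loc)
        dq = q - self.q0
        dq[..., 3:] = _wrap_deg(dq[..., 3:])
        dq[..., 3:] *= np.pi / 180.0
        return 0.5 * np.einsum("...i,...ij,...j->...", dq, self.kmat, dq)

    def relative_pose(self, state: State) -> tuple[np.ndarray, np.ndarray]:
        mats = state.triads()
        ra = mats[self.ia]
        rb = mats[self.ib]
        dx = state.positions[self.ib] - state.positions[self.ia]
        d_loc = np.einsum("eji,ej->ei", ra, dx)  # ra^T dx
        r_rel = np.einsum("eji,ejk->eik", ra, rb)  # ra^T rb
        return r_rel, d_loc

    def energy(self, state: State) -> float:
        total = 0.0
        if self.n_step:
            r_rel, d_loc = self.relative_pose(state)
            if _kernels.HAVE_NUMBA:
                e0, status = _kernels.element_energies(r_rel, d_loc, self.q0, self.kmat)
                if status:
                    raise StepGeometryError(
                        "degenerate step geometry (antiparallel frames or 180-degree twist)"
                    )
                total += float(e0.sum())
            else:
                total += float(self.step_energies(r_rel, d_loc).sum())
        if self.ss_a.size:
            dist = np.linalg.norm(
                state.positions[self.ss_b] - state.positions[self.ss_a], axis=1
            )
            total += float(np.sum(0.5 * self.ss_k * (dist - self.ss_rest) ** 2))
        return total

    # -- forces ----------------------------------------------------------

    def forces(self, state: State) -> tuple[np.ndarray, float]:
        """(6N generalized force vector, total elastic energy)."""
        n = self.n_nodes
        force = np.zeros((n, 6))
        energy = 0.0
        if self.n_step:
            r_rel, d_loc = self.relative_pose(state)
            if _kernels.HAVE_NUMBA:
                e0, g_d, g_psi, status = _kernels.element_energy_gradients(
                    r_rel, d_loc, self.q0, self.kmat, _ROT_P, _ROT_M, _FD_STEP
                )
                if status:
                    raise StepGeometryError(
                        "degenerate step geometry (antiparallel frames or 180-degree twist)"
                    )
            else:
                e0 = self.step_energies(r_rel, d_loc)
                g_d, g_psi = self._relative_gradients(r_rel, d_loc)
            energy += float(e0.sum())
            mats = state.triads()
            ra = mats[self.ia]
            gd_lab = np.einsum("eij,ej->ei", ra, g_d)
            gpsi_lab = np.einsum("eij,ej->ei", ra, g_psi)
            dx = state.positions[self.ib] - state.positions[self.ia]
            f_b = -gd_lab
            t_b = -gpsi_lab
            t_a = np.cross(dx, gd_lab) + gpsi_lab
            for k in range(3):
                force[:, k] += np.bincount(self.ib, f_b[:, k], minlength=n)
                force[:, k] -= np.bincount(self.ia, f_b[:, k], minlength=n)
                force[:, 3 + k] += np.bincount(self.ib, t_b[:, k], minlength=n)
                force[:, 3 + k] += np.bincount(self.ia, t_a[:, k], minlength=n)
        if self.ss_a.size:
            dx = state.positions[self.ss_b] - state.positions[self.ss_a]
            dist = np.linalg.norm(dx, axis=1)
            safe = np.where(dist < 1e-12, 1.0, dist)
            stretch = dist - self.ss_rest
            energy += float(np.sum(0.5 * self.ss_k * stretch**2))
            fmag = -self.ss_k * stretch  # along +dx acting on b
            fb = (fmag / safe)[:, None] * dx
            for k in range(3):
                force[:, k] += np.bincount(self.ss_b, fb[:, k], minlength=n)
                force[:, k] -= np.bincount(self.ss_a, fb[:, k], minlength=n)
        return force.reshape(-1), energy

    def _relative_gradients(
        self, r_rel: np.ndarray, d_loc: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Central-difference gradients of element energy in relative coords.

        Returns (g_d, g_psi), each (n_step, 3): derivative with respect to
        the local displacement and to a left rotation increment of the
        relative rotation (axis in frame a).
        """
        m = self.n_step
        h = _FD_STEP
        # displacement perturbations: 6 signed copies
        eye = np.eye(3)
        d_pert = d_loc[None, None] + (
            np.array([h, -h])[:, None, None, None] * eye[None, :, None, :]
        )  # (2, 3, m, 3)
        e_d = self.step_energies(np.broadcast_to(r_rel, (2, 3, m, 3, 3)), d_pert)
        g_d = (e_d[0] - e_d[1]).T / (2 * h)  # (m, 3) -- wait: axes (3, m) -> T

        # rotation perturbations: left-multiply by exp(+-h e_k)
        rp = Rotation.from_rotvec(h * eye).as_matrix()  # (3,3,3)
        rm = Rotation.from_rotvec(-h * eye).as_matrix()
        pert = np.stack([rp, rm])  # (2, 3, 3, 3)
        r_pert = np.einsum("skij,ejl->skeil", pert, r_rel)  # (2, 3, m, 3, 3)
        e_r = self.step_energies(r_pert, np.broadcast_to(d_loc, (2, 3, m, 3)))
        g_psi = (e_r[0] - e_r[1]).T / (2 * h)
        return g_d, g_psi


_ELASTIC_CACHE: dict[int, tuple[Structure, ElasticSet]] = {}


def get_elastic_set(structure: Structure) -> ElasticSet:
    key = id(structure)
    hit = _ELASTIC_CACHE.get(key)
    if hit is not None and hit[0] is structure:
        return hit[1]
    es = ElasticSet(structure)
    _ELASTIC_CACHE[key] = (structure, es)
    if len(_ELASTIC_CACHE) > 64:
        _ELASTIC_CACHE.pop(next(iter(_ELASTIC_CACHE)))
    return es


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def assemble_mass_matrix(structure: Structure) -> MassMatrix:
    """Diagonal mass matrix from node masses and principal inertias."""
    if structure.n_nodes == 0:
        raise ValueError("cannot assemble a mass matrix for an empty structure")
    diag = np.empty(6 * structure.n_nodes)
    for i, n in enumerate(structure.nodes):
        diag[6 * i : 6 * i + 3] = n.mass
        diag[6 * i + 3 : 6 * i + 6] = n.inertia
    return MassMatrix(diag)


def elastic_element_force(
    element: Element, state: State, structure: Structure
) -> np.ndarray:
    """12-component (force_a, torque_a, force_b, torque_b) of one element."""
    if element.kind not in ("step", "crossover", "ssdna"):
        raise ValueError(f"{element.kind} is not an elastic element kind")
    sub = Structure(
        nodes=list(structure.nodes), elements=[element], metadata={"single": True}
    )
    es = ElasticSet(sub)
    f, _ = es.forces(state)
    idx = structure.node_index()
    ia, ib = idx[element.node_ids[0]], idx[element.node_ids[1]]
    out = np.empty(12)
    out[0:6] = f[6 * ia : 6 * ia + 6]
    out[6:12] = f[6 * ib : 6 * ib + 6]
    return out


def assemble_elastic_forces(structure: Structure, state: State) -> tuple[np.ndarray, float]:
    """Scatter-add of all elastic element forces; returns (6N forces, energy)."""
    return get_elastic_set(structure).forces(state)


def elastic_energy(structure: Structure, state: State) -> float:
    return get_elastic_set(structure).energy(state)


def step_parameters_of_state(
    structure: Structure, state: State, kinds: tuple[str, ...] = ("step",)
) -> np.ndarray:
    """Step parameters of every element of the requested kinds, (M, 6)."""
    idx = structure.node_index()
    sel = [e for e in structure.elements if e.kind in kinds]
    if not sel:
        return np.zeros((0, 6))
    ia = np.array([idx[e.node_ids[0]] for e in sel])
    ib = np.array([idx[e.node_ids[1]] for e in sel])
    mats = state.triads()
    ra = mats[ia]
    dx = state.positions[ib] - state.positions[ia]
    d_loc = np.einsum("eji,ej->ei", ra, dx)
    r_rel = np.einsum("eji,ejk->eik", ra, mats[ib])
    return step_parameters_rel(r_rel, d_loc)


# ---------------------------------------------------------------------------
# static energy minimization
# ---------------------------------------------------------------------------


class MinimizationError(RuntimeError):
    def __init__(self, msg: str, residual: float):
        super().__init__(f"{msg} (final force residual {residual:.3g} pN)")
        self.residual = residual


def _rotvec_to_quat(rv: np.ndarray) -> np.ndarray:
    """Unit quaternions (scipy xyzw) of rotation vectors, batched and fast."""
    angle = np.linalg.norm(rv, axis=-1)
    half = 0.5 * angle
    small = angle < 1e-8
    safe = np.where(small, 1.0, angle)
    k = np.where(small, 0.5 - angle**2 / 48.0, np.sin(half) / safe)
    q = np.empty(rv.shape[:-1] + (4,))
    q[..., 0:3] = rv * k[..., None]
    q[..., 3] = np.cos(half)
    return q


def _quat_mul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 * q2 in scipy xyzw layout (compose rotations)."""
    v1, w1 = q1[..., 0:3], q1[..., 3:4]
    v2, w2 = q2[..., 0:3], q2[..., 3:4]
    out = np.empty(np.broadcast(q1, q2).shape)
    out[..., 0:3] = w1 * v2 + w2 * v1 + np.cross(v1, v2)
    out[..., 3] = (w1 * w2)[..., 0] - np.einsum("...i,...i->...", v1, v2)
    return out


def apply_increment(state: State, du: np.ndarray) -> State:
    """New state with generalized coordinate increment du (6N, lab frame).

    Translations are added; rotations are applied multiplicatively as lab
    rotation vectors and quaternions renormalized.
    """
    du = du.reshape(-1, 6)
    new = state.copy()
    new.positions = new.positions + du[:, 0:3]
    new.quaternions = _quat_mul(_rotvec_to_quat(du[:, 3:6]), state.quaternions)
    new.normalize()
    return new


def static_minimize(
    structure: Structure,
    ion=None,
    tol: float = 1e-3,
    state: State | None = None,
    max_iter: int = 5000,
) -> State:
    """Minimize total potential energy to a max-norm force residual <= tol.

    Uses Barzilai-Borwein gradient steps with backtracking, applying rotation
    increments multiplicatively (the 6-DOF manifold update).  The total
    potential includes elastic, stacking and - when ``ion`` is given -
    screened electrostatic terms.  Deterministic given structure, state and
    settings.
    """
    from .interactions import total_interaction_forces

    if tol <= 0:
        raise ValueError("tol must be positive")
    s = structure.reference_state() if state is None else state.copy()

    def force_and_energy(st: State) -> tuple[np.ndarray, float]:
        f, e = assemble_elastic_forces(structure, st)
        fi, ei = total_interaction_forces(structure, st, ion)
        return f + fi, e + ei

    f, e = force_and_energy(s)
    res = float(np.max(np.abs(f))) if f.size else 0.0
    if res <= tol:
        return s
    step = 1e-4
    for _ in range(max_iter):
        du = step * f
        trial = apply_increment(s, du)
        try:
            f_t, e_t = force_and_energy(trial)
        except (StepGeometryError, FloatingPointError):
            step *= 0.25
            continue
        if not np.isfinite(e_t) or e_t > e + 1e-12:
            step *= 0.5
            if step < 1e-14:
                raise MinimizationError("line search collapsed", res)
            continue
        # Barzilai-Borwein step from the gradient change over this move
        dg = -(f_t - f)
        denom = float(dg @ dg)
        if denom > 0:
            step = abs(float(du @ dg)) / denom
            step = min(max(step, 1e-10), 1.0)
        s, f, e = trial, f_t, e_t
        res = float(np.max(np.abs(f)))
        if res <= tol:
            s.velocities = np.zeros_like(s.velocities)
            return s
    raise MinimizationError(f"no convergence within {max_iter} iterations", res)
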