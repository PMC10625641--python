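"""Generalized Rotne-Prager-Yamakawa hydrodynamics over 6-DOF nodes.

Every node is an identical sphere of hydrodynamic radius sigma in a Stokes
solvent of viscosity eta.  The grand mobility Xi is a dense symmetric
positive-definite 6N x 6N operator with translation-translation,
rotation-rotation and translation-rotation coupling blocks; for separations
r >= 2 sigma the far-field RPY tensors are used and for r < 2 sigma the
regularized overlapping-sphere expressions, continuous at r = 2 sigma.
The friction matrix is Z = Xi^-1; its mobility Cholesky factor is retained
so correlated random forces can be drawn without refactorizing.

DOF layout is node-major: entries 6i..6i+2 are forces/velocities, entries
6i+3..6i+5 torques/angular velocities, all in the lab frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .constants import DEFAULT_TEMPERATURE, DEFAULT_VISCOSITY, KB
from .model import State, Structure


@dataclass
class SolventModel:
    """Viscous solvent: eta in pN*ns/nm^2 (0.89 = 890 uN s/m^2), T in K."""

    viscosity: float = DEFAULT_VISCOSITY
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def kBT(self) -> float:
        return KB * self.temperature

    def validate(self) -> None:
        if self.viscosity <= 0 or self.temperature < 0:
            raise ValueError("viscosity must be positive and temperature non-negative")


@dataclass
class MobilityMatrix:
    """Dense symmetric positive-definite grand mobility Xi."""

    matrix: np.ndarray  # (6N, 6N)
    radius: float
    time: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0] // 6


@dataclass
class FrictionMatrix:
    """Z = Xi^-1 with the mobility Cholesky factor cached for noise draws.

    ``matrix`` may be dense (6N, 6N) or, for uncoupled nodes (block-free
    ensemble runs), a 1-D array holding the diagonal of Z.
    """

    matrix: np.ndarray
    mobility_cholesky: np.ndarray | None = None  # lower C with Xi = C C^T

    @property
    def is_diagonal(self) -> bool:
        return self.matrix.ndim == 1

    def diagonal(self) -> np.ndarray:
        return self.matrix if self.is_diagonal else np.diag(self.matrix)

    def correlated_gaussian(self, rng: np.random.Generator, scale: float) -> np.ndarray:
        """Draw xi with covariance scale^2 * Z via the cached factor.

        With Xi = C C^T, the vector scale * C^-T xi_std has covariance
        scale^2 * C^-T C^-1 = scale^2 * Z.
        """
        xi = rng.standard_normal(self.matrix.shape[0])
        if self.is_diagonal:
            return scale * np.sqrt(self.matrix) * xi
        if self.mobility_cholesky is None:
            raise ValueError("dense friction matrix lacks its mobility factor")
        return scale * solve_triangular(
            self.mobility_cholesky, xi, trans="T", lower=True, check_finite=False
        )


def _eps_matrix(rhat: np.ndarray) -> np.ndarray:
    """epsilon(r)_ab = eps_abg r_g = -[r]_x, batched over leading axes."""
    z = np.zeros_like(rhat[..., 0])
    return np.stack(
        [
            np.stack([z, rhat[..., 2], -rhat[..., 1]], axis=-1),
            np.stack([-rhat[..., 2], z, rhat[..., 0]], axis=-1),
            np.stack([rhat[..., 1], -rhat[..., 0], z], axis=-1),
        ],
        axis=-2,
    )


def self_mobility_block(radius: float, solvent: SolventModel) -> np.ndarray:
    """6x6 single-sphere block: 1/(6 pi eta a) I, 1/(8 pi eta a^3) I, no coupling."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    eta = solvent.viscosity
    block = np.zeros((6, 6))
    block[0:3, 0:3] = np.eye(3) / (6.0 * np.pi * eta * radius)
    block[3:6, 3:6] = np.eye(3) / (8.0 * np.pi * eta * radius**3)
    return block


def _pair_coefficients(r: np.ndarray, a: float, eta: float):
    """Scalar coefficients (c1, c2, d1, d2, e1) of the pair blocks.

    tt = c1 I + c2 rr^T, rr-block = d1 I + d2 rr^T, coupling = e1 eps(rhat).
    Far field for r >= 2a, regularized overlap form for r < 2a; both branches
    agree at r = 2a.
    """
    r = np.asarray(r, dtype=float)
    far = r >= 2.0 * a
    rs = np.where(r == 0.0, 1.0, r)  # guarded; r=0 handled by caller
    x = rs / a

    mu_t = 1.0 / (6.0 * np.pi * eta * a)
    mu_r = 1.0 / (8.0 * np.pi * eta * a**3)

    c1_far = (1.0 + 2.0 * a**2 / (3.0 * rs**2)) / (8.0 * np.pi * eta * rs)
    c2_far = (1.0 - 2.0 * a**2 / rs**2) / (8.0 * np.pi * eta * rs)
    c1_near = mu_t * (1.0 - 9.0 * x / 32.0)
    c2_near = mu_t * (3.0 * x / 32.0)

    d1_far = -1.0 / (16.0 * np.pi * eta * rs**3)
    d2_far = 3.0 / (16.0 * np.pi * eta * rs**3)
    d1_near = mu_r * (1.0 - 27.0 * x / 32.0 + 5.0 * x**3 / 64.0)
    d2_near = mu_r * (9.0 * x / 32.0 - 3.0 * x**3 / 64.0)

    e1_far = 1.0 / (8.0 * np.pi * eta * rs**2)
    e1_near = (x - 3.0 * x**2 / 8.0) / (16.0 * np.pi * eta * a**2)

    c1 = np.where(far, c1_far, c1_near)
    c2 = np.where(far, c2_far, c2_near)
    d1 = np.where(far, d1_far, d1_near)
    d2 = np.where(far, d2_far, d2_near)
    e1 = np.where(far, e1_far, e1_near)
    return c1, c2, d1, d2, e1


def pair_mobility_block(
    r_vec: np.ndarray, radius: float, solvent: SolventModel
) -> np.ndarray:
    """6x6 coupling block M_ij for r_vec = x_i - x_j (force on j -> motion of i)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise ValueError("coincident distinct nodes: pair mobility undefined")
    rhat = r_vec / r
    c1, c2, d1, d2, e1 = _pair_coefficients(np.array(r), radius, solvent.viscosity)
    outer = np.outer(rhat, rhat)
    eps = _eps_matrix(rhat)
    block = np.zeros((6, 6))
    block[0:3, 0:3] = c1 * np.eye(3) + c2 * outer
    block[3:6, 3:6] = d1 * np.eye(3) + d2 * outer
    block[0:3, 3:6] = e1 * eps  # velocity of i from torque on j
    block[3:6, 0:3] = e1 * eps  # angular velocity of i from force on j
    return block


def assemble_mobility(
    structure: Structure, state: State, solvent: SolventModel
) -> MobilityMatrix:
    """Assemble the dense grand mobility for the current configuration.

    Requires a single shared hydrodynamic radius; certified symmetric and
    positive definite (the Cholesky factorization in
    :func:`friction_from_mobility` is the certificate used in practice).
    """
    solvent.validate()
    radii = {float(n.hydro_radius) for n in structure.nodes}
    if len(radii) != 1:
        raise ValueError("all nodes must share one hydrodynamic radius")
    a = radii.pop()
    n = structure.n_nodes
    pos = state.positions
    eta = solvent.viscosity

    rij = pos[:, None, :] - pos[None, :, :]  # x_i - x_j
    r = np.linalg.norm(rij, axis=-1)
    np.fill_diagonal(r, 1.0)
    rhat = rij / r[..., None]
    c1, c2, d1, d2, e1 = _pair_coefficients(r, a, eta)
    eye = np.eye(3)
    outer = rhat[..., :, None] * rhat[..., None, :]
    tt = c1[..., None, None] * eye + c2[..., None, None] * outer
    rr = d1[..., None, None] * eye + d2[..., None, None] * outer
    eps = _eps_matrix(rhat)
    tr = e1[..., None, None] * eps

    big = np.zeros((n, 6, n, 6))
    big[:, 0:3, :, 0:3] = tt.transpose(0, 2, 1, 3)
    big[:, 3:6, :, 3:6] = rr.transpose(0, 2, 1, 3)
    big[:, 0:3, :, 3:6] = tr.transpose(0, 2, 1, 3)
    big[:, 3:6, :, 0:3] = tr.transpose(0, 2, 1, 3)
    idx = np.arange(n)
    self_block = self_mobility_block(a, solvent)
    big[idx, :, idx, :] = self_block
    xi = big.reshape(6 * n, 6 * n)
    asym = np.max(np.abs(xi - xi.T))
    if asym > 1e-10:
        raise RuntimeError(f"mobility assembly asymmetry {asym:.3g}")
    xi = 0.5 * (xi + xi.T)
    return MobilityMatrix(xi, a, time=state.time)


def friction_from_mobility(mobility: MobilityMatrix) -> FrictionMatrix:
    """Z = Xi^-1 via Cholesky; the factor is retained for random-force draws.

    Raises if Xi is not positive definite or its estimated condition number
    exceeds 1e12.
    """
    xi = mobility.matrix
    try:
        c_upper = cholesky(xi, lower=False)
    except np.linalg.LinAlgError as err:
        raise RuntimeError(f"mobility not positive definite: {err}") from err
    d = np.diag(c_upper)
    if (d.max() / d.min()) ** 2 > 1e12:
        raise RuntimeError("mobility matrix ill-conditioned (cond > 1e12)")
    z = cho_solve((c_upper, False), np.eye(xi.shape[0]))
    z = 0.5 * (z + z.T)
    return FrictionMatrix(z, c_upper.T.copy())
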