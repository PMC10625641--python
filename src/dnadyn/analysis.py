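"""Trajectory observables: RMSD/RMSF, quasi-harmonic modes, correlations, angles.

Quasi-harmonic (PCA) modes follow the mass-weighted fluctuation-matrix
construction: sigma = <(x - <x>)(x - <x>)^T> over superposed position
trajectories, Sigma = M^1/2 sigma M^1/2, Sigma Phi = Phi Lambda, natural
frequencies omega_i = (kBT / Lambda_i)^1/2 and mode shapes
dx_i = M^-1/2 phi_i.  Normal mode analysis solves K phi = omega^2 M phi in
vacuum at an equilibrium configuration, with K obtained by differentiating
the total internal force.  For a harmonic system both constructions give the
same frequencies - a consistency contract the tests exercise.

The Pearson correlation map uses the 3-D vector convention
C_ij = <dx_i . dx_j> / sqrt(<|dx_i|^2><|dx_j|^2>); the generalized map is
the mutual-information-based r_MI = sqrt(1 - exp(-2 I / 3)) with a
Kraskov-Stoegbauer-Grassberger k-nearest-neighbour MI estimator (k = 6) and
a Gaussian-copula fallback for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial import cKDTree
from scipy.special import digamma

from .constants import DEFAULT_TEMPERATURE, kBT
from .mechanics import (
    MassMatrix,
    apply_increment,
    assemble_elastic_forces,
    step_parameters_of_state,
)
from .model import State, Structure
from .langevin import Trajectory

__all__ = [
    "FluctuationProfile",
    "ModeSet",
    "CorrelationMaps",
    "superpose",
    "rmsd_series",
    "rmsf_profile",
    "overlap_coefficient",
    "pca_modes",
    "nma_modes",
    "correlation_maps",
    "knn_mutual_information",
    "step_parameter_distributions",
    "angles",
]


@dataclass
class FluctuationProfile:
    """Per-node RMSF (nm) about the superposed mean configuration."""

    rmsf: np.ndarray  # (N,)
    reference: np.ndarray  # (N, 3) mean configuration


@dataclass
class ModeSet:
    """Eigenpairs of a quasi-harmonic or normal-mode decomposition.

    Eigenvalues are sorted descending (PCA: mass-weighted variances;
    NMA: stored as omega^2).  ``frequencies`` is aligned with the columns of
    ``eigenvectors``; rigid/zero-variance modes carry frequency NaN and are
    flagged in ``rigid``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns are phi_i
    frequencies: np.ndarray  # rad/ns
    mode_shapes: np.ndarray  # columns are dx_i
    rigid: np.ndarray  # bool mask


@dataclass
class CorrelationMaps:
    pearson: np.ndarray  # (N, N) in [-1, 1]
    generalized: np.ndarray  # (N, N) in [0, 1]


# ---------------------------------------------------------------------------
# superposition, RMSD, RMSF
# ---------------------------------------------------------------------------


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) rigid superposition of mobile onto target."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (rot @ mc.T).T + target.mean(axis=0)


def _superposed_stack(traj: Trajectory, reference: np.ndarray | None = None) -> np.ndarray:
    """(F, N, 3) positions superposed onto the (iteratively refined) mean."""
    frames = traj.positions
    ref = frames[0] if reference is None else reference
    aligned = np.stack([superpose(f, ref) for f in frames])
    if reference is None:
        for _ in range(2):
            mean = aligned.mean(axis=0)
            aligned = np.stack([superpose(f, mean) for f in frames])
    return aligned


def rmsd_series(traj: Trajectory, ref: State) -> np.ndarray:
    """Per-frame RMSD (nm) after optimal rigid superposition onto ref."""
    refpos = ref.positions
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.positions):
        fitted = superpose(frame, refpos)
        out[i] = np.sqrt(np.mean(np.sum((fitted - refpos) ** 2, axis=1)))
    return out


def rmsf_profile(traj: Trajectory) -> FluctuationProfile:
    """Per-node RMSF about the superposed mean configuration."""
    aligned = _superposed_stack(traj)
    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    return FluctuationProfile(rmsf, mean)


def overlap_coefficient(x, y) -> float:
    """Normalized dot product of two fluctuation profiles, in [-1, 1]."""
    xv = x.rmsf if isinstance(x, FluctuationProfile) else np.asarray(x, dtype=float)
    yv = y.rmsf if isinstance(y, FluctuationProfile) else np.asarray(y, dtype=float)
    nx, ny = np.linalg.norm(xv), np.linalg.norm(yv)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("zero-norm fluctuation profile")
    return float(xv @ yv / (nx * ny))


# ---------------------------------------------------------------------------
# quasi-harmonic (PCA) and normal-mode analysis
# ---------------------------------------------------------------------------


def pca_modes(
    traj: Trajectory,
    mass: MassMatrix,
    temperature: float = DEFAULT_TEMPERATURE,
    superpose_first: bool = True,
    variance_floor: float = 1e-10,
) -> ModeSet:
    """Quasi-harmonic modes of the position trajectory (positions only).

    Rigid-body motion is removed by superposition before forming the
    fluctuation matrix; near-zero-variance modes are flagged rather than
    inverted.
    """
    frames = _superposed_stack(traj) if superpose_first else traj.positions
    f, n, _ = frames.shape
    x = frames.reshape(f, 3 * n)
    xc = x - x.mean(axis=0)
    sigma = (xc.T @ xc) / f
    m_trans = np.repeat(mass.diagonal.reshape(-1, 6)[:, 0], 3)
    sqrt_m = np.sqrt(m_trans)
    big_sigma = sigma * np.outer(sqrt_m, sqrt_m)
    lam, phi = np.linalg.eigh(big_sigma)
    order = np.argsort(lam)[::-1]
    lam, phi = lam[order], phi[:, order]
    scale = max(lam.max(), variance_floor)
    rigid = lam < variance_floor * scale
    freqs = np.full(lam.size, np.nan)
    good = ~rigid
    freqs[good] = np.sqrt(kBT(temperature) / lam[good])
    shapes = phi / sqrt_m[:, None]
    return ModeSet(lam, phi, freqs, shapes, rigid)


def _stiffness_matrix(
    structure: Structure, state: State, ion=None, h: float = 1e-5
) -> np.ndarray:
    """K = -dF/du by central differences over all 6N nodal coordinates."""
    from .interactions import total_interaction_forces

    def total_force(s: State) -> np.ndarray:
        fe, _ = assemble_elastic_forces(structure, s)
        fi, _ = total_interaction_forces(structure, s, ion)
        return fe + fi

    n6 = 6 * structure.n_nodes
    k = np.empty((n6, n6))
    for j in range(n6):
        e = np.zeros(n6)
        e[j] = h
        fp = total_force(apply_increment(state, e))
        fm = total_force(apply_increment(state, -e))
        k[:, j] = -(fp - fm) / (2.0 * h)
    return 0.5 * (k + k.T)


def nma_modes(
    structure: Structure,
    state: State,
    mass: MassMatrix,
    ion=None,
    equilibrium_tol: float = 1e-2,
    rigid_threshold: float = 1e-3,
) -> ModeSet:
    """Normal modes K phi = omega^2 M phi in vacuum at an equilibrium state.

    The six rigid-body modes of a free structure are identified by
    |omega| < rigid_threshold x the smallest internal frequency.
    """
    from .interactions import total_interaction_forces

    fe, _ = assemble_elastic_forces(structure, state)
    fi, _ = total_interaction_forces(structure, state, ion)
    residual = float(np.max(np.abs(fe + fi)))
    if residual > equilibrium_tol:
        raise ValueError(
            f"state is not an equilibrium (force residual {residual:.3g} pN)"
        )
    k = _stiffness_matrix(structure, state, ion)
    w2, phi = eigh(k, np.diag(mass.diagonal))
    order = np.argsort(w2)[::-1]
    w2, phi = w2[order], phi[:, order]
    omega = np.sqrt(np.clip(w2, 0.0, None))
    # rigid-mode identification: 6 smallest |omega| vs smallest internal mode
    asc = np.argsort(omega)
    internal_floor = omega[asc[6]] if omega.size > 6 else np.inf
    rigid = omega < rigid_threshold * internal_floor
    freqs = np.where(rigid, np.nan, omega)
    return ModeSet(w2, phi, freqs, phi.copy(), rigid)


# ---------------------------------------------------------------------------
# correlation maps
# ---------------------------------------------------------------------------


def knn_mutual_information(x: np.ndarray, y: np.ndarray, k: int = 6) -> float:
    """KSG (algorithm 1) k-NN mutual information between vector samples.

    ``x`` (F, dx) and ``y`` (F, dy); returns I in nats, clipped at 0.
    """
    f = x.shape[0]
    xy = np.hstack([x, y])
    tree_xy = cKDTree(xy)
    # distance to the k-th neighbour in the joint space (Chebyshev metric)
    dist, _ = tree_xy.query(xy, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    tree_x = cKDTree(x)
    tree_y = cKDTree(y)
    nx = np.array(
        [len(tree_x.query_ball_point(x[i], eps[i] - 1e-12, p=np.inf)) - 1 for i in range(f)]
    )
    ny = np.array(
        [len(tree_y.query_ball_point(y[i], eps[i] - 1e-12, p=np.inf)) - 1 for i in range(f)]
    )
    mi = digamma(k) + digamma(f) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return float(max(mi, 0.0))


def _gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information under a joint-Gaussian model (copula fallback)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    joint = np.hstack([xc, yc])
    c = np.cov(joint.T)
    dx = x.shape[1]
    sx = c[:dx, :dx]
    sy = c[dx:, dx:]
    sign, logdet_joint = np.linalg.slogdet(c)
    _, logdet_x = np.linalg.slogdet(sx)
    _, logdet_y = np.linalg.slogdet(sy)
    if sign <= 0:
        return 0.0
    return float(max(0.5 * (logdet_x + logdet_y - logdet_joint), 0.0))


def correlation_maps(
    traj: Trajectory,
    method: str = "ksg",
    k: int = 6,
    min_frames: int = 100,
    superpose: bool = True,
) -> CorrelationMaps:
    """Pearson and generalized (mutual-information) node-node correlation maps.

    ``superpose=False`` treats the frames as already-superposed displacement
    data (e.g. synthetic per-node samples); the default removes rigid-body
    motion first.
    """
    if traj.n_frames < min_frames:
        raise ValueError(f"need at least {min_frames} frames for correlation maps")
    aligned = _superposed_stack(traj) if superpose else traj.positions
    disp = aligned - aligned.mean(axis=0)  # (F, N, 3)
    n = disp.shape[1]
    inner = np.einsum("fid,fjd->ij", disp, disp) / disp.shape[0]
    norms = np.sqrt(np.diag(inner))
    pearson = inner / np.outer(norms, norms)
    pearson = np.clip(pearson, -1.0, 1.0)
    np.fill_diagonal(pearson, 1.0)

    mi_fun = {"ksg": lambda a, b: knn_mutual_information(a, b, k), "gaussian": _gaussian_mi}[
        method
    ]
    gen = np.eye(n)
    d = 3.0
    for i in range(n):
        for j in range(i + 1, n):
            mi = mi_fun(disp[:, i, :], disp[:, j, :])
            gen[i, j] = gen[j, i] = np.sqrt(1.0 - np.exp(-2.0 * mi / d))
    return CorrelationMaps(pearson, gen)


def correlation_difference(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Vectorized off-diagonal difference c_ref - c (for difference histograms)."""
    iu = np.triu_indices(reference.shape[0], k=1)
    return reference[iu] - other[iu]


# ---------------------------------------------------------------------------
# step parameters and angles
# ---------------------------------------------------------------------------


def step_parameter_distributions(
    traj: Trajectory,
    structure: Structure,
    kinds: tuple[str, ...] = ("step",),
    bins: int = 60,
) -> dict:
    """Per-parameter samples, means, standard deviations and histograms.

    Aggregates compute_step_parameters over every frame and every element of
    the requested kinds.  Keys: shift, slide, rise (nm), tilt, roll, twist
    (degrees); each maps to {samples, mean, sd, hist, edges}.
    """
    if not any(e.kind in kinds for e in structure.elements):
        raise ValueError(f"structure has no elements of kinds {kinds}")
    names = ["shift", "slide", "rise", "tilt", "roll", "twist"]
    all_params = []
    for i in range(traj.n_frames):
        all_params.append(step_parameters_of_state(structure, traj.frame(i), kinds))
    samples = np.concatenate(all_params, axis=0)  # (F*M, 6)
    out = {}
    for p, name in enumerate(names):
        col = samples[:, p]
        if np.ptp(col) < 1e-9 * max(1.0, abs(col[0])):  # delta distribution
            rng_pair = (col[0] - 0.5, col[0] + 0.5)
            hist, edges = np.histogram(col, bins=bins, range=rng_pair)
        else:
            hist, edges = np.histogram(col, bins=bins)
        out[name] = {
            "samples": col,
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)) if col.size > 1 else 0.0,
            "hist": hist,
            "edges": edges,
        }
    return out


def _axis_of(points: np.ndarray) -> np.ndarray:
    """Least-squares line direction through points, oriented head-to-tail."""
    c = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(c, full_matrices=False)
    if s[0] < 1e-9 or (s.size > 1 and s[1] / s[0] > 0.99):
        raise ValueError("degenerate axis fit: points not line-like")
    axis = vt[0]
    span = points[-1] - points[0]
    if axis @ span < 0:
        axis = -axis
    return axis


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))))


def angles(
    traj: Trajectory, definition: str, structure: Structure
) -> np.ndarray:
    """Per-frame angle series (degrees) for an annotated structure.

    ``opening``: angle between the two arm axes (switch); ``interior_vertex``:
    interior angles between consecutive wireframe edges; ``out_of_plane``:
    per-edge angle to the best-fit structure plane.
    """
    meta = structure.metadata
    out = []
    if definition == "opening":
        ia = np.asarray(meta["arm_a_nodes"])
        ib = np.asarray(meta["arm_b_nodes"])
        for frame in traj.positions:
            out.append(_angle_deg(_axis_of(frame[ia]), _axis_of(frame[ib])))
        return np.array(out)
    if definition not in ("interior_vertex", "out_of_plane"):
        raise ValueError(f"unknown angle definition {definition!r}")
    edge_nodes = {int(k): np.asarray(v) for k, v in meta["edge_nodes"].items()}
    n_edges = len(edge_nodes)
    for frame in traj.positions:
        axes = [_axis_of(frame[edge_nodes[e]]) for e in range(n_edges)]
        if definition == "interior_vertex":
            row = [
                _angle_deg(-axes[e], axes[(e + 1) % n_edges]) for e in range(n_edges)
            ]
        else:
            c = frame - frame.mean(axis=0)
            _, _, vt = np.linalg.svd(c, full_matrices=False)
            normal = vt[2]
            row = [90.0 - _angle_deg(a, normal) for a in axes]
            row = [abs(r) for r in row]
        out.append(row)
    return np.array(out)
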