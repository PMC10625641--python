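"""Non-elastic interactions: screened electrostatics and Morse base stacking.

Electrostatics reduces each base-pair node to a point charge with
counterion-condensation scaling (q_eff = 2e x 0.24 per bp) interacting by a
Debye-Hueckel screened Coulomb potential

    E(r) = q1 q2 l_B kBT exp(-kappa r) / r,

with Bjerrum length l_B = 0.714 nm at 300 K and cutoff 3/kappa.  The Debye
length follows kappa^-1 = 0.304/sqrt(I) nm with the ionic strength I (in M)
summed over Mg2+, Na+ and the balancing Cl-.  Ion-concentration changes act
on electrostatics only.

Blunt-end coaxial stacking is a breakable Morse bond on the distance r
between the two node reference points,

    Pi_SK(r) = eps [1 - exp(-a (r - r0))]^2 - eps,

with defaults eps = 42.79 pN nm, a = 2.668 nm^-1, r0 = 0.3742 nm fitted to a
potential of mean force Pi_PMF(r) = -kBT log g(r) of stacking distances.
The PMF treats the stacking distance as a one-dimensional reaction
coordinate (no 4 pi r^2 shell factor).  A bond is reported "stacked" when
r < r0 + ln(2)/a, the maximum-force point beyond which the contact yields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from . import _kernels
from .constants import DEFAULT_PARAMS, DEFAULT_TEMPERATURE, kBT
from .model import MorseParams  # re-exported domain type

if TYPE_CHECKING:
    from .model import State, Structure

__all__ = [
    "IonCondition",
    "MorseParams",
    "PmfTable",
    "debye_length",
    "electrostatic_forces",
    "morse_energy",
    "morse_force",
    "stacking_forces",
    "stacking_report",
    "pmf_from_distances",
    "fit_morse_to_pmf",
    "total_interaction_forces",
]


@dataclass
class IonCondition:
    """Monovalent/divalent salt condition of the buffer."""

    mg_mM: float = 0.0
    na_mM: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE

    def validate(self) -> None:
        if self.mg_mM < 0 or self.na_mM < 0:
            raise ValueError("concentrations must be non-negative")
        if self.mg_mM == 0 and self.na_mM == 0:
            raise ValueError("at least one ion concentration must be positive")

    def ionic_strength_molar(self) -> float:
        """I = 1/2 sum c_i z_i^2 over Mg2+, Na+ and balancing Cl-."""
        mg = self.mg_mM * 1e-3
        na = self.na_mM * 1e-3
        cl = 2.0 * mg + na
        return 0.5 * (4.0 * mg + na + cl)


def debye_length(ion: IonCondition) -> float:
    """Debye screening length kappa^-1 = 0.304/sqrt(I) nm, I in M."""
    ion.validate()
    i = ion.ionic_strength_molar()
    if i <= 0:
        raise ValueError("zero ionic strength: Debye length undefined")
    return 0.304 / np.sqrt(i)


@dataclass
class PmfTable:
    """Histogram-based potential of mean force along the stacking distance."""

    r: np.ndarray  # bin centers, nm (strictly increasing)
    g: np.ndarray  # distribution values
    pmf: np.ndarray  # -kBT log g, shifted so min(pmf) = 0; NaN where g = 0
    counts: np.ndarray  # samples per bin
    temperature: float = DEFAULT_TEMPERATURE

    def valid(self) -> np.ndarray:
        return np.isfinite(self.pmf)


# ---------------------------------------------------------------------------
# electrostatics
# ---------------------------------------------------------------------------


class _PairList:
    """Cutoff neighbour list over non-excluded node pairs, with a skin."""

    def __init__(self, structure: "Structure", skin: float = 1.0):
        n = structure.n_nodes
        self.n = n
        self.excl_keys = np.array(
            sorted(min(i, j) * n + max(i, j) for i, j in structure.electro_exclusions),
            dtype=np.int64,
        )
        # per-node effective charge; NaN means "use the parameter-table value"
        self.charges = np.array(
            [np.nan if nd.charge is None else float(nd.charge) for nd in structure.nodes]
        )
        self.skin = skin
        self.pairs: np.ndarray | None = None
        self.ref_positions: np.ndarray | None = None
        self.cutoff_built = 0.0

    def get(self, positions: np.ndarray, cutoff: float) -> np.ndarray:
        stale = (
            self.pairs is None
            or cutoff > self.cutoff_built
            or np.max(
                np.linalg.norm(positions - self.ref_positions, axis=1), initial=0.0
            )
            > self.skin / 2.0
        )
        if stale:
            tree = cKDTree(positions)
            raw = tree.query_pairs(cutoff + self.skin, output_type="ndarray")
            raw = raw.reshape(-1, 2)
            if raw.size and self.excl_keys.size:
                lo = np.minimum(raw[:, 0], raw[:, 1]).astype(np.int64)
                hi = np.maximum(raw[:, 0], raw[:, 1]).astype(np.int64)
                keys = lo * self.n + hi
                raw = raw[~np.isin(keys, self.excl_keys, assume_unique=False)]
            self.pairs = raw
            self.ref_positions = positions.copy()
            self.cutoff_built = cutoff
        return self.pairs


_PAIRLIST_CACHE: dict[int, tuple[object, _PairList]] = {}


def _get_pairlist(structure: "Structure") -> _PairList:
    key = id(structure)
    hit = _PAIRLIST_CACHE.get(key)
    if hit is not None and hit[0] is structure:
        return hit[1]
    pl = _PairList(structure)
    _PAIRLIST_CACHE[key] = (structure, pl)
    if len(_PAIRLIST_CACHE) > 64:
        _PAIRLIST_CACHE.pop(next(iter(_PAIRLIST_CACHE)))
    return pl


def electrostatic_forces(
    structure: "Structure",
    state: "State",
    ion: IonCondition,
    params: dict = DEFAULT_PARAMS,
) -> tuple[np.ndarray, float]:
    """Screened-Coulomb nodal forces and total electrostatic energy.

    Pairwise central repulsion between non-excluded node pairs within the
    cutoff (3 Debye lengths); forces are equal and opposite.  Overlapping
    nodes (r < 0.1 nm) raise an error.
    """
    n = structure.n_nodes
    force = np.zeros((n, 6))
    lam = debye_length(ion)
    kappa = 1.0 / lam
    cutoff = params["electro_cutoff_debye_multiple"] * lam
    pl = _get_pairlist(structure)
    q = np.where(np.isnan(pl.charges), params["effective_charge_per_bp"], pl.charges)
    scale = params["bjerrum_length_nm"] * kBT(ion.temperature)
    pairs = pl.get(state.positions, cutoff)
    if pairs.size == 0:
        return force.reshape(-1), 0.0
    if _kernels.HAVE_NUMBA:
        f3, energy, status = _kernels.screened_coulomb(
            state.positions, pairs, q, scale, kappa, cutoff
        )
        if status:
            raise ValueError("overlapping nodes (r < 0.1 nm) in electrostatics")
        force[:, 0:3] = f3
        return force.reshape(-1), float(energy)
    dx = state.positions[pairs[:, 1]] - state.positions[pairs[:, 0]]
    r = np.linalg.norm(dx, axis=1)
    if np.any(r < 0.1):
        raise ValueError("overlapping nodes (r < 0.1 nm) in electrostatics")
    mask = r < cutoff
    if not np.any(mask):
        return force.reshape(-1), 0.0
    pairs, dx, r = pairs[mask], dx[mask], r[mask]
    e_pair = scale * q[pairs[:, 0]] * q[pairs[:, 1]] * np.exp(-kappa * r) / r
    energy = float(e_pair.sum())
    # repulsive: force on j along +dx
    fmag = e_pair * (kappa + 1.0 / r)
    fvec = (fmag / r)[:, None] * dx
    for k in range(3):
        force[:, k] += np.bincount(pairs[:, 1], fvec[:, k], minlength=n)
        force[:, k] -= np.bincount(pairs[:, 0], fvec[:, k], minlength=n)
    return force.reshape(-1), energy


# ---------------------------------------------------------------------------
# Morse stacking
# ---------------------------------------------------------------------------


def morse_energy(r, p: MorseParams):
    """Pi_SK(r) = eps [1 - exp(-a (r - r0))]^2 - eps, pN*nm."""
    u = np.exp(-p.a * (np.asarray(r, dtype=float) - p.r0))
    return p.epsilon * (1.0 - u) ** 2 - p.epsilon


def morse_force(r, p: MorseParams):
    """Radial force -dPi/dr (positive pushes the pair apart), pN."""
    u = np.exp(-p.a * (np.asarray(r, dtype=float) - p.r0))
    return -2.0 * p.epsilon * p.a * u * (1.0 - u)


def stacking_threshold(p: MorseParams) -> float:
    """Distance r0 + ln(2)/a separating stacked from unstacked.

    This is where the Morse exponential has decayed to 1/2 - the point of
    maximum bond force, beyond which the contact yields rather than holds.
    """
    return p.r0 + np.log(2.0) / p.a


@dataclass
class StackingReport:
    """Per-bond diagnostics of the stacking elements at one configuration."""

    distances: np.ndarray
    energies: np.ndarray
    stacked: np.ndarray  # bool, r < half-depth threshold

    @property
    def total_energy(self) -> float:
        return float(self.energies.sum())


def _stacking_arrays(structure: "Structure"):
    idx = structure.node_index()
    els = [e for e in structure.elements if e.kind == "stacking"]
    ia = np.array([idx[e.node_ids[0]] for e in els], dtype=int)
    ib = np.array([idx[e.node_ids[1]] for e in els], dtype=int)
    return els, ia, ib


def stacking_forces(
    structure: "Structure", state: "State"
) -> tuple[np.ndarray, StackingReport]:
    """Nodal forces -grad Pi_SK of every stacking element, plus diagnostics."""
    n = structure.n_nodes
    force = np.zeros((n, 6))
    els, ia, ib = _stacking_arrays(structure)
    if not els:
        return force.reshape(-1), StackingReport(
            np.zeros(0), np.zeros(0), np.zeros(0, dtype=bool)
        )
    dx = state.positions[ib] - state.positions[ia]
    r = np.linalg.norm(dx, axis=1)
    safe = np.where(r < 1e-12, 1.0, r)
    energies = np.empty(len(els))
    fmags = np.empty(len(els))
    stacked = np.empty(len(els), dtype=bool)
    for k, e in enumerate(els):
        energies[k] = morse_energy(r[k], e.morse)
        fmags[k] = morse_force(r[k], e.morse)
        stacked[k] = r[k] < stacking_threshold(e.morse)
    fvec = (fmags / safe)[:, None] * dx
    for k in range(3):
        force[:, k] += np.bincount(ib, fvec[:, k], minlength=n)
        force[:, k] -= np.bincount(ia, fvec[:, k], minlength=n)
    return force.reshape(-1), StackingReport(r, energies, stacked)


def stacking_report(structure: "Structure", state: "State") -> StackingReport:
    return stacking_forces(structure, state)[1]


def total_interaction_forces(
    structure: "Structure",
    state: "State",
    ion: IonCondition | None,
    params: dict = DEFAULT_PARAMS,
) -> tuple[np.ndarray, float]:
    """Electrostatic (if an ion condition is given) plus stacking forces."""
    f_s, rep = stacking_forces(structure, state)
    energy = rep.total_energy
    if ion is not None:
        f_e, e_e = electrostatic_forces(structure, state, ion, params)
        f_s = f_s + f_e
        energy += e_e
    return f_s, energy


# ---------------------------------------------------------------------------
# PMF machinery
# ---------------------------------------------------------------------------


def pmf_from_distances(
    samples: np.ndarray,
    bins: int | np.ndarray = 100,
    temperature: float = DEFAULT_TEMPERATURE,
) -> PmfTable:
    """Histogram-based g(r) and Pi_PMF = -kBT log g from distance samples.

    The distance is treated as a 1-D reaction coordinate: no spherical-shell
    normalization.  Empty bins get NaN in the PMF (masked, never
    zero-filled); the PMF is shifted so its global minimum is zero.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1000:
        raise ValueError("need at least 1000 distance samples for a PMF")
    counts, edges = np.histogram(samples, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = np.diff(edges)
    g = counts / (samples.size * width)
    with np.errstate(divide="ignore"):
        pmf = np.where(counts > 0, -kBT(temperature) * np.log(np.maximum(g, 1e-300)), np.nan)
    pmf = pmf - np.nanmin(pmf)
    return PmfTable(centers, g, pmf, counts, temperature)


def fit_morse_to_pmf(
    pmf: PmfTable, p0: MorseParams | None = None
) -> tuple[MorseParams, float]:
    """Weighted least-squares fit of Pi_SK + offset to the PMF well.

    Bins are weighted by the square root of their sample count.  Returns the
    fitted parameters and the weighted RMS residual (pN*nm).  Raises if the
    PMF has no well (minimum not below the right-tail plateau).
    """
    valid = pmf.valid()
    r = pmf.r[valid]
    y = pmf.pmf[valid]
    w = np.sqrt(np.maximum(pmf.counts[valid], 1.0))
    if r.size < 8:
        raise ValueError("too few valid PMF bins to fit")
    i_min = int(np.argmin(y))
    tail = y[int(0.8 * y.size):]
    # a well needs an interior minimum with a wall on the left and a plateau
    # above it on the right
    if (
        i_min < 2
        or i_min >= int(0.8 * y.size)
        or y[i_min] > np.median(tail) - 1e-9
        or y[0] < y[i_min] + 0.5
    ):
        raise ValueError("no well detected in PMF: nothing to fit")

    depth0 = float(np.median(tail) - y[i_min])
    if p0 is None:
        p0 = MorseParams(epsilon=max(depth0, 1.0), a=2.5, r0=float(r[i_min]))

    def resid(theta):
        eps, a, r0, c = theta
        model = eps * (1.0 - np.exp(-a * (r - r0))) ** 2 - eps + c
        return w * (model - y)

    x0 = np.array([p0.epsilon, p0.a, p0.r0, depth0])
    sol = least_squares(
        resid,
        x0,
        bounds=([1e-6, 1e-3, 1e-6, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"Morse fit did not converge: {sol.message}")
    eps, a, r0, _ = sol.x
    rms = float(np.sqrt(np.mean((sol.fun / w) ** 2)))
    fitted = MorseParams(float(eps), float(a), float(r0))
    fitted.validate()
    return fitted, rms
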