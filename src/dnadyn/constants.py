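"""Unit system, physical constants and the editable mechanical parameter table.

Internal unit system: length nm, force pN, time ns.  The derived energy unit
is pN*nm (= 1e-21 J) and the derived mass unit is pN*ns^2/nm (= 1e-21 kg).
Simulated times map to real times one-to-one; no time rescaling factor is
introduced anywhere.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# fundamental constants (SI -> internal units)
# ---------------------------------------------------------------------------

KB = 1.380649e-23 * 1e21  # Boltzmann constant, pN*nm/K  (0.01380649)
AVOGADRO = 6.02214076e23  # 1/mol
JOULE_PER_KCAL = 4184.0  # thermochemical calorie
DALTON = 1.66053906660e-27 / 1e-21  # one Da in internal mass units (1.66e-6)

DEFAULT_TEMPERATURE = 300.0  # K
DEFAULT_VISCOSITY = 0.89  # pN*ns/nm^2  (= 890 uN s/m^2, water at 300 K)
DEFAULT_HYDRO_RADIUS = 1.1  # nm, per-node hydrodynamic sphere radius


def kBT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy in pN*nm (4.1419 at 300 K)."""
    return KB * temperature


def pn_nm_to_kcal_per_mol(energy_pn_nm: float) -> float:
    """Convert a per-molecule energy in pN*nm to kcal/mol."""
    return energy_pn_nm * 1e-21 * AVOGADRO / JOULE_PER_KCAL


def kcal_per_mol_to_pn_nm(energy_kcal_mol: float) -> float:
    return energy_kcal_mol * JOULE_PER_KCAL / AVOGADRO / 1e-21


# ---------------------------------------------------------------------------
# nucleotide masses
# ---------------------------------------------------------------------------

# average residue (nucleoside monophosphate) masses in Da
NUCLEOTIDE_MASS_DA = {"A": 313.2, "C": 289.2, "G": 329.2, "T": 304.2}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# sequence-averaged base pair: mean over the four Watson identities
AVERAGE_BP_MASS_DA = sum(
    NUCLEOTIDE_MASS_DA[b] + NUCLEOTIDE_MASS_DA[COMPLEMENT[b]]
    for b in "ACGT"
) / 4.0


def base_pair_mass(base: str) -> float:
    """Mass of one base-pair node (both strands) in internal mass units.

    ``base`` is the Watson-strand identity, ``N`` for the sequence-averaged
    base pair, or ``S`` for a single-stranded (single nucleotide) node.
    """
    base = base.upper()
    if base == "N":
        da = AVERAGE_BP_MASS_DA
    elif base == "S":
        da = AVERAGE_BP_MASS_DA / 2.0
    else:
        da = NUCLEOTIDE_MASS_DA[base] + NUCLEOTIDE_MASS_DA[COMPLEMENT[base]]
    return da * DALTON


# ---------------------------------------------------------------------------
# node inertia: rigid cylinder, radius 1 nm, height 0.34 nm
# ---------------------------------------------------------------------------

NODE_CYLINDER_RADIUS = 1.0  # nm
NODE_CYLINDER_HEIGHT = 0.34  # nm


def node_inertia(mass: float) -> np.ndarray:
    """Principal moments (I_x, I_y, I_z) of a base-pair node, mass*nm^2.

    The node is a rigid cylinder with its axis along the local z (helical)
    direction.
    """
    r2 = NODE_CYLINDER_RADIUS**2
    h2 = NODE_CYLINDER_HEIGHT**2
    i_perp = mass * (3.0 * r2 + h2) / 12.0
    i_axis = mass * r2 / 2.0
    return np.array([i_perp, i_perp, i_axis])


# ---------------------------------------------------------------------------
# the mechanical parameter table
# ---------------------------------------------------------------------------
# Sequence-averaged B-DNA elasticity.  Per-step diagonal stiffnesses are
# derived from bulk moduli: stretch modulus S ~ 1100 pN, bending persistence
# length 50 nm, torsional persistence length 100 nm, helical rise h = 0.34 nm.
# Shear stiffnesses (shift, slide) are set equal to the stretch value.
# Rotational entries are in pN*nm/rad^2; step-parameter angles are reported in
# degrees but energies are always evaluated in radians.
#
# Everything lives in this one table so that a measured (e.g. MD-derived,
# sequence-dependent) table can be dropped in without touching any code.

_RISE = 0.34  # nm
_TWIST = 34.3  # degrees
_STRETCH_MODULUS = 1100.0  # pN
_BEND_LP = 50.0  # nm
_TWIST_LP = 100.0  # nm
_KBT300 = KB * 300.0

DEFAULT_PARAMS: dict = {
    "name": "bdna-average-v1",
    "rise_nm": _RISE,
    "twist_deg": _TWIST,
    # diagonal 6x6 step stiffness: shift, slide, rise [pN/nm];
    # tilt, roll, twist [pN*nm/rad^2]
    "step_stiffness": [
        _STRETCH_MODULUS / _RISE,
        _STRETCH_MODULUS / _RISE,
        _STRETCH_MODULUS / _RISE,
        _KBT300 * _BEND_LP / _RISE,
        _KBT300 * _BEND_LP / _RISE,
        _KBT300 * _TWIST_LP / _RISE,
    ],
    # crossovers are strand junctions, not intact duplex steps: one
    # softening factor applies to the whole 6x6 table (a junction spanning
    # the ~2.5 nm inter-helix pitch with full duplex shear stiffness would
    # also make the stable integration step impractically small)
    "crossover_softening": 10.0,
    # ssDNA entropic spring: k = 3 kBT / (2 Lp Lc), Lp = 1 nm
    "ssdna_persistence_nm": 1.0,
    "ssdna_contour_per_nt_nm": 0.7,
    # electrostatics: Debye-Hueckel point charges with counterion condensation
    "bjerrum_length_nm": 0.714,
    "effective_charge_per_bp": 0.48,  # in units of e (2 e x 0.24)
    "electro_cutoff_debye_multiple": 3.0,
    # base stacking (Morse) defaults, fitted to an MD potential of mean force
    "morse_epsilon_pn_nm": 42.79,
    "morse_a_per_nm": 2.668,
    "morse_r0_nm": 0.3742,
    # reported per-bond stacking free energy (distinct from the fitted well
    # depth; both are exposed, never conflated)
    "stacking_free_energy_pn_nm": 42.2,
    "hydro_radius_nm": DEFAULT_HYDRO_RADIUS,
    "lattice_pitch_nm": 2.5,  # inter-helix centre-centre distance
}


def step_stiffness_matrix(params: dict = DEFAULT_PARAMS) -> np.ndarray:
    """6x6 diagonal stiffness for an intrahelical base-pair step."""
    return np.diag(np.asarray(params["step_stiffness"], dtype=float))


def crossover_stiffness_matrix(params: dict = DEFAULT_PARAMS) -> np.ndarray:
    """6x6 diagonal stiffness for an interhelical crossover junction."""
    k = np.asarray(params["step_stiffness"], dtype=float) / params["crossover_softening"]
    return np.diag(k)


def ssdna_spring_constant(n_nt: int, params: dict = DEFAULT_PARAMS) -> float:
    """Entropic spring constant of an ssDNA connection of n_nt nucleotides."""
    lc = n_nt * params["ssdna_contour_per_nt_nm"]
    lp = params["ssdna_persistence_nm"]
    return 3.0 * _KBT300 / (2.0 * lp * lc)
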