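"""Finite-element representation of structured DNA assemblies.

A structure is a graph of rigid base-pair nodes (6 degrees of freedom each:
three translations, three rotations) joined by typed elements:

``step``
    intrahelical base-pair step, harmonic in the six step parameters,
``crossover``
    interhelical strand exchange, same form with a softer table,
``ssdna``
    single-stranded connection, isotropic entropic spring on distance,
``stacking``
    blunt-end coaxial stacking contact, breakable Morse bond on distance.

Positions are in nm; orientations are right-handed orthonormal triads stored
internally as unit quaternions (scipy ``[x, y, z, w]`` convention), with the
local z axis along the helical direction.  Parametric builders construct
desk-scale test structures: a straight duplex, a lattice helix bundle, a
wireframe polygon, and a two-arm stacked switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy.spatial.transform import Rotation

from .constants import (
    DEFAULT_HYDRO_RADIUS,
    DEFAULT_PARAMS,
    base_pair_mass,
    crossover_stiffness_matrix,
    node_inertia,
    ssdna_spring_constant,
    step_stiffness_matrix,
)

ELEMENT_KINDS = ("step", "crossover", "ssdna", "stacking")
VALID_BASES = set("ACGTN S")


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices from scipy-layout (x, y, z, w) quaternions, batched."""
    x, y, z, w = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    n = x * x + y * y + z * z + w * w
    s = 2.0 / n
    xx, yy, zz = x * x * s, y * y * s, z * z * s
    xy, xz, yz = x * y * s, x * z * s, y * z * s
    wx, wy, wz = w * x * s, w * y * s, w * z * s
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1.0 - yy - zz
    m[..., 0, 1] = xy - wz
    m[..., 0, 2] = xz + wy
    m[..., 1, 0] = xy + wz
    m[..., 1, 1] = 1.0 - xx - zz
    m[..., 1, 2] = yz - wx
    m[..., 2, 0] = xz - wy
    m[..., 2, 1] = yz + wx
    m[..., 2, 2] = 1.0 - xx - yy
    return m


@dataclass
class MorseParams:
    """Morse bond parameters: Pi(r) = eps*[1 - exp(-a*(r - r0))]^2 - eps."""

    epsilon: float  # well depth, pN*nm
    a: float  # shape parameter, 1/nm
    r0: float  # equilibrium distance, nm

    def validate(self) -> None:
        if not (self.epsilon > 0 and self.a > 0 and self.r0 > 0):
            raise ValueError("Morse parameters must all be positive")


@dataclass
class BasePairNode:
    """One rigid base pair: reference point plus body frame.

    ``sequence`` is the Watson-strand base (A/C/G/T), ``N`` for a
    sequence-averaged pair, or ``S`` for a single-stranded node.
    Mass is in internal units (1 = 1e-21 kg); inertia holds the three
    principal moments in mass*nm^2.
    """

    id: int
    position: np.ndarray
    quaternion: np.ndarray  # scipy [x, y, z, w]
    mass: float
    inertia: np.ndarray
    hydro_radius: float = DEFAULT_HYDRO_RADIUS
    sequence: str = "N"
    charge: float | None = None  # effective charge, units of e; None -> table value

    @property
    def orientation(self) -> np.ndarray:
        """3x3 triad; columns are the local x, y, z axes in the lab frame."""
        return Rotation.from_quat(self.quaternion).as_matrix()

    def validate(self) -> None:
        r = self.orientation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError(f"node {self.id}: orientation not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError(f"node {self.id}: orientation not proper (det != +1)")
        if not self.mass > 0:
            raise ValueError(f"node {self.id}: mass must be positive")
        if not self.hydro_radius > 0:
            raise ValueError(f"node {self.id}: hydro_radius must be positive")
        if self.sequence.upper() not in VALID_BASES:
            raise ValueError(f"node {self.id}: invalid base {self.sequence!r}")


@dataclass
class Element:
    """Typed connection between two nodes.

    For elastic kinds (step/crossover) ``intrinsic_geometry`` holds the
    equilibrium step parameters (shift, slide, rise in nm; tilt, roll, twist
    in degrees) and ``stiffness`` the 6x6 matrix (angles taken in radians for
    the energy).  An ssDNA element uses only the [2] slot of the intrinsic
    geometry (rest length, nm) and the [2, 2] entry of the stiffness (pN/nm)
    for its isotropic distance spring.  Stacking elements carry ``morse``
    instead of a stiffness matrix.
    """

    kind: str
    node_ids: tuple[int, int]
    intrinsic_geometry: np.ndarray | None = None
    stiffness: np.ndarray | None = None
    morse: MorseParams | None = None

    def validate(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.node_ids[0] == self.node_ids[1]:
            raise ValueError("element node_ids must be distinct")
        if self.kind == "stacking":
            if self.stiffness is not None:
                raise ValueError("stacking elements carry no stiffness matrix")
            if self.morse is None:
                raise ValueError("stacking elements require Morse parameters")
            self.morse.validate()
        else:
            if self.stiffness is None or self.intrinsic_geometry is None:
                raise ValueError(f"{self.kind} element requires geometry and stiffness")
            k = np.asarray(self.stiffness)
            if not np.allclose(k, k.T, atol=1e-9):
                raise ValueError("stiffness matrix must be symmetric")
            if np.any(np.linalg.eigvalsh(0.5 * (k + k.T)) < -1e-9):
                raise ValueError("stiffness matrix must be positive semidefinite")


@dataclass
class State:
    """Configuration and generalized velocity of a structure.

    The 6N generalized velocity vector is node-major: for node i, entries
    ``6i..6i+2`` are the lab-frame velocity (nm/ns) and ``6i+3..6i+5`` the
    lab-frame angular velocity (rad/ns).
    """

    positions: np.ndarray  # (N, 3) nm
    quaternions: np.ndarray  # (N, 4) scipy xyzw
    velocities: np.ndarray  # (6N,)
    time: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    def rotations(self) -> Rotation:
        return Rotation.from_quat(self.quaternions)

    def triads(self) -> np.ndarray:
        """(N, 3, 3) triads; columns of each matrix are the frame axes."""
        return _quat_to_matrix(self.quaternions)

    def copy(self) -> "State":
        return State(
            self.positions.copy(),
            self.quaternions.copy(),
            self.velocities.copy(),
            self.time,
        )

    def normalize(self) -> None:
        self.quaternions /= np.linalg.norm(self.quaternions, axis=1, keepdims=True)


@dataclass
class Structure:
    """Nodes + elements + electrostatic exclusions + provenance metadata."""

    nodes: list[BasePairNode]
    elements: list[Element]
    electro_exclusions: set[tuple[int, int]] = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def validate(self) -> None:
        ids = {n.id for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for n in self.nodes:
            n.validate()
        seen = set()
        for e in self.elements:
            e.validate()
            for nid in e.node_ids:
                if nid not in ids:
                    raise ValueError(
                        f"element {e.kind} {e.node_ids} references missing node {nid}"
                    )
            key = (e.kind, e.node_ids)
            if key in seen:
                raise ValueError(f"duplicate element {key}")
            seen.add(key)

    # -- convenience accessors -------------------------------------------

    def node_index(self) -> dict[int, int]:
        return {n.id: i for i, n in enumerate(self.nodes)}

    def masses(self) -> np.ndarray:
        return np.array([n.mass for n in self.nodes])

    def reference_state(self) -> State:
        pos = np.array([n.position for n in self.nodes], dtype=float)
        quat = np.array([n.quaternion for n in self.nodes], dtype=float)
        return State(pos, quat, np.zeros(6 * len(self.nodes)))

    def add_bonded_exclusions(self) -> None:
        """Exclude every element's node pair from electrostatics."""
        idx = self.node_index()
        for e in self.elements:
            i, j = idx[e.node_ids[0]], idx[e.node_ids[1]]
            self.electro_exclusions.add((min(i, j), max(i, j)))


# ---------------------------------------------------------------------------
# small geometry helpers
# ---------------------------------------------------------------------------


def _helix_quat(axis_rot: Rotation, k: int, twist_deg: float) -> np.ndarray:
    """Frame of base pair k in a helix: axis placement then twist about z."""
    return (axis_rot * Rotation.from_euler("z", k * twist_deg, degrees=True)).as_quat()


def _make_node(nid: int, pos, quat, base: str = "N") -> BasePairNode:
    m = base_pair_mass(base)
    return BasePairNode(
        id=nid,
        position=np.asarray(pos, dtype=float),
        quaternion=np.asarray(quat, dtype=float),
        mass=m,
        inertia=node_inertia(m),
        sequence=base,
    )


def _as_built_intrinsic(structure: Structure, element: Element) -> np.ndarray:
    """Step parameters of an element in the as-built configuration."""
    from .mechanics import compute_step_parameters

    idx = structure.node_index()
    a = structure.nodes[idx[element.node_ids[0]]]
    b = structure.nodes[idx[element.node_ids[1]]]
    return compute_step_parameters(a, b).as_array()


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_duplex(
    n_bp: int,
    sequence: str = "average",
    rise: float | None = None,
    twist: float | None = None,
    params: dict = DEFAULT_PARAMS,
    origin: np.ndarray | None = None,
    axis_rot: Rotation | None = None,
    id_offset: int = 0,
    twist_phase: float = 0.0,
) -> Structure:
    """Straight B-form duplex along z (or along a rotated axis).

    Node k sits at z = k*rise with its frame rotated by k*twist about the
    helical axis; consecutive nodes are joined by step elements with
    intrinsic geometry (0, 0, rise, 0, 0, twist) and the default step
    stiffness table.
    """
    if n_bp < 2:
        raise ValueError("a duplex needs at least 2 base pairs")
    rise = params["rise_nm"] if rise is None else rise
    twist = params["twist_deg"] if twist is None else twist
    if sequence == "average":
        bases = ["N"] * n_bp
    else:
        bases = list(sequence.upper())
        if len(bases) != n_bp:
            raise ValueError("sequence length must equal n_bp")
        bad = set(bases) - set("ACGT")
        if bad:
            raise ValueError(f"invalid base characters: {sorted(bad)}")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    axis_rot = Rotation.identity() if axis_rot is None else axis_rot

    nodes = []
    for k in range(n_bp):
        pos = origin + axis_rot.apply([0.0, 0.0, k * rise])
        quat = _helix_quat(axis_rot, k, twist)
        # fold the twist phase into the frame
        if twist_phase:
            quat = (
                Rotation.from_quat(quat)
                * Rotation.from_euler("z", twist_phase, degrees=True)
            ).as_quat()
        nodes.append(_make_node(id_offset + k, pos, quat, bases[k]))

    kmat = step_stiffness_matrix(params)
    intrinsic = np.array([0.0, 0.0, rise, 0.0, 0.0, twist])
    elements = [
        Element(
            "step",
            (id_offset + k, id_offset + k + 1),
            intrinsic.copy(),
            kmat.copy(),
        )
        for k in range(n_bp - 1)
    ]
    s = Structure(nodes, elements, metadata={"name": f"duplex-{n_bp}bp"})
    s.add_bonded_exclusions()
    s.validate()
    return s


def _honeycomb_xy(i: int, pitch: float) -> tuple[float, float]:
    col, row = divmod(i, 2)
    x = col * pitch * np.sqrt(3.0) / 2.0
    y = row * pitch + (col % 2) * pitch / 2.0
    return x, y


def _square_xy(i: int, pitch: float) -> tuple[float, float]:
    col, row = divmod(i, 2)  # strip layout: two rows
    return col * pitch, row * pitch


def build_bundle(
    n_helices: int,
    lattice: str = "honeycomb",
    n_bp: int = 32,
    crossover_spacing: int = 16,
    params: dict = DEFAULT_PARAMS,
) -> Structure:
    """Parallel duplexes on a honeycomb or square lattice joined by crossovers.

    Neighbouring helices (centre distance ~2.5 nm) are connected by crossover
    elements every ``crossover_spacing`` base pairs, using the softer
    crossover stiffness table; crossover intrinsic geometry is the as-built
    relative pose, so the construction is stress-free.
    """
    if n_helices < 2:
        raise ValueError("a bundle needs at least 2 helices")
    if crossover_spacing < 7:
        raise ValueError("crossover spacing below 7 bp is not buildable")
    if crossover_spacing // 2 >= n_bp:
        raise ValueError("crossover spacing incompatible with helix length")
    if lattice not in ("honeycomb", "square"):
        raise ValueError(f"unknown lattice {lattice!r}")
    pitch = params["lattice_pitch_nm"]
    xy = _honeycomb_xy if lattice == "honeycomb" else _square_xy

    nodes: list[BasePairNode] = []
    elements: list[Element] = []
    centers = []
    for h in range(n_helices):
        x, y = xy(h, pitch)
        centers.append((x, y))
        sub = build_duplex(
            n_bp,
            params=params,
            origin=np.array([x, y, 0.0]),
            id_offset=h * n_bp,
        )
        nodes.extend(sub.nodes)
        elements.extend(sub.elements)

    # adjacency on the lattice
    pairs = []
    for i in range(n_helices):
        for j in range(i + 1, n_helices):
            d = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d < 1.1 * pitch:
                pairs.append((i, j))

    kx = crossover_stiffness_matrix(params)
    structure = Structure(nodes, elements, metadata={"name": f"{n_helices}hb-{lattice}"})
    n_pairs = max(1, len(pairs))
    for k, (i, j) in enumerate(pairs):
        offset = (crossover_spacing // 2 + (k * crossover_spacing) // n_pairs) % crossover_spacing
        for bp in range(offset, n_bp, crossover_spacing):
            el = Element("crossover", (i * n_bp + bp, j * n_bp + bp), None, kx.copy())
            el.intrinsic_geometry = _as_built_intrinsic(structure, el)
            elements.append(el)
    structure.metadata["helix_nodes"] = {
        h: list(range(h * n_bp, (h + 1) * n_bp)) for h in range(n_helices)
    }
    structure.add_bonded_exclusions()
    structure.validate()
    return structure


def build_switch_toy(
    arm_bp: int = 64,
    n_stack_bonds: int = 6,
    params: dict = DEFAULT_PARAMS,
    seam_gap: float = 2.4,
    arm_helices: int = 12,
) -> Structure:
    """Two-arm switch held closed by blunt-end stacking bonds.

    Each arm is a rigid multi-helix bundle, modelled as a single chain of
    cross-section nodes: every node carries the mass, inertia and composite
    stiffness of an ``arm_helices``-helix bundle slice (stretch/shear scale
    with the helix count, bending/torsion with the parallel-axis composite
    ~ count squared / 2), but only the charge of the seam-facing base pair
    - deeper helices are screened out of the seam interaction.  Modelling
    the arm as a beam this stiff is essential: flexible arms simply bulge
    away from each other, bank the electrostatic relief without ever
    loading the latch, and the switch never operates.

    The arms face each other across a seam of centre-centre distance
    ``seam_gap`` in z and share a hinge at x = 0 (two crossover elements).
    ``n_stack_bonds`` stacking bonds bridge the seam through short
    blunt-end latch nodes built at the Morse equilibrium distance, so the
    as-built state is closed and stress-free; the opening angle (between
    the arm axes) is 0 as built.  Latch sites alternate between the arm
    tip and just outside the hinge: the tip bond carries the whole
    electrostatic lever and must break under any scissor opening (the
    delayed stacking response), while a near-hinge bond never leaves the
    Morse capture range and zips the switch closed again once the
    repulsion relaxes - the multi-contact latching of shape-complementary
    DNA switches.
    """
    if arm_bp < 8:
        raise ValueError("arm_bp must be at least 8")
    if n_stack_bonds < 1:
        raise ValueError("need at least one stacking bond")
    rise = params["rise_nm"]
    twist = params["twist_deg"]
    morse = MorseParams(
        params["morse_epsilon_pn_nm"], params["morse_a_per_nm"], params["morse_r0_nm"]
    )
    # latch sites: one bond at the arm tip plus a ladder of bonds climbing
    # outward from the hinge.  The tip bond carries the largest share of the
    # electrostatic lever, so low salt unzips the latch from the tip inward
    # (the delayed stacking response); on re-closing the ladder re-engages
    # from the hinge outward, each captured bond pulling the next into its
    # Morse capture range until the tip re-latches - the distributed,
    # zipper-like latching of shape-complementary DNA switches.
    ladder = [bp for bp in range(max(3, arm_bp // 6), arm_bp - 3, 4)]
    mid = 5 * arm_bp // 8  # bridges the capture gap between ladder and tip
    sites = [arm_bp - 2] + ladder[:4]
    if mid not in sites:
        sites.append(mid)
    sites += [b for b in ladder[4:] if b not in sites]
    if n_stack_bonds > len(sites):
        raise ValueError(
            f"n_stack_bonds={n_stack_bonds} exceeds available blunt-end pairs ({len(sites)})"
        )

    axis_rot = Rotation.from_euler("y", 90, degrees=True)  # local z -> lab x
    z_arm = seam_gap / 2.0
    bundle_radius = 1.25 * np.sqrt(arm_helices)  # nm, packed-circle estimate
    m_slice = arm_helices * base_pair_mass("N")
    i_perp = m_slice * (3.0 * bundle_radius**2 + rise**2) / 12.0
    i_axis = m_slice * bundle_radius**2 / 2.0

    # the seam interaction sees the facing helix row plus deeper rows
    # attenuated by screening; an effective ~2.3 base pairs of condensed
    # charge per slice represents that partial visibility of the bundle
    q_slice = params["effective_charge_per_bp"] * 2.083

    def make_arm_node(nid, pos, quat) -> BasePairNode:
        return BasePairNode(
            id=nid,
            position=np.asarray(pos, dtype=float),
            quaternion=np.asarray(quat, dtype=float),
            mass=m_slice,
            inertia=np.array([i_perp, i_perp, i_axis]),
            sequence="N",
            charge=q_slice,
        )

    nodes: list[BasePairNode] = []
    elements: list[Element] = []
    nid = 0
    arm_nodes: dict[str, list[int]] = {"A": [], "B": []}
    for arm, zsign in (("A", +1.0), ("B", -1.0)):
        for k in range(arm_bp):
            pos = [k * rise, 0.0, zsign * z_arm]
            quat = _helix_quat(axis_rot, k, twist)
            nodes.append(make_arm_node(nid, pos, quat))
            arm_nodes[arm].append(nid)
            nid += 1

    def node_id(arm: str, k: int) -> int:
        return (0 if arm == "A" else arm_bp) + k

    kstep = step_stiffness_matrix(params)
    k_arm = kstep.copy()
    k_arm[:3, :3] *= arm_helices
    k_arm[3:, 3:] *= arm_helices**2 / 2.0
    kx = crossover_stiffness_matrix(params)
    intrinsic_step = np.array([0.0, 0.0, rise, 0.0, 0.0, twist])
    for arm in ("A", "B"):
        for k in range(arm_bp - 1):
            elements.append(
                Element(
                    "step",
                    (node_id(arm, k), node_id(arm, k + 1)),
                    intrinsic_step.copy(),
                    k_arm.copy(),
                )
            )

    structure = Structure(nodes, elements, metadata={"name": "switch-toy"})

    def add_crossover(na: int, nb: int) -> None:
        el = Element("crossover", (na, nb), None, kx.copy())
        el.intrinsic_geometry = _as_built_intrinsic(structure, el)
        elements.append(el)

    # hinge: the arm chains tied over the first six slices; the hinge
    # rotational stiffness caps how far a transient tip-bond flicker can
    # swing the arms at high salt and speeds re-closing, while remaining
    # negligible against the low-salt opening torque
    for bp in range(6):
        add_crossover(node_id("A", bp), node_id("B", bp))

    # latch: blunt-end nodes protruding into the seam, bonded by Morse elements
    latch_pairs = []
    for b in range(n_stack_bonds):
        bp = sites[b]
        x = bp * rise
        y = 0.0
        qa = _helix_quat(Rotation.from_euler("y", 90, degrees=True), bp, twist)
        la = _make_node(nid, [x, y, +morse.r0 / 2.0], qa)
        nid += 1
        lb = _make_node(nid, [x, y, -morse.r0 / 2.0], qa)
        nid += 1
        nodes.extend([la, lb])
        # full-stiffness tether: the blunt end tracks its arm rigidly, so a
        # broken bond separates with the arm instead of dangling within
        # recapture range
        k_latch = kstep.copy()
        for latch, arm in ((la, "A"), (lb, "B")):
            el = Element(
                "step", (node_id(arm, bp), latch.id), None, k_latch.copy()
            )
            el.intrinsic_geometry = _as_built_intrinsic(structure, el)
            elements.append(el)
        elements.append(Element("stacking", (la.id, lb.id), morse=morse))
        latch_pairs.append((la.id, lb.id))

    structure.metadata.update(
        {
            "arm_a_nodes": arm_nodes["A"],
            "arm_b_nodes": arm_nodes["B"],
            "latch_pairs": latch_pairs,
            "seam_gap_nm": seam_gap,
        }
    )
    structure.add_bonded_exclusions()
    structure.validate()
    return structure


def build_wireframe_polygon(
    n_edges: int,
    edge_type: str = "DX",
    circumradius: float = 25.0,
    params: dict = DEFAULT_PARAMS,
    crossover_spacing: int = 16,
) -> Structure:
    """Planar wireframe polygon with bundle edges and ssDNA vertex joints.

    Edges are two-helix (DX) or six-helix (6HB) bundles laid along the
    polygon sides; adjacent edge ends are joined by single-stranded spring
    elements.  Ideal interior angles are 180*(n-2)/n degrees.
    """
    if n_edges not in (3, 4, 6):
        raise ValueError("n_edges must be 3, 4 or 6")
    if edge_type not in ("DX", "6HB"):
        raise ValueError("edge_type must be 'DX' or '6HB'")
    rise = params["rise_nm"]
    twist = params["twist_deg"]
    pitch = params["lattice_pitch_nm"]
    n_hel = 2 if edge_type == "DX" else 6
    vertex_gap = 2.0  # nm of ssDNA slack at each corner
    side = 2.0 * circumradius * np.sin(np.pi / n_edges)
    n_bp_edge = int((side - vertex_gap) / rise)
    if n_bp_edge < 2 * crossover_spacing:
        raise ValueError("circumradius too small to hold crossover-spaced edges")

    vertices = [
        circumradius * np.array([np.cos(2 * np.pi * k / n_edges), np.sin(2 * np.pi * k / n_edges), 0.0])
        for k in range(n_edges)
    ]
    nodes: list[BasePairNode] = []
    elements: list[Element] = []
    nid = 0
    edge_nodes: dict[int, list[int]] = {}
    edge_ends: list[tuple[list[int], list[int]]] = []  # (start ids, end ids) per edge

    kstep = step_stiffness_matrix(params)
    intrinsic_step = np.array([0.0, 0.0, rise, 0.0, 0.0, twist])
    for e in range(n_edges):
        a, b = vertices[e], vertices[(e + 1) % n_edges]
        direction = (b - a) / np.linalg.norm(b - a)
        start = a + direction * (vertex_gap / 2.0)
        # rotation taking local z to the edge direction, keeping lab z as a
        # reference normal for the in-plane helix offsets
        zhat = np.array([0.0, 0.0, 1.0])
        xref = np.cross(zhat, direction)
        xref /= np.linalg.norm(xref)
        frame = np.column_stack([xref, np.cross(direction, xref), direction])
        axis_rot = Rotation.from_matrix(frame)
        ids_this_edge: list[int] = []
        offsets = []
        if edge_type == "DX":
            offsets = [np.zeros(3), xref * pitch]
        else:
            for h in range(6):
                hx, hy = _honeycomb_xy(h, pitch)
                offsets.append(xref * hx + zhat * hy)
        helix_first_last = []
        for off in offsets:
            first = nid
            for k in range(n_bp_edge):
                pos = start + off + direction * (k * rise)
                nodes.append(_make_node(nid, pos, _helix_quat(axis_rot, k, twist)))
                ids_this_edge.append(nid)
                nid += 1
            for k in range(n_bp_edge - 1):
                elements.append(
                    Element(
                        "step",
                        (first + k, first + k + 1),
                        intrinsic_step.copy(),
                        kstep.copy(),
                    )
                )
            helix_first_last.append((first, nid - 1))
        edge_nodes[e] = ids_this_edge
        edge_ends.append(
            ([f for f, _ in helix_first_last], [l for _, l in helix_first_last])
        )

    structure = Structure(nodes, elements, metadata={"name": f"wireframe-{n_edges}-{edge_type}"})
    kx = crossover_stiffness_matrix(params)
    # interhelix crossovers within each edge
    for e in range(n_edges):
        ids = edge_nodes[e]
        per_helix = n_bp_edge
        for h in range(n_hel - 1):
            for bp in range(crossover_spacing // 2, n_bp_edge, crossover_spacing):
                el = Element(
                    "crossover",
                    (ids[h * per_helix + bp], ids[(h + 1) * per_helix + bp]),
                    None,
                    kx.copy(),
                )
                el.intrinsic_geometry = _as_built_intrinsic(structure, el)
                elements.append(el)

    # ssDNA joints at the vertices: end of edge e to start of edge e+1
    n_nt = max(2, int(round(vertex_gap / params["ssdna_contour_per_nt_nm"])))
    k_ss = ssdna_spring_constant(n_nt, params)
    idx = structure.node_index()
    for e in range(n_edges):
        ends = edge_ends[e][1]
        starts = edge_ends[(e + 1) % n_edges][0]
        for na, nb in zip(ends, starts):
            rest = float(
                np.linalg.norm(
                    structure.nodes[idx[na]].position - structure.nodes[idx[nb]].position
                )
            )
            geom = np.zeros(6)
            geom[2] = rest
            kmat = np.zeros((6, 6))
            kmat[2, 2] = k_ss
            elements.append(Element("ssdna", (na, nb), geom, kmat))

    structure.metadata["edge_nodes"] = {str(e): edge_nodes[e] for e in range(n_edges)}
    structure.add_bonded_exclusions()
    structure.validate()
    return structure


# ---------------------------------------------------------------------------
# simplified caDNAno import
# ---------------------------------------------------------------------------


def from_cadnano(
    data: dict, lattice: str = "auto", params: dict = DEFAULT_PARAMS
) -> Structure:
    """Convert a (simplified) caDNAno design dictionary to a Structure.

    Supports the plain square/honeycomb JSON dialect: every virtual strand
    carries ``row``, ``col``, ``scaf``, ``stap``, ``loop`` and ``skip``
    arrays.  Occupied scaffold positions become base-pair nodes, consecutive
    occupied positions become step elements, and scaffold or staple jumps
    between helices become crossovers.  Designs using loops (insertions) or
    skips (deletions) are rejected with a clear error.
    """
    vstrands = data.get("vstrands")
    if not vstrands:
        raise ValueError("not a caDNAno design: missing 'vstrands'")
    for vs in vstrands:
        if any(x != 0 for x in vs.get("loop", [])):
            raise ValueError(f"helix {vs.get('num')}: loop (insertion) not supported")
        if any(x != 0 for x in vs.get("skip", [])):
            raise ValueError(f"helix {vs.get('num')}: skip (deletion) not supported")

    pitch = params["lattice_pitch_nm"]
    rise = params["rise_nm"]
    twist = params["twist_deg"]
    if lattice == "auto":
        # honeycomb designs traditionally use 21-multiple strand lengths
        length = len(vstrands[0]["scaf"])
        lattice = "honeycomb" if length % 21 == 0 else "square"

    def helix_xy(row: int, col: int) -> tuple[float, float]:
        if lattice == "square":
            return col * pitch, row * pitch
        x = col * pitch * np.sqrt(3.0) / 2.0
        y = row * pitch * 1.5 + ((row + col) % 2) * pitch / 2.0
        return x, y

    num_to_vs = {vs["num"]: vs for vs in vstrands}
    nodes: list[BasePairNode] = []
    elements: list[Element] = []
    node_key_to_id: dict[tuple[int, int], int] = {}
    nid = 0
    for vs in vstrands:
        x, y = helix_xy(vs["row"], vs["col"])
        for i, entry in enumerate(vs["scaf"]):
            if entry == [-1, -1, -1, -1]:
                continue
            pos = [x, y, i * rise]
            quat = _helix_quat(Rotation.identity(), i, twist)
            nodes.append(_make_node(nid, pos, quat))
            node_key_to_id[(vs["num"], i)] = nid
            nid += 1

    structure = Structure(nodes, elements, metadata={"name": "cadnano-import", "lattice": lattice})
    kstep = step_stiffness_matrix(params)
    kx = crossover_stiffness_matrix(params)
    seen: set[tuple[int, tuple[int, int]]] = set()

    def connect(a_key, b_key) -> None:
        if a_key not in node_key_to_id or b_key not in node_key_to_id:
            raise ValueError(f"dangling connection {a_key} -> {b_key}")
        na, nb = node_key_to_id[a_key], node_key_to_id[b_key]
        if na == nb:
            return
        same_helix = a_key[0] == b_key[0]
        kind = "step" if same_helix else "crossover"
        key = (min(na, nb), max(na, nb))
        if key in seen:
            return
        seen.add(key)
        el = Element(kind, (na, nb), None, (kstep if same_helix else kx).copy())
        el.intrinsic_geometry = _as_built_intrinsic(structure, el)
        elements.append(el)

    for vs in vstrands:
        for strand in ("scaf", "stap"):
            for i, entry in enumerate(vs[strand]):
                if entry == [-1, -1, -1, -1]:
                    continue
                nxt_num, nxt_i = entry[2], entry[3]
                if nxt_num == -1:
                    continue
                if nxt_num not in num_to_vs:
                    raise ValueError(f"connection to unknown helix {nxt_num}")
                connect((vs["num"], i), (nxt_num, nxt_i))

    structure.add_bonded_exclusions()
    structure.validate()
    return structure
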