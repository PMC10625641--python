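"""File formats: structure JSON schema, trajectory HDF5 container, PMF tables,
XYZ/PDB pseudo-atom exports and the run configuration.

The structure file is a versioned JSON document; floats survive a round trip
bit-exactly (Python writes shortest round-trip representations).  The
trajectory container is HDF5 with frames, the per-frame energy
decomposition, and full protocol provenance including the seed, so any run
is regenerable from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .constants import DEFAULT_PARAMS
from .hydrodynamics import SolventModel
from .interactions import IonCondition, PmfTable
from .langevin import SimulationProtocol, Trajectory
from .model import BasePairNode, Element, MorseParams, State, Structure

STRUCTURE_SCHEMA = "dnadyn-structure"
STRUCTURE_VERSION = 1


def _plain(obj):
    """Recursively convert numpy scalars/arrays so json can serialize them."""
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_plain(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# structure files
# ---------------------------------------------------------------------------


def write_structure(structure: Structure, path: str | Path) -> None:
    doc = {
        "schema": STRUCTURE_SCHEMA,
        "version": STRUCTURE_VERSION,
        "metadata": _plain(structure.metadata),
        "nodes": [
            {
                "id": int(n.id),
                "position": n.position.tolist(),
                "quaternion": n.quaternion.tolist(),
                "mass": float(n.mass),
                "inertia": n.inertia.tolist(),
                "hydro_radius": float(n.hydro_radius),
                "sequence": n.sequence,
                "charge": None if n.charge is None else float(n.charge),
            }
            for n in structure.nodes
        ],
        "elements": [
            {
                "kind": e.kind,
                "node_ids": [int(e.node_ids[0]), int(e.node_ids[1])],
                "intrinsic_geometry": None
                if e.intrinsic_geometry is None
                else np.asarray(e.intrinsic_geometry).tolist(),
                "stiffness": None
                if e.stiffness is None
                else np.asarray(e.stiffness).tolist(),
                "morse": None
                if e.morse is None
                else {"epsilon": e.morse.epsilon, "a": e.morse.a, "r0": e.morse.r0},
            }
            for e in structure.elements
        ],
        "electro_exclusions": sorted([int(a), int(b)] for a, b in structure.electro_exclusions),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_structure(path: str | Path) -> Structure:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != STRUCTURE_SCHEMA:
        raise ValueError(f"{path}: not a {STRUCTURE_SCHEMA} file")
    if doc.get("version") != STRUCTURE_VERSION:
        raise ValueError(
            f"{path}: unsupported schema version {doc.get('version')!r} "
            f"(this build reads version {STRUCTURE_VERSION})"
        )
    nodes = []
    for rec in doc["nodes"]:
        try:
            nodes.append(
                BasePairNode(
                    id=rec["id"],
                    position=np.asarray(rec["position"], dtype=float),
                    quaternion=np.asarray(rec["quaternion"], dtype=float),
                    mass=rec["mass"],
                    inertia=np.asarray(rec["inertia"], dtype=float),
                    hydro_radius=rec["hydro_radius"],
                    sequence=rec["sequence"],
                    charge=rec.get("charge"),
                )
            )
        except KeyError as err:
            raise ValueError(f"{path}: node record {rec.get('id')} missing {err}") from err
    elements = []
    for k, rec in enumerate(doc["elements"]):
        try:
            morse = rec.get("morse")
            elements.append(
                Element(
                    kind=rec["kind"],
                    node_ids=(rec["node_ids"][0], rec["node_ids"][1]),
                    intrinsic_geometry=None
                    if rec.get("intrinsic_geometry") is None
                    else np.asarray(rec["intrinsic_geometry"], dtype=float),
                    stiffness=None
                    if rec.get("stiffness") is None
                    else np.asarray(rec["stiffness"], dtype=float),
                    morse=None if morse is None else MorseParams(**morse),
                )
            )
        except KeyError as err:
            raise ValueError(f"{path}: element record {k} missing {err}") from err
    s = Structure(
        nodes,
        elements,
        electro_exclusions={(int(a), int(b)) for a, b in doc.get("electro_exclusions", [])},
        metadata=doc.get("metadata", {}),
    )
    try:
        s.validate()
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err
    return s


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("positions", data=traj.positions)
        f.create_dataset("quaternions", data=traj.quaternions)
        if traj.velocities is not None:
            f.create_dataset("velocities", data=traj.velocities)
        g = f.create_group("energies")
        for k, v in traj.energies.items():
            g.create_dataset(k, data=v)
        f.attrs["protocol"] = json.dumps(_plain(traj.protocol))


def read_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(
            times=f["times"][...],
            positions=f["positions"][...],
            quaternions=f["quaternions"][...],
            energies={k: f["energies"][k][...] for k in f["energies"]},
            protocol=json.loads(f.attrs["protocol"]),
            velocities=f["velocities"][...] if "velocities" in f else None,
        )


def state_trajectory(state: State, protocol: dict | None = None) -> Trajectory:
    """Wrap a single state (e.g. a minimized configuration) as one frame."""
    return Trajectory(
        times=np.array([state.time]),
        positions=state.positions[None, ...].copy(),
        quaternions=state.quaternions[None, ...].copy(),
        energies={k: np.zeros(1) for k in ("elastic", "electrostatic", "stacking", "kinetic")},
        protocol=protocol or {"single_frame": True},
    )


# ---------------------------------------------------------------------------
# PMF tables: two-column delimited text with header metadata
# ---------------------------------------------------------------------------


def write_pmf(pmf: PmfTable, path: str | Path) -> None:
    lines = [
        "# dnadyn-pmf v1",
        f"# temperature_K {pmf.temperature}",
        "# r_nm pmf_pNnm g counts",
    ]
    for i in range(pmf.r.size):
        lines.append(
            f"{float(pmf.r[i])!r} {float(pmf.pmf[i])!r} "
            f"{float(pmf.g[i])!r} {int(pmf.counts[i])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_pmf(path: str | Path) -> PmfTable:
    temperature = 300.0
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if line.startswith("# temperature_K"):
                temperature = float(line.split()[-1])
            continue
        if line.strip():
            rows.append([float(x) for x in line.split()])
    arr = np.asarray(rows)
    return PmfTable(arr[:, 0], arr[:, 2], arr[:, 1], arr[:, 3].astype(int), temperature)


# ---------------------------------------------------------------------------
# visualization exports (one pseudo-atom per node)
# ---------------------------------------------------------------------------


def export_xyz(traj: Trajectory, path: str | Path, element: str = "C") -> None:
    with open(path, "w") as f:
        for i in range(traj.n_frames):
            f.write(f"{traj.n_nodes}\n")
            f.write(f"t= {traj.times[i]:.6f} ns\n")
            for x, y, z in traj.positions[i]:
                f.write(f"{element} {x:.5f} {y:.5f} {z:.5f}\n")


def export_pdb(traj: Trajectory, path: str | Path) -> None:
    """PDB-flavoured pseudo-atom models, one CA record per node, nm -> A."""
    with open(path, "w") as f:
        for i in range(traj.n_frames):
            f.write(f"MODEL     {i + 1:4d}\n")
            for j, (x, y, z) in enumerate(traj.positions[i] * 10.0):
                f.write(
                    f"ATOM  {j + 1:5d}  CA  DNA A{(j % 9999) + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            f.write("ENDMDL\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fully serializable description of one simulation run."""

    structure: dict  # {"builder": name, "kwargs": {...}} or {"file": path}
    protocol: dict = field(default_factory=dict)
    output: str = "trajectory.h5"
    params: dict = field(default_factory=dict)  # overrides of DEFAULT_PARAMS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            structure=doc["structure"],
            protocol=doc.get("protocol", {}),
            output=doc.get("output", "trajectory.h5"),
            params=doc.get("params", {}),
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {"structure": self.structure, "protocol": self.protocol, "params": self.params},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def resolved_params(self) -> dict:
        p = dict(DEFAULT_PARAMS)
        p.update(self.params)
        return p

    def build_structure(self) -> Structure:
        from . import model

        if "file" in self.structure:
            return read_structure(self.structure["file"])
        builders = {
            "duplex": model.build_duplex,
            "bundle": model.build_bundle,
            "switch_toy": model.build_switch_toy,
            "wireframe_polygon": model.build_wireframe_polygon,
        }
        name = self.structure.get("builder")
        if name not in builders:
            raise ValueError(f"unknown structure builder {name!r}")
        kwargs = dict(self.structure.get("kwargs", {}))
        kwargs.setdefault("params", self.resolved_params())
        return builders[name](**kwargs)

    def build_protocol(self) -> SimulationProtocol:
        p = dict(self.protocol)
        schedule = []
        for dur, ion in p.pop("ion_schedule", []):
            schedule.append((float(dur), None if ion is None else IonCondition(**ion)))
        solvent = p.pop("solvent", None)
        return SimulationProtocol(
            ion_schedule=schedule,
            solvent=None if solvent is None else SolventModel(**solvent),
            **p,
        )
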