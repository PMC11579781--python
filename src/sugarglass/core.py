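"""Topology/trajectory data model, periodic geometry and text-file I/O.

The in-memory model is deliberately small: a :class:`Topology` holding
per-atom annotations plus hydrogen-bond donor/acceptor declarations and
named oxygen/hydroxyl groups, :class:`Frame` objects with positions in nm,
and a :class:`Trajectory` binding ordered frames to one topology.  Cells
are orthorhombic only; the systems modelled here live in cubic ~5 nm boxes
with isotropic coupling, and triclinic support would complicate every
minimum-image call for no benefit.

Atom indexing is 0-based everywhere in memory; 1-based numbering appears
only inside GRO records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConsistencyError, FileFormatError, TopologyError

__all__ = [
    "UnitCell",
    "Topology",
    "Frame",
    "Trajectory",
    "minimum_image",
    "minimum_image_displacement",
    "select_group",
    "read_gro",
    "write_gro",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "topology_to_yaml",
    "topology_from_yaml",
]

# Default element -> molar mass table (g/mol); fallback 1.0 keeps the
# masses-positive invariant for exotic names in skeleton topologies.
_ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

# Residue-name -> molecule-kind defaults; GRO residue names are
# dialect-dependent so callers may pass an override map.
_KIND_MAP = {
    "SUC": "sucrose",
    "SUCR": "sucrose",
    "TRE": "trehalose",
    "TREH": "trehalose",
    "SOL": "water",
    "WAT": "water",
    "HOH": "water",
    "SPC": "water",
}

SUGAR_KINDS = frozenset({"sucrose", "trehalose", "model"})


@dataclass(frozen=True)
class UnitCell:
    """Orthorhombic periodic cell with edge lengths in nm."""

    lengths: tuple[float, float, float]

    def __post_init__(self):
        if len(self.lengths) != 3:
            raise ValueError("cell needs exactly three edge lengths")
        if any(not np.isfinite(x) or x <= 0 for x in self.lengths):
            raise ValueError(f"cell lengths must be positive, got {self.lengths}")
        object.__setattr__(self, "lengths", tuple(float(x) for x in self.lengths))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @property
    def volume(self) -> float:
        lx, ly, lz = self.lengths
        return lx * ly * lz


@dataclass
class Topology:
    """Per-atom annotations plus H-bond and group declarations.

    Attributes
    ----------
    names, elements : per-atom labels; elements drive default masses.
    masses : g/mol, all positive.
    mol_index : molecule index per atom (0-based, need not be contiguous).
    mol_kind : per-atom molecule kind in {sucrose, trehalose, water, model}.
    bonds : covalent bonds as (i, j) index pairs.
    donor_groups : (O, H) pairs eligible to donate a hydrogen bond.
    acceptor_atoms : oxygen indices eligible to accept.
    named_groups : label -> sorted atom-index tuple (e.g. "O10-H21", "O5");
        a label may span several molecules of the same kind, one instance each.
    symmetry_classes : sets of group labels treated as equivalent.
    """

    names: list[str]
    elements: list[str]
    masses: np.ndarray
    mol_index: np.ndarray
    mol_kind: list[str]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    donor_groups: list[tuple[int, int]] = field(default_factory=list)
    acceptor_atoms: list[int] = field(default_factory=list)
    named_groups: dict[str, tuple[int, ...]] = field(default_factory=dict)
    symmetry_classes: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.mol_index = np.asarray(self.mol_index, dtype=int)
        self.named_groups = {
            k: tuple(sorted(int(i) for i in v)) for k, v in self.named_groups.items()
        }
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def validate(self) -> None:
        n = self.n_atoms
        if not (len(self.elements) == len(self.mol_kind) == n
                and self.masses.shape == (n,) and self.mol_index.shape == (n,)):
            raise TopologyError("per-atom arrays have inconsistent lengths")
        if np.any(self.masses <= 0):
            raise TopologyError("all masses must be positive")
        bondset = {frozenset(b) for b in self.bonds}
        for d, h in self.donor_groups:
            if frozenset((d, h)) not in bondset:
                raise TopologyError(
                    f"donor hydrogen {h} is not bonded to donor oxygen {d}")
        for label, idx in self.named_groups.items():
            if len(idx) == 0:
                raise TopologyError(f"named group {label!r} is empty")
        # named groups must be disjoint within each molecule
        seen: dict[tuple[int, int], str] = {}
        for label, idx in self.named_groups.items():
            for i in idx:
                key = (int(self.mol_index[i]), i)
                if key in seen:
                    raise TopologyError(
                        f"groups {seen[key]!r} and {label!r} overlap at atom {i}")
                seen[key] = label
        labels = set(self.named_groups)
        for cls in self.symmetry_classes:
            if len(cls) == 0:
                raise TopologyError("empty symmetry class")
            missing = set(cls) - labels
            if missing:
                raise TopologyError(f"symmetry class refers to unknown groups {missing}")

    def atoms_of_element(self, element: str) -> np.ndarray:
        return np.asarray([i for i, e in enumerate(self.elements) if e == element])

    def atoms_of_kind(self, kind: str) -> np.ndarray:
        return np.asarray([i for i, k in enumerate(self.mol_kind) if k == kind])

    @property
    def n_oxygens(self) -> int:
        return sum(1 for e in self.elements if e == "O")

    def molecules(self) -> dict[int, np.ndarray]:
        """Map molecule index -> atom indices, in index order."""
        out: dict[int, list[int]] = {}
        for i, m in enumerate(self.mol_index):
            out.setdefault(int(m), []).append(i)
        return {m: np.asarray(v) for m, v in out.items()}

    def group_instances(self, label: str) -> list[tuple[int, ...]]:
        """Split a (possibly multi-molecule) named group into per-molecule instances."""
        idx = self.named_groups[label]
        per_mol: dict[int, list[int]] = {}
        for i in idx:
            per_mol.setdefault(int(self.mol_index[i]), []).append(i)
        return [tuple(sorted(v)) for _, v in sorted(per_mol.items())]


@dataclass
class Frame:
    """Single configuration: time (ps), positions (nm) and its cell."""

    time: float
    positions: np.ndarray
    cell: UnitCell

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")


PROTOCOLS = ("preheated", "not_preheated", "n/a")


@dataclass
class Trajectory:
    """Ordered frames bound to one topology plus dataset metadata."""

    topology: Topology
    frames: list[Frame]
    protocol: str = "n/a"
    water_mass_pct: float | None = None
    description: str = ""

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.positions.shape[0] != n:
                raise ConsistencyError(
                    f"frame {k} has {fr.positions.shape[0]} atoms, topology has {n}")
        times = [fr.time for fr in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ConsistencyError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([fr.time for fr in self.frames])


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def minimum_image(d: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Wrap raw displacement vectors into the minimum-image convention.

    Each component of the result lies in (-L/2, L/2].  Works on any
    (..., 3)-shaped array.
    """
    L = cell.array
    d = np.asarray(d, dtype=float)
    w = d - L * np.floor(d / L)          # into [0, L)
    return np.where(w > L / 2, w - L, w)  # into (-L/2, L/2]


def minimum_image_displacement(a, b, cell: UnitCell) -> np.ndarray:
    """Minimum-image displacement vector from ``a`` to ``b`` (nm)."""
    return minimum_image(np.asarray(b, float) - np.asarray(a, float), cell)


# ---------------------------------------------------------------------------
# group selection
# ---------------------------------------------------------------------------

_KINDS = ("sucrose", "trehalose", "water", "model")


def select_group(topology: Topology, expr: str) -> tuple[int, ...]:
    """Resolve a named-group label or a small filter expression.

    Expressions are conjunctions joined by ``and``; each clause is one of
    ``element <E>``, ``kind <k>``, a bare kind name, ``not <clause>``, or a
    named-group label.  The result is a deterministic sorted index tuple.
    """
    expr = expr.strip()
    if expr in topology.named_groups:
        return topology.named_groups[expr]

    def clause_mask(clause: str) -> np.ndarray:
        clause = clause.strip()
        if clause.startswith("not "):
            return ~clause_mask(clause[4:])
        parts = clause.split()
        if len(parts) == 2 and parts[0] == "element":
            return np.asarray([e == parts[1] for e in topology.elements])
        if len(parts) == 2 and parts[0] == "kind":
            if parts[1] not in _KINDS:
                raise KeyError(f"unknown molecule kind {parts[1]!r}; kinds: {_KINDS}")
            return np.asarray([k == parts[1] for k in topology.mol_kind])
        if clause in _KINDS:
            return np.asarray([k == clause for k in topology.mol_kind])
        if clause in topology.named_groups:
            mask = np.zeros(topology.n_atoms, dtype=bool)
            mask[list(topology.named_groups[clause])] = True
            return mask
        raise KeyError(
            f"unknown group or clause {clause!r}; available labels: "
            f"{sorted(topology.named_groups)}")

    mask = np.ones(topology.n_atoms, dtype=bool)
    for clause in expr.split(" and "):
        mask &= clause_mask(clause)
    return tuple(int(i) for i in np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# GRO I/O (fixed-column GROMACS layout, nm, 1-based atom numbering on disk)
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    m = re.match(r"[A-Za-z]", atom_name.strip())
    return m.group(0).upper() if m else "X"


def read_gro(path, kind_map: dict[str, str] | None = None) -> tuple[Topology, Frame]:
    """Read a GRO file into a skeleton topology and one frame.

    The skeleton carries names, elements (first letter of the atom name),
    element-table masses, molecule indices from residue numbering and
    molecule kinds from the residue name via ``kind_map`` (unknown residue
    names become kind ``model``).  Bonds, donors and named groups are not
    stored in GRO files and stay empty.
    """
    kmap = dict(_KIND_MAP)
    if kind_map:
        kmap.update({k.upper(): v for k, v in kind_map.items()})

    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise FileFormatError(f"{path}: fewer than 3 lines, not a GRO file")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise FileFormatError(f"{path}, line 2: malformed atom count "
                              f"{lines[1]!r}") from exc
    if len(lines) < n_atoms + 3:
        raise FileFormatError(
            f"{path}: header declares {n_atoms} atoms but file ends at line "
            f"{len(lines)} (need {n_atoms + 3})")

    names, elements, mol_index, mol_kind = [], [], [], []
    positions = np.empty((n_atoms, 3))
    resid_seen: dict[int, int] = {}
    for k in range(n_atoms):
        line = lines[2 + k]
        lineno = 3 + k
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            positions[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except (ValueError, IndexError) as exc:
            raise FileFormatError(f"{path}, line {lineno}: malformed atom record "
                                  f"{line!r}") from exc
        if resid not in resid_seen:
            resid_seen[resid] = len(resid_seen)
        names.append(name)
        elements.append(_infer_element(name))
        mol_index.append(resid_seen[resid])
        mol_kind.append(kmap.get(resname.upper(), "model"))

    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) < 3:
        raise FileFormatError(f"{path}, line {3 + n_atoms}: malformed box line")
    box = [float(x) for x in box_fields]
    if len(box) > 3 and any(abs(v) > 1e-12 for v in box[3:]):
        raise FileFormatError(
            f"{path}: triclinic box not supported (off-diagonal elements present)")

    masses = np.asarray([_ELEMENT_MASSES.get(e, 1.0) for e in elements])
    topo = Topology(names=names, elements=elements, masses=masses,
                    mol_index=np.asarray(mol_index), mol_kind=mol_kind)
    frame = Frame(time=0.0, positions=positions, cell=UnitCell(tuple(box[:3])))
    return topo, frame


def write_gro(topology: Topology, frame: Frame, path, title: str = "sugarglass") -> None:
    """Write one frame in fixed-column GRO layout (3-decimal nm, bit-stable)."""
    n = topology.n_atoms
    if n == 0:
        raise ConsistencyError("refusing to write an empty system")
    if frame.positions.shape[0] != n:
        raise ConsistencyError(
            f"frame has {frame.positions.shape[0]} positions, topology {n} atoms")
    kind_res = {"sucrose": "SUC", "trehalose": "TRE", "water": "SOL", "model": "MOL"}
    with open(path, "w") as fh:
        fh.write(f"{title}\n{n:5d}\n")
        for i in range(n):
            resid = (int(topology.mol_index[i]) + 1) % 100000
            resname = kind_res.get(topology.mol_kind[i], "MOL")
            x, y, z = frame.positions[i]
            fh.write(f"{resid:5d}{resname:<5s}{topology.names[i]:>5s}"
                     f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n")
        lx, ly, lz = frame.cell.lengths
        fh.write(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}\n")


# ---------------------------------------------------------------------------
# XYZ-with-box trajectory dialect
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(
    r"time=\s*([-\d.eE+]+)\s+box=\s*([-\d.eE+]+)\s*,\s*([-\d.eE+]+)\s*,\s*([-\d.eE+]+)")


def read_xyz_trajectory(path, topology: Topology | None = None, **traj_kw) -> Trajectory:
    """Read the multi-frame XYZ dialect: blocks of

        <n_atoms>
        time=<ps> box=<lx>,<ly>,<lz>
        <name> <x> <y> <z>      (nm)

    If no topology is supplied a skeleton (kind ``model``, one molecule per
    atom) is built from the first frame's names.
    """
    frames: list[Frame] = []
    names0: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FileFormatError(f"{path}, line {i + 1}: expected atom count, "
                                  f"got {lines[i]!r}") from exc
        if i + 1 >= len(lines):
            raise FileFormatError(f"{path}: truncated after line {i + 1}")
        m = _COMMENT_RE.search(lines[i + 1])
        if not m:
            raise FileFormatError(
                f"{path}, line {i + 2}: comment must carry 'time=<ps> "
                f"box=<lx>,<ly>,<lz>', got {lines[i + 1]!r}")
        t = float(m.group(1))
        cell = UnitCell((float(m.group(2)), float(m.group(3)), float(m.group(4))))
        if i + 2 + n > len(lines):
            raise FileFormatError(
                f"{path}: frame at line {i + 1} declares {n} atoms but file ends")
        pos = np.empty((n, 3))
        names = []
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise FileFormatError(
                    f"{path}, line {i + 3 + k}: malformed atom line "
                    f"{lines[i + 2 + k]!r}")
            names.append(parts[0])
            pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if not frames:
            names0 = names
        if frames and t <= frames[-1].time:
            raise ConsistencyError(
                f"{path}: frame times not strictly increasing at t={t}")
        frames.append(Frame(time=t, positions=pos, cell=cell))
        i += 2 + n
    if not frames:
        raise FileFormatError(f"{path}: no frames found")
    if topology is None:
        elements = [_infer_element(nm) for nm in names0]
        topology = Topology(
            names=names0, elements=elements,
            masses=np.asarray([_ELEMENT_MASSES.get(e, 1.0) for e in elements]),
            mol_index=np.arange(len(names0)), mol_kind=["model"] * len(names0))
    return Trajectory(topology=topology, frames=frames, **traj_kw)


def write_xyz_trajectory(trajectory: Trajectory, path) -> None:
    topo = trajectory.topology
    with open(path, "w") as fh:
        for fr in trajectory.frames:
            lx, ly, lz = fr.cell.lengths
            fh.write(f"{topo.n_atoms}\n")
            fh.write(f"time={fr.time:.6f} box={lx:.6f},{ly:.6f},{lz:.6f}\n")
            for name, (x, y, z) in zip(topo.names, fr.positions):
                fh.write(f"{name} {x:.9f} {y:.9f} {z:.9f}\n")


# ---------------------------------------------------------------------------
# YAML topology exchange (group/symmetry maps travel beside XYZ files)
# ---------------------------------------------------------------------------

def topology_to_yaml(topology: Topology, path) -> None:
    doc = {
        "names": list(topology.names),
        "elements": list(topology.elements),
        "masses": [float(m) for m in topology.masses],
        "mol_index": [int(i) for i in topology.mol_index],
        "mol_kind": list(topology.mol_kind),
        "bonds": [[int(a), int(b)] for a, b in topology.bonds],
        "donor_groups": [[int(a), int(b)] for a, b in topology.donor_groups],
        "acceptor_atoms": [int(i) for i in topology.acceptor_atoms],
        "named_groups": {k: [int(i) for i in v]
                         for k, v in topology.named_groups.items()},
        "symmetry_classes": [sorted(c) for c in topology.symmetry_classes],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def topology_from_yaml(path) -> Topology:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return Topology(
        names=doc["names"], elements=doc["elements"],
        masses=np.asarray(doc["masses"]), mol_index=np.asarray(doc["mol_index"]),
        mol_kind=doc["mol_kind"],
        bonds=[tuple(b) for b in doc.get("bonds", [])],
        donor_groups=[tuple(d) for d in doc.get("donor_groups", [])],
        acceptor_atoms=list(doc.get("acceptor_atoms", [])),
        named_groups={k: tuple(v) for k, v in doc.get("named_groups", {}).items()},
        symmetry_classes=[frozenset(c) for c in doc.get("symmetry_classes", [])],
    )
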