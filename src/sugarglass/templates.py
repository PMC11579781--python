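"""Rigid model molecules used by the synthetic generators.

The disaccharide templates are 23-site schematics, not force-field
conformers: two six-membered "rings" of scaffold carbons and hydroxyl
oxygens, one ring-ether oxygen above each ring centre and one glycosidic
ether oxygen between the rings.  What matters for the analyses is the
label set (eight hydroxyl O-H groups, three ether oxygens), the
donor/acceptor declarations, a connected bond graph for PBC rewrapping,
and the fact that no intramolecular pair satisfies the default
hydrogen-bond criterion, so planted bond counts stay exact.

Trehalose is the symmetric template: its hydroxyl and ether labels are
grouped into mirror-pair symmetry classes (the glycosidic oxygen O6 is
its own class).  Sucrose carries the same label inventory but no
symmetry pairing.
"""

from __future__ import annotations

import numpy as np

from .core import Topology

__all__ = ["water_template", "sugar_template", "merge_templates"]

_RING_RADIUS = 0.30   # nm, ring-circle radius
_OH_LEN = 0.10        # nm, hydroxyl O-H bond
_RING_SEP = 0.80      # nm, ring-centre separation

# per-ring labels: (ether label, [(hydroxyl O label, H label) x4])
_SUCROSE_RINGS = [
    ("O1", [("O2", "H8"), ("O3", "H9"), ("O4", "H10"), ("O6", "H11")]),
    ("O5", [("O8", "H19"), ("O9", "H20"), ("O10", "H21"), ("O11", "H22")]),
]
_SUCROSE_GLYCOSIDIC = "O7"

_TREHALOSE_RINGS = [
    ("O1", [("O2", "H8"), ("O3", "H9"), ("O4", "H10"), ("O5", "H11")]),
    ("O7", [("O8", "H19"), ("O9", "H20"), ("O10", "H21"), ("O11", "H22")]),
]
_TREHALOSE_GLYCOSIDIC = "O6"

TREHALOSE_SYMMETRY = [
    frozenset({"O2-H8", "O11-H22"}),
    frozenset({"O3-H9", "O10-H21"}),
    frozenset({"O4-H10", "O9-H20"}),
    frozenset({"O5-H11", "O8-H19"}),
    frozenset({"O1", "O7"}),
    frozenset({"O6"}),
]


def water_template() -> tuple[Topology, np.ndarray]:
    """3-site rigid water: O at origin, O-H 0.1 nm, H-O-H 109.47 deg."""
    theta = np.deg2rad(109.47) / 2
    pos = np.array([
        [0.0, 0.0, 0.0],
        [_OH_LEN * np.cos(theta), _OH_LEN * np.sin(theta), 0.0],
        [_OH_LEN * np.cos(theta), -_OH_LEN * np.sin(theta), 0.0],
    ])
    topo = Topology(
        names=["OW", "HW1", "HW2"], elements=["O", "H", "H"],
        masses=np.array([15.999, 1.008, 1.008]), mol_index=np.zeros(3, dtype=int),
        mol_kind=["water"] * 3,
        bonds=[(0, 1), (0, 2)], donor_groups=[(0, 1), (0, 2)], acceptor_atoms=[0],
    )
    return topo, pos


def sugar_template(kind: str = "sucrose") -> tuple[Topology, np.ndarray]:
    """Rigid 23-site model disaccharide carrying the standard label set."""
    if kind == "sucrose":
        rings, glyco, sym = _SUCROSE_RINGS, _SUCROSE_GLYCOSIDIC, []
    elif kind == "trehalose":
        rings, glyco, sym = _TREHALOSE_RINGS, _TREHALOSE_GLYCOSIDIC, TREHALOSE_SYMMETRY
    else:
        raise ValueError(f"unknown sugar kind {kind!r}")

    names: list[str] = []
    elements: list[str] = []
    pos: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    groups: dict[str, tuple[int, ...]] = {}

    def add(name, element, p):
        names.append(name)
        elements.append(element)
        pos.append(np.asarray(p, float))
        return len(names) - 1

    ring_carbons: list[list[int]] = []
    for ring_i, (ether, hydroxyls) in enumerate(rings):
        cx = -_RING_SEP / 2 if ring_i == 0 else _RING_SEP / 2
        # six ring-circle sites at 60 deg steps in the y-z plane:
        # carbons at slots 0 and 3, hydroxyl oxygens at 1,2,4,5
        slot_atoms: list[int] = []
        carbons: list[int] = []
        oh_iter = iter(hydroxyls)
        for slot in range(6):
            ang = np.deg2rad(60 * slot)
            p = (cx, _RING_RADIUS * np.cos(ang), _RING_RADIUS * np.sin(ang))
            if slot in (0, 3):
                ci = add(f"C{ring_i * 2 + (slot // 3) + 1}", "C", p)
                slot_atoms.append(ci)
                carbons.append(ci)
            else:
                o_label, h_label = next(oh_iter)
                oi = add(o_label, "O", p)
                r_out = _RING_RADIUS + _OH_LEN
                hp = (cx, r_out * np.cos(ang), r_out * np.sin(ang))
                hi = add(h_label, "H", hp)
                slot_atoms.append(oi)
                bonds.append((oi, hi))
                donors.append((oi, hi))
                acceptors.append(oi)
                groups[f"{o_label}-{h_label}"] = (oi, hi)
        for a, b in zip(slot_atoms, slot_atoms[1:] + slot_atoms[:1]):
            bonds.append((a, b))
        # ring-ether oxygen slightly off the ring plane
        ei = add(ether, "O", (cx + (0.15 if ring_i else -0.15), 0.0, 0.0))
        bonds.append((carbons[0], ei))
        acceptors.append(ei)
        groups[ether] = (ei,)
        ring_carbons.append(carbons)

    gi = add(glyco, "O", (0.0, 0.0, 0.0))
    bonds.append((ring_carbons[0][0], gi))
    bonds.append((ring_carbons[1][0], gi))
    acceptors.append(gi)
    groups[glyco] = (gi,)

    n = len(names)
    assert n == 23
    topo = Topology(
        names=names, elements=elements,
        masses=np.array([{"O": 15.999, "H": 1.008, "C": 12.011}[e] for e in elements]),
        mol_index=np.zeros(n, dtype=int), mol_kind=[kind] * n,
        bonds=bonds, donor_groups=donors, acceptor_atoms=acceptors,
        named_groups=groups, symmetry_classes=list(sym),
    )
    return topo, np.asarray(pos)


def merge_templates(parts: list[tuple[Topology, np.ndarray]]) -> tuple[Topology, np.ndarray]:
    """Concatenate per-molecule templates into one topology + coordinate block.

    Named groups with the same label across molecules of the same kind are
    merged into one multi-instance group; symmetry classes are unioned.
    """
    names, elements, mol_kind = [], [], []
    masses, mol_index, pos = [], [], []
    bonds, donors, acceptors = [], [], []
    groups: dict[str, list[int]] = {}
    sym: list[frozenset[str]] = []
    offset = 0
    mol_offset = 0
    for topo, p in parts:
        n = topo.n_atoms
        names += topo.names
        elements += topo.elements
        mol_kind += topo.mol_kind
        masses.append(topo.masses)
        mol_index.append(topo.mol_index + mol_offset)
        pos.append(p)
        bonds += [(a + offset, b + offset) for a, b in topo.bonds]
        donors += [(a + offset, b + offset) for a, b in topo.donor_groups]
        acceptors += [a + offset for a in topo.acceptor_atoms]
        for label, idx in topo.named_groups.items():
            groups.setdefault(label, []).extend(i + offset for i in idx)
        for cls in topo.symmetry_classes:
            if cls not in sym:
                sym.append(cls)
        offset += n
        mol_offset += int(topo.mol_index.max()) + 1 if n else 0
    topo = Topology(
        names=names, elements=elements, masses=np.concatenate(masses),
        mol_index=np.concatenate(mol_index), mol_kind=mol_kind,
        bonds=bonds, donor_groups=donors, acceptor_atoms=acceptors,
        named_groups={k: tuple(v) for k, v in groups.items()},
        symmetry_classes=sym,
    )
    return topo, np.concatenate(pos, axis=0)
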