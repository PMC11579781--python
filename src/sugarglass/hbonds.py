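"""Geometric hydrogen-bond detection, category/group counting, profiles.

A bond is a donor-hydrogen/acceptor triple D-H...A with the minimum-image
O(D)...O(A) distance at or below a cutoff and the H-D-A angle at or below
an angular cutoff (defaults 0.35 nm / 30 degrees, the GROMACS engine
defaults; the criterion is config-exposed because geometric definitions
vary).  Each D-H...A triple counts once, so a donor with two hydrogens can
form two bonds.  Category labels follow molecule kinds: water molecules
vs. everything sugar-like (sucrose/trehalose/model).

Counting per total oxygen divides by ALL oxygens (sugar + water); group
tables divide by the number of group instances — the two normalisations
the concentration-series figures use.

Detection switches to a periodic cell-list pair search above
``CELL_LIST_THRESHOLD`` atoms; the candidate pairs are evaluated by the
same arithmetic as the brute-force path, so results are bitwise
identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import SUGAR_KINDS, Frame, Topology, Trajectory, minimum_image
from .errors import ConfigError, ConsistencyError, SugarglassError, TopologyError

__all__ = [
    "HBondCriterion",
    "HBondRecord",
    "HBondSeries",
    "GroupHBondTable",
    "detect_hbonds",
    "count_series",
    "group_hbond_profile",
    "difference_profile",
    "crossing_points",
]

CATEGORIES = ("sugar-sugar", "sugar-water", "water-water")
CELL_LIST_THRESHOLD = 1000


@dataclass(frozen=True)
class HBondCriterion:
    """Distance (nm) and H-D-A angle (degrees) cutoffs."""

    distance: float = 0.35
    angle: float = 30.0

    def __post_init__(self):
        if self.distance <= 0 or self.angle <= 0:
            raise ValueError("criterion cutoffs must be positive")


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor: int       # donor oxygen index
    hydrogen: int
    acceptor: int    # acceptor oxygen index
    category: str


@dataclass
class HBondSeries:
    """Per-frame counts by category with a declared normalization."""

    counts: np.ndarray                  # (n_frames, 3) raw integer counts
    normalization: str = "raw"          # raw | per_total_oxygen | per_group
    denominator: float = 1.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ValueError("counts must have shape (n_frames, 3)")

    @property
    def values(self) -> np.ndarray:
        return self.counts / self.denominator

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def std(self) -> np.ndarray:
        return self.values.std(axis=0, ddof=0)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "category": CATEGORIES,
            "mean": self.mean,
            "sd": self.std,
            "n_frames": self.counts.shape[0],
            "normalization": self.normalization,
        })


@dataclass
class GroupHBondTable:
    """Per-group mean bond counts (sugar-sugar and sugar-water columns)."""

    table: pd.DataFrame                 # index: group label (or class label)
    symmetry_averaged: bool = False


def _category(kind_a: str, kind_b: str) -> str:
    wa, wb = kind_a == "water", kind_b == "water"
    if wa and wb:
        return "water-water"
    if wa or wb:
        return "sugar-water"
    return "sugar-sugar"


def _evaluate_pairs(frame: Frame, d_idx, h_idx, a_idx, criterion) -> np.ndarray:
    """Boolean mask of candidate triples satisfying the geometric criterion.

    Shared by the brute-force and cell-list paths so both produce bitwise
    identical decisions.
    """
    pos = frame.positions
    v_da = minimum_image(pos[a_idx] - pos[d_idx], frame.cell)
    dist = np.linalg.norm(v_da, axis=1)
    v_dh = minimum_image(pos[h_idx] - pos[d_idx], frame.cell)
    # angle between D->H and D->A at the donor
    num = (v_da * v_dh).sum(axis=1)
    den = dist * np.linalg.norm(v_dh, axis=1)
    cosang = np.clip(num / np.where(den > 0, den, 1.0), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return (dist <= criterion.distance) & (ang <= criterion.angle)


def detect_hbonds(frame: Frame, topology: Topology,
                  criterion: HBondCriterion = HBondCriterion(),
                  frame_index: int = 0,
                  use_cell_list: bool | None = None) -> list[HBondRecord]:
    """All D-H...A triples satisfying the criterion, sorted by indices."""
    if not topology.donor_groups:
        raise TopologyError("topology declares no donor groups")
    donors = np.asarray(topology.donor_groups, dtype=int)
    acceptors = np.asarray(topology.acceptor_atoms, dtype=int)
    if acceptors.size == 0:
        raise TopologyError("topology declares no acceptor atoms")

    if use_cell_list is None:
        use_cell_list = topology.n_atoms > CELL_LIST_THRESHOLD

    if use_cell_list:
        L = frame.cell.array
        d_pos = frame.positions[donors[:, 0]] % L
        a_pos = frame.positions[acceptors] % L
        tree_a = cKDTree(a_pos, boxsize=L)
        tree_d = cKDTree(d_pos, boxsize=L)
        pairs = tree_d.query_ball_tree(tree_a, r=criterion.distance * 1.0000001)
        di, ai = [], []
        for i, neigh in enumerate(pairs):
            for j in neigh:
                di.append(i)
                ai.append(j)
        di = np.asarray(di, dtype=int)
        ai = np.asarray(ai, dtype=int)
    else:
        di, ai = np.meshgrid(np.arange(len(donors)), np.arange(len(acceptors)),
                             indexing="ij")
        di, ai = di.ravel(), ai.ravel()

    d_idx = donors[di, 0]
    h_idx = donors[di, 1]
    a_idx = acceptors[ai]
    keep = d_idx != a_idx
    d_idx, h_idx, a_idx = d_idx[keep], h_idx[keep], a_idx[keep]
    if d_idx.size == 0:
        return []
    mask = _evaluate_pairs(frame, d_idx, h_idx, a_idx, criterion)
    records = [
        HBondRecord(frame=frame_index, donor=int(d), hydrogen=int(h),
                    acceptor=int(a),
                    category=_category(topology.mol_kind[d], topology.mol_kind[a]))
        for d, h, a in zip(d_idx[mask], h_idx[mask], a_idx[mask])
    ]
    records.sort(key=lambda r: (r.donor, r.hydrogen, r.acceptor))
    return records


def count_series(trajectory: Trajectory,
                 criterion: HBondCriterion = HBondCriterion(),
                 normalization: str = "raw") -> HBondSeries:
    """Per-frame category totals with mean/sd across frames.

    ``per_total_oxygen`` divides by the count of all oxygen atoms in the
    system (sugar and water alike).
    """
    if trajectory.n_frames == 0:
        raise SugarglassError("empty trajectory")
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    counts = np.zeros((trajectory.n_frames, 3), dtype=int)
    for t, fr in enumerate(trajectory.frames):
        for rec in detect_hbonds(fr, trajectory.topology, criterion, frame_index=t):
            counts[t, cat_index[rec.category]] += 1
    if normalization == "raw":
        denom = 1.0
    elif normalization == "per_total_oxygen":
        denom = float(trajectory.topology.n_oxygens)
        if denom == 0:
            raise SugarglassError("no oxygen atoms to normalize by")
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return HBondSeries(counts=counts, normalization=normalization, denominator=denom)


def group_hbond_profile(trajectory: Trajectory,
                        criterion: HBondCriterion = HBondCriterion(),
                        groups: list[str] | None = None,
                        symmetry_average: bool = True) -> GroupHBondTable:
    """Mean hydrogen bonds per labeled O/O-H group, per frame and instance.

    For each group: bonds linking any of its atoms to another *sugar*
    group (sugar-sugar column) or to water (sugar-water column), excluding
    bonds internal to the selected group.  Members of a symmetry class are
    averaged into one row (class total divided by class size).
    """
    topo = trajectory.topology
    labels = groups if groups is not None else sorted(topo.named_groups)
    for a, la in [(i, l) for l in labels for i in topo.named_groups[l]]:
        for lb in labels:
            if lb != la and a in topo.named_groups[lb]:
                raise ConfigError(f"groups {la!r} and {lb!r} overlap at atom {a}")

    # atom -> (label, instance) map over selected groups
    atom_group: dict[int, str] = {}
    n_instances: dict[str, int] = {}
    for label in labels:
        instances = topo.group_instances(label)
        n_instances[label] = len(instances)
        for inst in instances:
            for i in inst:
                atom_group[i] = label

    ss = {l: 0.0 for l in labels}
    sw = {l: 0.0 for l in labels}
    mol_of = topo.mol_index
    for t, fr in enumerate(trajectory.frames):
        for rec in detect_hbonds(fr, topo, criterion, frame_index=t):
            for end_atom, other_atom in ((rec.donor, rec.acceptor),
                                         (rec.acceptor, rec.donor)):
                label = atom_group.get(end_atom)
                if label is None:
                    continue
                # skip bonds internal to the same group instance
                if atom_group.get(other_atom) == label and \
                        mol_of[other_atom] == mol_of[end_atom]:
                    continue
                other_kind = topo.mol_kind[other_atom]
                if other_kind == "water":
                    sw[label] += 1.0
                elif other_kind in SUGAR_KINDS:
                    ss[label] += 1.0

    n_frames = trajectory.n_frames
    rows = {}
    for label in labels:
        denom = n_frames * max(n_instances[label], 1)
        rows[label] = (ss[label] / denom, sw[label] / denom)

    if symmetry_average and topo.symmetry_classes:
        merged: dict[str, tuple[float, float]] = {}
        used = set()
        for cls in topo.symmetry_classes:
            members = sorted(m for m in cls if m in rows)
            if not members:
                continue
            key = "/".join(members)
            merged[key] = (
                float(np.mean([rows[m][0] for m in members])),
                float(np.mean([rows[m][1] for m in members])))
            used.update(members)
        for label, vals in rows.items():
            if label not in used:
                merged[label] = vals
        rows = merged

    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["sugar-sugar", "sugar-water"])
    df.index.name = "group"
    return GroupHBondTable(table=df.sort_index(),
                           symmetry_averaged=symmetry_average)


# ---------------------------------------------------------------------------
# concentration-series arithmetic
# ---------------------------------------------------------------------------

def difference_profile(series_a: pd.DataFrame,
                       series_b: pd.DataFrame) -> pd.DataFrame:
    """Pointwise A - B per category with propagated sd.

    Inputs are tidy tables with columns (water_pct, category, mean, sd)
    on identical (water_pct, category) grids; output has the same shape
    with sd = sqrt(sd_A^2 + sd_B^2).
    """
    key = ["water_pct", "category"]
    a = series_a.sort_values(key).reset_index(drop=True)
    b = series_b.sort_values(key).reset_index(drop=True)
    if len(a) != len(b) or not (a[key].values == b[key].values).all():
        raise ConsistencyError("difference_profile: concentration grids differ")
    out = a[key].copy()
    out["mean"] = a["mean"].values - b["mean"].values
    out["sd"] = np.sqrt(a["sd"].values ** 2 + b["sd"].values ** 2)
    return out


def crossing_points(grid: np.ndarray, curve_a: np.ndarray,
                    curve_b: np.ndarray) -> tuple[list[float], list[float]]:
    """Linear-interpolation crossings of two curves on a shared sorted grid.

    Returns (crossings, degenerate): crossing abscissae in increasing
    order, and grid points where the curves coincide exactly (flagged
    separately rather than reported as crossings).
    """
    grid = np.asarray(grid, float)
    a = np.asarray(curve_a, float)
    b = np.asarray(curve_b, float)
    if grid.size < 2:
        raise SugarglassError("need at least 2 grid points")
    if np.any(np.diff(grid) <= 0):
        raise SugarglassError("grid must be sorted strictly increasing")
    d = a - b
    degenerate = [float(x) for x in grid[d == 0]]
    crossings = []
    for i in range(len(grid) - 1):
        if d[i] == 0 or d[i + 1] == 0:
            continue  # exact hits are reported as degenerate points
        if d[i] * d[i + 1] < 0:
            x = grid[i] - d[i] * (grid[i + 1] - grid[i]) / (d[i + 1] - d[i])
            crossings.append(float(x))
    return sorted(set(crossings + degenerate)), degenerate
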