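"""Radial distribution functions, contact scores, dihedrals, gyration radii.

All pair geometry uses the minimum-image convention in orthorhombic
cells.  Molecules are made whole across periodic boundaries (bond-graph
traversal) before dihedrals and radii of gyration are computed, since a
PBC-split molecule corrupts both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trajectory, minimum_image
from .errors import GeometryError, SugarglassError

__all__ = [
    "RDFProfile",
    "ContactScoreMap",
    "DihedralDistribution",
    "GyrationSeries",
    "compute_rdf",
    "contact_scores",
    "dihedral_angle",
    "dihedral_distribution",
    "make_whole",
    "radius_of_gyration",
]


@dataclass
class RDFProfile:
    r: np.ndarray          # bin centers, nm
    g: np.ndarray
    selection_a: str = ""
    selection_b: str = ""
    n_frames: int = 1

    def __post_init__(self):
        self.r = np.asarray(self.r, float)
        self.g = np.asarray(self.g, float)
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def peak(self) -> float:
        return float(self.g.max())


@dataclass
class ContactScoreMap:
    """Integer 1-10 scores over (oxygen label x partner-hydrogen class)."""

    scores: pd.DataFrame
    mapping_rule: str

    def __post_init__(self):
        vals = self.scores.values
        if vals.size and (vals.min() < 1 or vals.max() > 10):
            raise ValueError("scores must lie in 1..10")


@dataclass
class DihedralDistribution:
    quadruplet: tuple
    bin_centers: np.ndarray      # degrees, (-180, 180]
    probabilities: np.ndarray
    n_skipped_frames: int = 0

    def __post_init__(self):
        p = np.asarray(self.probabilities, float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")


@dataclass
class GyrationSeries:
    times: np.ndarray
    rg: np.ndarray               # nm, per frame

    def __post_init__(self):
        if np.any(np.asarray(self.rg) <= 0):
            raise ValueError("radius of gyration must be positive")


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def compute_rdf(trajectory: Trajectory, selection_a, selection_b,
                bin_width: float = 0.002, r_max: float | None = None,
                label_a: str = "A", label_b: str = "B") -> RDFProfile:
    """g(r) between two index selections with ideal-gas normalisation.

    Shell counts are divided by n_frames * n_A * rho_B * 4 pi r^2 dr where
    rho_B excludes the self atom when the selections overlap.  ``r_max``
    must not exceed half the smallest cell edge.
    """
    sel_a = np.asarray(sorted(selection_a), dtype=int)
    sel_b = np.asarray(sorted(selection_b), dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise SugarglassError("empty selection")
    half_min = min(fr.cell.array.min() for fr in trajectory.frames) / 2.0
    if r_max is None:
        r_max = min(2.0, half_min)
    if r_max > half_min * (1 + 1e-12):
        raise GeometryError(
            f"r_max {r_max} nm exceeds half the smallest cell edge {half_min} nm")

    n_bins = int(np.floor(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    hist = np.zeros(n_bins)
    norm = 0.0
    overlap = np.intersect1d(sel_a, sel_b).size > 0
    for fr in trajectory.frames:
        d = fr.positions[sel_a][:, None, :] - fr.positions[sel_b][None, :, :]
        d = minimum_image(d, fr.cell)
        dist = np.linalg.norm(d, axis=2)
        if overlap:
            same = sel_a[:, None] == sel_b[None, :]
            dist = dist[~same]
        else:
            dist = dist.ravel()
        hist += np.histogram(dist, bins=edges)[0]
        n_b_eff = sel_b.size - (1 if overlap else 0)
        norm += sel_a.size * n_b_eff / fr.cell.volume
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers**2 * bin_width
    g = hist / (shell * norm)
    return RDFProfile(r=centers, g=g, selection_a=label_a, selection_b=label_b,
                      n_frames=trajectory.n_frames)


def contact_scores(rdf_set: dict[tuple[str, str], RDFProfile]) -> ContactScoreMap:
    """Map first-peak g(r) maxima onto integer 1-10 scores, reproducibly.

    score = 1 + round(9 log10(max g / g_floor) / log10(g_ceil / g_floor))
    with g_floor = 1 and g_ceil the largest maximum in the set, clipped to
    [1, 10] and rounded half-even.  All-flat sets score 1 everywhere.  The
    mapping is deterministic and independent of dict ordering.
    """
    if not rdf_set:
        raise SugarglassError("empty RDF set")
    peaks = {key: p.peak for key, p in rdf_set.items()}
    g_floor = 1.0
    g_ceil = max(peaks.values())
    rows = sorted({k[0] for k in peaks})
    cols = sorted({k[1] for k in peaks})
    mat = pd.DataFrame(1, index=rows, columns=cols, dtype=int)
    if g_ceil > g_floor:
        span = np.log10(g_ceil / g_floor)
        for (r, c), peak in peaks.items():
            if peak <= g_floor:
                score = 1
            else:
                raw = 1 + round(9 * np.log10(peak / g_floor) / span)
                score = int(np.clip(raw, 1, 10))
            mat.loc[r, c] = score
    rule = f"1+round_half_even(9*log10(max_g/{g_floor})/log10({g_ceil:g}/{g_floor}))"
    return ContactScoreMap(scores=mat, mapping_rule=rule)


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def dihedral_angle(p: np.ndarray, cell=None) -> float:
    """Signed dihedral (degrees) of 4 points via the atan2 construction.

    Right-handed IUPAC convention, range (-180, 180].  Bond vectors are
    minimum-imaged when a cell is given.  Raises on colinear triplets.
    """
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    if cell is not None:
        b1, b2, b3 = (minimum_image(b, cell) for b in (b1, b2, b3))
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or nb2 < 1e-12:
        raise GeometryError("colinear triplet: dihedral undefined")
    ang = float(np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2,
                                      np.dot(n1, n2))))
    return ang + 360.0 if ang <= -180.0 else ang


def dihedral_distribution(trajectory: Trajectory, quadruplet,
                          n_bins: int = 72) -> DihedralDistribution:
    """Histogram of a signed dihedral over frames, normalised to probability.

    Frames with a degenerate (colinear) geometry are skipped and counted.
    """
    q = tuple(int(i) for i in quadruplet)
    if len(set(q)) != 4:
        raise SugarglassError("quadruplet must name 4 distinct atoms")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    angles = []
    skipped = 0
    for fr in trajectory.frames:
        try:
            angles.append(dihedral_angle(fr.positions[list(q)], fr.cell))
        except GeometryError:
            skipped += 1
    if not angles:
        raise SugarglassError("all frames degenerate: no dihedral statistics")
    hist, _ = np.histogram(angles, bins=edges)
    probs = hist / hist.sum()
    return DihedralDistribution(
        quadruplet=q, bin_centers=0.5 * (edges[:-1] + edges[1:]),
        probabilities=probs, n_skipped_frames=skipped)


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------

def make_whole(positions: np.ndarray, atoms: np.ndarray,
               bonds: list[tuple[int, int]], cell) -> np.ndarray:
    """Unwrap one molecule across PBC by breadth-first bond traversal."""
    atoms = list(int(a) for a in atoms)
    index = {a: i for i, a in enumerate(atoms)}
    adj: dict[int, list[int]] = {a: [] for a in atoms}
    for i, j in bonds:
        if i in index and j in index:
            adj[i].append(j)
            adj[j].append(i)
    out = positions[atoms].copy()
    seen = {atoms[0]}
    queue = [atoms[0]]
    while queue:
        a = queue.pop(0)
        for b in adj[a]:
            if b not in seen:
                seen.add(b)
                out[index[b]] = out[index[a]] + minimum_image(
                    positions[b] - positions[a], cell)
                queue.append(b)
    if len(seen) != len(atoms):
        raise GeometryError(
            f"molecule bond graph is disconnected ({len(seen)}/{len(atoms)} reached)")
    return out


def radius_of_gyration(trajectory: Trajectory, molecule: int) -> GyrationSeries:
    """Mass-weighted Rg of one molecule per frame, PBC-rewrapped first."""
    topo = trajectory.topology
    atoms = np.flatnonzero(topo.mol_index == molecule)
    if atoms.size < 2:
        raise SugarglassError(f"molecule {molecule} has fewer than 2 atoms")
    masses = topo.masses[atoms]
    total = masses.sum()
    if total <= 0:
        raise SugarglassError("zero total mass")
    rg = np.empty(trajectory.n_frames)
    for t, fr in enumerate(trajectory.frames):
        pos = make_whole(fr.positions, atoms, topo.bonds, fr.cell)
        com = (masses[:, None] * pos).sum(axis=0) / total
        rg[t] = np.sqrt((masses * ((pos - com) ** 2).sum(axis=1)).sum() / total)
    return GyrationSeries(times=trajectory.times, rg=rg)
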