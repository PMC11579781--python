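"""RDFs, contact scores, dihedral distributions, radii of gyration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sugarglass.core import Frame, Topology, Trajectory, UnitCell
from sugarglass.errors import GeometryError
from sugarglass.structure import (RDFProfile, compute_rdf, contact_scores,
                                  dihedral_angle, dihedral_distribution,
                                  make_whole, radius_of_gyration)
from sugarglass.synthetic import SyntheticSpec, ideal_gas_config


def ideal_gas_traj(n=1000, n_frames=20, L=5.0, seed=0):
    frames = []
    topo = None
    for k in range(n_frames):
        t, f = ideal_gas_config(SyntheticSpec(seed=seed + k, n_molecules=n,
                                              cell=(L, L, L)))
        topo = topo or t
        frames.append(Frame(float(k), f.positions, f.cell))
    return Trajectory(topology=topo, frames=frames)


class TestRDF:
    def test_ideal_gas_is_unity(self):
        traj = ideal_gas_traj(1000, 20)
        sel = tuple(range(1000))
        prof = compute_rdf(traj, sel, sel, bin_width=0.05, r_max=2.0)
        beyond = prof.r > 0.2
        assert np.abs(prof.g[beyond] - 1.0).max() < 0.05

    def test_two_fixed_atoms_single_bin(self):
        topo = Topology(names=["A", "B"], elements=["X", "X"],
                        masses=np.ones(2), mol_index=np.arange(2),
                        mol_kind=["model"] * 2)
        cell = UnitCell((8.0, 8.0, 8.0))
        frame = Frame(0.0, np.array([[1.0, 1.0, 1.0], [2.0, 1.0, 1.0]]), cell)
        traj = Trajectory(topology=topo, frames=[frame])
        prof = compute_rdf(traj, (0,), (1,), bin_width=0.05, r_max=2.0)
        occupied = np.flatnonzero(prof.g > 0)
        assert len(occupied) == 1
        r_bin = prof.r[occupied[0]]
        assert abs(r_bin - 1.0) <= 0.05
        # analytic shell normalisation: one count over rho * 4 pi r^2 dr
        rho = 1.0 / cell.volume
        expected = 1.0 / (4 * np.pi * r_bin**2 * 0.05 * rho)
        assert prof.g[occupied[0]] == pytest.approx(expected)

    def test_count_conservation_under_rebinning(self):
        """The integral of g(r) rho 4 pi r^2 dr counts neighbours either way."""
        traj = ideal_gas_traj(500, 5)
        sel = tuple(range(500))
        rho = 499 / traj.frames[0].cell.volume

        def neighbour_count(prof):
            return float(np.sum(prof.g * 4 * np.pi * prof.r**2 * rho
                                * prof.bin_width))

        fine = compute_rdf(traj, sel, sel, bin_width=0.01, r_max=2.0)
        coarse = compute_rdf(traj, sel, sel, bin_width=0.02, r_max=2.0)
        assert neighbour_count(fine) == pytest.approx(neighbour_count(coarse),
                                                      rel=1e-6)

    def test_r_max_beyond_half_cell_rejected(self):
        traj = ideal_gas_traj(10, 1, L=3.0)
        with pytest.raises(GeometryError):
            compute_rdf(traj, (0, 1), (2, 3), r_max=2.0)


class TestContactScores:
    def _profile(self, peak):
        r = np.linspace(0.05, 1.0, 20)
        g = np.full_like(r, 0.5)
        g[10] = peak
        return RDFProfile(r=r, g=g)

    def test_floor_scores_one(self):
        rdfs = {("O1", "HW"): self._profile(1.0), ("O2", "HW"): self._profile(100.0)}
        m = contact_scores(rdfs).scores
        assert m.loc["O1", "HW"] == 1

    def test_ceiling_scores_ten(self):
        rdfs = {("O1", "HW"): self._profile(2.0), ("O2", "HW"): self._profile(100.0)}
        assert contact_scores(rdfs).scores.loc["O2", "HW"] == 10

    def test_geometric_mean_rounds_half_even(self):
        # peak at sqrt(ceiling): 9 * 0.5 = 4.5 -> round-half-even -> 4 -> score 5
        rdfs = {("O1", "HW"): self._profile(10.0), ("O2", "HW"): self._profile(100.0)}
        assert contact_scores(rdfs).scores.loc["O1", "HW"] == 5

    def test_all_flat_scores_one(self):
        rdfs = {("O1", "HW"): self._profile(1.0), ("O2", "HW"): self._profile(0.9)}
        assert (contact_scores(rdfs).scores == 1).all().all()

    def test_order_independence(self):
        rdfs = {("O1", "HW"): self._profile(3.0), ("O2", "HW"): self._profile(30.0)}
        a = contact_scores(dict(rdfs)).scores
        b = contact_scores(dict(reversed(list(rdfs.items())))).scores
        assert a.equals(b)


def gram_schmidt_dihedral(p):
    """Independent dihedral construction via projection onto the b2 plane.

    The reference direction is the 2->1 bond (-b1) projected normal to the
    central bond; the angle is the signed rotation carrying it onto the
    projected 3->4 bond, right-handed about b2.
    """
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    b2u = b2 / np.linalg.norm(b2)
    u = -(b1 - np.dot(b1, b2u) * b2u)
    w = b3 - np.dot(b3, b2u) * b2u
    x = np.dot(u, w)
    y = np.dot(np.cross(b2u, u), w)
    return np.degrees(np.arctan2(y, x))


class TestDihedrals:
    def test_planar_cis_is_zero(self):
        p = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0.0]])
        assert dihedral_angle(p) == pytest.approx(0.0, abs=1e-10)

    def test_trans_is_180(self):
        p = np.array([[-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0.0]])
        assert abs(dihedral_angle(p)) == pytest.approx(180.0, abs=1e-10)

    def test_right_handed_sign(self):
        p = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 1.0]])
        q = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, -1.0]])
        assert dihedral_angle(p) == pytest.approx(-dihedral_angle(q))

    @given(st.lists(st.floats(-2, 2), min_size=12, max_size=12))
    def test_matches_gram_schmidt_oracle(self, coords):
        p = np.asarray(coords).reshape(4, 3)
        b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
        if (np.linalg.norm(np.cross(b1, b2)) < 1e-6
                or np.linalg.norm(np.cross(b2, b3)) < 1e-6):
            return  # degenerate: covered by the colinear test
        a = dihedral_angle(p)
        b = gram_schmidt_dihedral(p)
        assert abs((a - b + 180) % 360 - 180) < 1e-9

    def test_colinear_raises(self):
        p = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0.0]])
        with pytest.raises(GeometryError):
            dihedral_angle(p)

    def test_distribution_probabilities_and_rotation_invariance(self):
        rng = np.random.default_rng(8)
        topo = Topology(names=list("ABCD"), elements=["C"] * 4,
                        masses=np.ones(4), mol_index=np.zeros(4, int),
                        mol_kind=["model"] * 4,
                        bonds=[(0, 1), (1, 2), (2, 3)])
        cell = UnitCell((10, 10, 10))
        frames = [Frame(float(t), rng.normal(5, 0.5, (4, 3)), cell)
                  for t in range(40)]
        traj = Trajectory(topology=topo, frames=frames)
        dist = dihedral_distribution(traj, (0, 1, 2, 3), n_bins=36)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

        # rigid rotation of every frame leaves the histogram unchanged
        from sugarglass.synthetic import _random_rotation
        rot = _random_rotation(np.random.default_rng(3))
        frames_r = [Frame(f.time, (f.positions - 5) @ rot.T + 5, cell)
                    for f in frames]
        dist_r = dihedral_distribution(
            Trajectory(topology=topo, frames=frames_r), (0, 1, 2, 3), n_bins=36)
        assert np.allclose(dist.probabilities, dist_r.probabilities)


class TestGyration:
    def _two_atom_traj(self, d=0.4):
        topo = Topology(names=["A", "B"], elements=["C", "C"],
                        masses=np.ones(2), mol_index=np.zeros(2, int),
                        mol_kind=["model"] * 2, bonds=[(0, 1)])
        cell = UnitCell((5, 5, 5))
        frame = Frame(0.0, np.array([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]]), cell)
        return Trajectory(topology=topo, frames=[frame])

    def test_two_unit_masses(self):
        rg = radius_of_gyration(self._two_atom_traj(0.4), 0)
        assert rg.rg[0] == pytest.approx(0.2)

    def test_translation_invariance(self):
        traj = self._two_atom_traj()
        shifted = Trajectory(
            topology=traj.topology,
            frames=[Frame(0.0, traj.frames[0].positions + [1.3, 0.2, 2.0],
                          traj.frames[0].cell)])
        assert radius_of_gyration(shifted, 0).rg[0] == \
            pytest.approx(radius_of_gyration(traj, 0).rg[0])

    def test_pbc_split_molecule_made_whole(self):
        topo = Topology(names=["A", "B"], elements=["C", "C"],
                        masses=np.ones(2), mol_index=np.zeros(2, int),
                        mol_kind=["model"] * 2, bonds=[(0, 1)])
        cell = UnitCell((5, 5, 5))
        # bonded pair split across the boundary: true separation 0.4 nm
        frame = Frame(0.0, np.array([[0.1, 1, 1], [4.7, 1, 1.0]]), cell)
        traj = Trajectory(topology=topo, frames=[frame])
        assert radius_of_gyration(traj, 0).rg[0] == pytest.approx(0.2)

    def test_matches_direct_formula_on_random_cluster(self):
        rng = np.random.default_rng(4)
        n = 12
        pos = rng.normal(2.5, 0.3, (n, 3))
        masses = rng.uniform(1, 16, n)
        topo = Topology(names=[f"A{i}" for i in range(n)], elements=["C"] * n,
                        masses=masses, mol_index=np.zeros(n, int),
                        mol_kind=["model"] * n,
                        bonds=[(i, i + 1) for i in range(n - 1)])
        traj = Trajectory(topology=topo,
                          frames=[Frame(0.0, pos, UnitCell((50, 50, 50)))])
        com = (masses[:, None] * pos).sum(0) / masses.sum()
        expected = np.sqrt((masses * ((pos - com) ** 2).sum(1)).sum()
                           / masses.sum())
        assert radius_of_gyration(traj, 0).rg[0] == pytest.approx(expected,
                                                                  abs=1e-12)

    def test_disconnected_molecule_raises(self):
        topo = Topology(names=["A", "B"], elements=["C", "C"],
                        masses=np.ones(2), mol_index=np.zeros(2, int),
                        mol_kind=["model"] * 2)  # no bonds
        traj = Trajectory(topology=topo,
                          frames=[Frame(0.0, np.ones((2, 3)), UnitCell((5, 5, 5)))])
        with pytest.raises(GeometryError, match="disconnected"):
            radius_of_gyration(traj, 0)
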