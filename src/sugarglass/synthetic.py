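"""Synthetic input generators with known ground truth.

Every analysis in the package is exercised on data from this module:
ideal-gas boxes for RDF normalisation, planted donor/acceptor pairs with
prescribed O...O distance and H-D-A angle for the hydrogen-bond detector,
unit vectors undergoing isotropic rotational diffusion with a known
diffusion coefficient for correlation-time recovery, overdamped 1D
Langevin walkers on analytic potentials (optionally under an umbrella
restraint or well-tempered hill deposition) for the free-energy solvers,
and the composition series of the study.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from . import templates
from .core import Frame, Topology, Trajectory, UnitCell
from .errors import PackingError, StabilityError, SugarglassError
from .free_energy import HillsRecord
from .rotation import OrientationSeries
from .units import KB, MW_DISACCHARIDE, MW_WATER

__all__ = [
    "SyntheticSpec",
    "ModelPotential",
    "CompositionSpec",
    "ideal_gas_config",
    "planted_hbond_config",
    "rotational_diffusion_vectors",
    "langevin_1d",
    "LangevinResult",
    "UmbrellaBias",
    "WellTemperedBias",
    "build_composition_series",
    "TABLE_COMPOSITIONS",
    "toy_mixture_builder",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Common knobs for configuration generators."""

    seed: int = 0
    n_molecules: int = 0
    cell: tuple[float, float, float] = (5.0, 5.0, 5.0)
    #: rotational diffusion coefficient, rad^2/ps (where applicable)
    d_rot: float | None = None

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# analytic potentials (kJ/mol over nm)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelPotential:
    """Analytic 1D potential used as ground truth by the free-energy solvers.

    Forms
    -----
    ``harmonic``   : U = k/2 (z - z0)^2,          params (k, z0)
    ``double_well``: quartic with minima at (z1, z2), barrier height at the
                     midpoint equal to ``barrier``; U = b ((z-m)^2-a^2)^2/a^4
    ``flat``       : U = 0
    ``tabulated``  : linear interpolation of (grid, values)
    """

    form: str
    params: tuple = ()
    grid: np.ndarray | None = None
    values: np.ndarray | None = None

    def energy(self, z):
        z = np.asarray(z, dtype=float)
        if self.form == "harmonic":
            k, z0 = self.params
            return 0.5 * k * (z - z0) ** 2
        if self.form == "double_well":
            barrier, (z1, z2) = self.params[0], self.params[1]
            m, a = (z1 + z2) / 2.0, (z2 - z1) / 2.0
            return barrier * ((z - m) ** 2 - a**2) ** 2 / a**4
        if self.form == "flat":
            return np.zeros_like(z)
        if self.form == "tabulated":
            return np.interp(z, self.grid, self.values)
        raise ValueError(f"unknown potential form {self.form!r}")

    def force(self, z):
        z = np.asarray(z, dtype=float)
        if self.form == "harmonic":
            k, z0 = self.params
            return -k * (z - z0)
        if self.form == "double_well":
            barrier, (z1, z2) = self.params[0], self.params[1]
            m, a = (z1 + z2) / 2.0, (z2 - z1) / 2.0
            return -4.0 * barrier * ((z - m) ** 2 - a**2) * (z - m) / a**4
        if self.form == "flat":
            return np.zeros_like(z)
        if self.form == "tabulated":
            dv = np.gradient(np.asarray(self.values, float), np.asarray(self.grid, float))
            return -np.interp(z, self.grid, dv)
        raise ValueError(f"unknown potential form {self.form!r}")

    @staticmethod
    def harmonic(k: float, z0: float) -> "ModelPotential":
        return ModelPotential("harmonic", (float(k), float(z0)))

    @staticmethod
    def double_well(barrier: float, minima: tuple[float, float]) -> "ModelPotential":
        return ModelPotential("double_well", (float(barrier), tuple(minima)))

    @staticmethod
    def flat() -> "ModelPotential":
        return ModelPotential("flat")

    @staticmethod
    def tabulated(grid, values) -> "ModelPotential":
        return ModelPotential("tabulated", (), np.asarray(grid, float),
                              np.asarray(values, float))


# ---------------------------------------------------------------------------
# configuration generators
# ---------------------------------------------------------------------------

def ideal_gas_config(spec: SyntheticSpec) -> tuple[Topology, Frame]:
    """Uniform i.i.d. single-atom 'molecules' — the exact g(r)=1 reference."""
    n = spec.n_molecules
    if n < 2:
        raise SugarglassError("ideal gas needs at least 2 atoms")
    rng = spec.rng()
    cell = UnitCell(spec.cell)
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * cell.array
    topo = Topology(
        names=["X"] * n, elements=["X"] * n, masses=np.ones(n),
        mol_index=np.arange(n), mol_kind=["model"] * n)
    return topo, Frame(time=0.0, positions=pos, cell=cell)


def planted_hbond_config(n_pairs: int, d_oo: float, angle_deg: float,
                         spec: SyntheticSpec,
                         cutoff: float = 0.35) -> tuple[Topology, Frame]:
    """Plant ``n_pairs`` donor->acceptor water pairs with exact geometry.

    Each pair is one donor water whose first hydrogen points along +x and
    an acceptor water whose oxygen sits at distance ``d_oo`` from the donor
    oxygen, rotated by ``angle_deg`` from the O-H1 direction (so the H-D-A
    angle is exactly ``angle_deg``).  The donor's second hydrogen and both
    acceptor hydrogens point away, and pairs sit on a lattice whose
    spacing keeps inter-pair atom distances above ``2 * cutoff``, so the
    planted pairs are the only candidate bonds: the detector must report
    exactly ``n_pairs`` when (d_oo, angle_deg) is inside the criterion and
    zero otherwise.
    """
    cell = UnitCell(spec.cell)
    ang = math.radians(angle_deg)
    # pair-local coordinates (donor O at origin)
    oh = 0.10
    donor = np.array([
        [0.0, 0.0, 0.0],          # O(D)
        [oh, 0.0, 0.0],           # H1 along +x
        [-oh * 0.6, 0.0, oh * 0.8],  # H2 pointing backwards/up
    ])
    a_dir = np.array([math.cos(ang), math.sin(ang), 0.0])
    acc_o = d_oo * a_dir
    away = a_dir  # acceptor hydrogens continue away from the donor
    perp = np.array([-math.sin(ang), math.cos(ang), 0.0])
    acceptor = np.stack([
        acc_o,
        acc_o + oh * (0.8 * away + 0.6 * perp),
        acc_o + oh * (0.8 * away - 0.6 * perp),
    ])
    pair = np.concatenate([donor, acceptor])
    extent = float(np.linalg.norm(pair, axis=1).max())

    spacing = extent + 2.0 * cutoff + 0.05
    n_sites = [int(L // spacing) for L in cell.lengths]
    total_sites = int(np.prod(n_sites))
    if total_sites < n_pairs:
        raise PackingError(
            f"cell {cell.lengths} fits {total_sites} pair sites at spacing "
            f"{spacing:.2f} nm, need {n_pairs}")
    sites = [(i, j, k) for i in range(n_sites[0])
             for j in range(n_sites[1]) for k in range(n_sites[2])]
    rng = spec.rng()
    chosen = [sites[i] for i in rng.choice(total_sites, size=n_pairs, replace=False)]

    parts = []
    wt, _ = templates.water_template()
    for (i, j, k) in chosen:
        origin = (np.array([i, j, k]) + 0.5) * spacing
        parts.append((wt, donor + origin))
        parts.append((wt, acceptor + origin))
    topo, pos = templates.merge_templates(parts)
    return topo, Frame(time=0.0, positions=pos, cell=cell)


def rotational_diffusion_vectors(n_vectors: int, d_rot: float, dt: float,
                                 n_steps: int, seed: int = 0) -> OrientationSeries:
    """Unit vectors under isotropic rotational diffusion.

    Each step adds tangential Gaussian noise of variance ``2 d_rot dt`` per
    orthogonal axis and renormalises, so the first-rank autocorrelation has
    expectation exp(-2 d_rot t) and the correlation time is 1/(2 d_rot).
    """
    if d_rot < 0 or dt <= 0:
        raise ValueError("d_rot must be >= 0 and dt > 0")
    if d_rot * dt > 0.1:
        raise StabilityError(f"d_rot*dt = {d_rot * dt:.3g} > 0.1: step too coarse")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_vectors, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    out = np.empty((n_steps + 1, n_vectors, 3))
    out[0] = u
    sigma = math.sqrt(2.0 * d_rot * dt)
    for t in range(1, n_steps + 1):
        if sigma > 0.0:
            # orthonormal tangent basis per vector
            ref = np.where(np.abs(u[:, :1]) < 0.9,
                           np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
            e1 = np.cross(u, ref)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(u, e1)
            xi = rng.normal(size=(n_vectors, 2))
            u = u + sigma * (xi[:, :1] * e1 + xi[:, 1:] * e2)
            u /= np.linalg.norm(u, axis=1, keepdims=True)
        out[t] = u
    times = np.arange(n_steps + 1) * dt
    return OrientationSeries(times=times, vectors=out)


# ---------------------------------------------------------------------------
# overdamped Langevin sandbox (unit mass, friction in amu/ps)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UmbrellaBias:
    k: float      # kJ/(mol nm^2)
    z0: float     # nm


@dataclass(frozen=True)
class WellTemperedBias:
    height: float        # kJ/mol, initial Gaussian height
    sigma: float         # nm
    stride: int          # steps between deposits
    bias_factor: float   # gamma > 1


@dataclass
class LangevinResult:
    times: np.ndarray    # ps
    z: np.ndarray        # nm
    hills: HillsRecord | None = None


@njit(cache=True)
def _total_force(z, grid_lo, grid_dz, n_grid, pot_force,
                 use_metad, bias_force, use_umb, uk, uz0):
    x = (z - grid_lo) / grid_dz
    i0 = int(x)
    if i0 < 0:
        i0 = 0
    if i0 > n_grid - 2:
        i0 = n_grid - 2
    w = x - i0
    f = pot_force[i0] * (1.0 - w) + pot_force[i0 + 1] * w
    if use_metad:
        f += bias_force[i0] * (1.0 - w) + bias_force[i0 + 1] * w
    if use_umb:
        f += -uk * (z - uz0)
    return f


@njit(cache=True)
def _langevin_core(z0, dt, n_steps, inv_friction, noise_scale, noise,
                   grid_lo, grid_hi, grid_dz, pot_force,
                   use_umb, uk, uz0,
                   use_metad, h0, sigma, stride, kb_dt_well,
                   bias, bias_force, z_out,
                   hill_step, hill_center, hill_height):
    n_grid = pot_force.shape[0]
    z = z0
    z_out[0] = z
    n_hills = 0
    for step in range(n_steps):
        # Heun (predictor-corrector) step: second-order weak accuracy keeps
        # the stationary density accurate even where the bias is rough
        f = _total_force(z, grid_lo, grid_dz, n_grid, pot_force,
                         use_metad, bias_force, use_umb, uk, uz0)
        eta = noise_scale * noise[step]
        z_pred = z + dt * inv_friction * f + eta
        if z_pred < grid_lo:
            z_pred = 2.0 * grid_lo - z_pred
        if z_pred > grid_hi:
            z_pred = 2.0 * grid_hi - z_pred
        f_pred = _total_force(z_pred, grid_lo, grid_dz, n_grid, pot_force,
                              use_metad, bias_force, use_umb, uk, uz0)
        z = z + 0.5 * dt * inv_friction * (f + f_pred) + eta
        if not math.isfinite(z):
            return step, n_hills
        # reflective walls at the grid edges keep the walker on the grid
        if z < grid_lo:
            z = 2.0 * grid_lo - z
        if z > grid_hi:
            z = 2.0 * grid_hi - z
        z_out[step + 1] = z
        if use_metad and (step + 1) % stride == 0:
            xb = (z - grid_lo) / grid_dz
            ib = int(xb)
            if ib > n_grid - 2:
                ib = n_grid - 2
            wb = xb - ib
            v_here = bias[ib] * (1.0 - wb) + bias[ib + 1] * wb
            h = h0 * math.exp(-v_here / kb_dt_well)
            inv2s2 = 1.0 / (2.0 * sigma * sigma)
            for g in range(n_grid):
                dzg = grid_lo + g * grid_dz - z
                gauss = h * math.exp(-dzg * dzg * inv2s2)
                # deposit plus mirror images at the reflective walls, so the
                # bias stays consistent with the reflected walker density
                dzl = grid_lo + g * grid_dz - (2.0 * grid_lo - z)
                dzh = grid_lo + g * grid_dz - (2.0 * grid_hi - z)
                gl = h * math.exp(-dzl * dzl * inv2s2)
                gh = h * math.exp(-dzh * dzh * inv2s2)
                bias[g] += gauss + gl + gh
                # force = -dV/dz evaluated on the grid
                bias_force[g] += (gauss * dzg + gl * dzl + gh * dzh) * 2.0 * inv2s2
            hill_step[n_hills] = step + 1
            hill_center[n_hills] = z
            hill_height[n_hills] = h
            n_hills += 1
    return -1, n_hills


def langevin_1d(potential: ModelPotential, friction: float, temperature: float,
                dt: float, n_steps: int, seed: int = 0,
                bias: UmbrellaBias | WellTemperedBias | None = None,
                z_init: float | None = None,
                domain: tuple[float, float] = (-2.0, 2.0),
                n_grid: int = 4001) -> LangevinResult:
    """Overdamped (Brownian) dynamics on a 1D potential.

    Update: ``z += dt F(z)/friction + sqrt(2 kB T dt / friction) xi`` with
    standard-normal ``xi``.  An umbrella bias adds ``k/2 (z-z0)^2``; a
    well-tempered bias deposits a Gaussian of width ``sigma`` every
    ``stride`` steps with height ``h0 exp(-V(z)/kB dT)``,
    ``dT = (bias_factor-1) T``, and logs every deposit.  Reflective walls
    at the ``domain`` edges keep the walker on the force grid.
    """
    if friction <= 0 or dt <= 0 or temperature <= 0:
        raise ValueError("friction, dt and temperature must be positive")
    if isinstance(bias, UmbrellaBias) and bias.k * dt / friction > 0.5:
        raise StabilityError(
            f"umbrella k*dt/friction = {bias.k * dt / friction:.3g} > 0.5")

    lo, hi = float(domain[0]), float(domain[1])
    grid = np.linspace(lo, hi, n_grid)
    dz = grid[1] - grid[0]
    pot_force = np.ascontiguousarray(potential.force(grid), dtype=float)

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n_steps)
    noise_scale = math.sqrt(2.0 * KB * temperature * dt / friction)
    z0 = float(z_init) if z_init is not None else (
        bias.z0 if isinstance(bias, UmbrellaBias) else 0.5 * (lo + hi))

    use_umb = isinstance(bias, UmbrellaBias)
    use_metad = isinstance(bias, WellTemperedBias)
    if use_metad:
        if bias.bias_factor <= 1:
            raise ValueError("bias_factor must exceed 1")
        max_hills = n_steps // bias.stride + 1
        kb_dt_well = KB * (bias.bias_factor - 1.0) * temperature
    else:
        max_hills = 1
        kb_dt_well = 1.0

    z_out = np.empty(n_steps + 1)
    bias_grid = np.zeros(n_grid)
    bias_force = np.zeros(n_grid)
    hill_step = np.zeros(max_hills, dtype=np.int64)
    hill_center = np.zeros(max_hills)
    hill_height = np.zeros(max_hills)

    bad_step, n_hills = _langevin_core(
        z0, dt, n_steps, 1.0 / friction, noise_scale, noise,
        lo, hi, dz, pot_force,
        use_umb, bias.k if use_umb else 0.0, bias.z0 if use_umb else 0.0,
        use_metad,
        bias.height if use_metad else 0.0,
        bias.sigma if use_metad else 1.0,
        bias.stride if use_metad else 1,
        kb_dt_well, bias_grid, bias_force, z_out,
        hill_step, hill_center, hill_height)
    if bad_step >= 0:
        raise StabilityError(f"non-finite coordinate at step {bad_step}")

    hills = None
    if use_metad:
        hills = HillsRecord(
            times=hill_step[:n_hills] * dt,
            centers=hill_center[:n_hills].copy(),
            sigmas=np.full(n_hills, bias.sigma),
            heights=hill_height[:n_hills].copy(),
            bias_factor=bias.bias_factor,
            temperature=temperature)
    return LangevinResult(times=np.arange(n_steps + 1) * dt, z=z_out, hills=hills)


# ---------------------------------------------------------------------------
# composition series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionSpec:
    """One row of the study's composition grid."""

    n_sugar: int
    n_water: int
    mw_sugar: float = MW_DISACCHARIDE
    mw_water: float = MW_WATER

    def __post_init__(self):
        if self.n_sugar < 0 or self.n_water < 0:
            raise ValueError("molecule counts must be non-negative")
        if self.n_sugar == 0 and self.n_water == 0:
            raise SugarglassError("composition undefined: no molecules at all")

    @property
    def water_mass_pct(self) -> float:
        mw = self.n_water * self.mw_water
        ms = self.n_sugar * self.mw_sugar
        return 100.0 * mw / (mw + ms)


#: (n_sugar, n_water) pairs of the study's concentration grid, 0-100 wt%.
TABLE_COMPOSITIONS = [
    (2, 3700), (1, 3356), (2, 3341), (9, 3206), (18, 3038), (36, 2700),
    (53, 2363), (71, 2025), (89, 1688), (107, 1350), (124, 1013),
    (142, 675), (151, 506), (160, 338), (169, 169), (176, 34), (178, 0),
]


def build_composition_series(mw_sugar: float = MW_DISACCHARIDE,
                             mw_water: float = MW_WATER,
                             counts=None) -> list[CompositionSpec]:
    """Composition specs for a list of (n_sugar, n_water) pairs.

    Mass percent follows 100 n_w MW_w / (n_w MW_w + n_s MW_s); rounding is
    left to the caller (reporting time only).
    """
    if counts is None:
        counts = TABLE_COMPOSITIONS
    return [CompositionSpec(ns, nw, mw_sugar, mw_water) for ns, nw in counts]


# ---------------------------------------------------------------------------
# toy mixtures
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion construction)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1.0 + 1e-12:  # antiparallel: rotate pi about any perpendicular
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def toy_mixture_builder(composition: CompositionSpec, spec: SyntheticSpec,
                        sugar_kind: str = "sucrose",
                        min_separation: float = 0.3,
                        max_retries: int = 500,
                        attach_fraction: float = 0.6,
                        cluster_sugars: bool = False) -> tuple[Topology, Frame]:
    """Pack rigid model sugars and 3-site waters without overlap.

    Placement rule: every inter-molecular heavy-atom (non-hydrogen)
    distance stays at or above ``min_separation`` under periodic
    boundaries (hydrogens live inside their heavy atom's envelope, and a
    donated hydrogen must sit ~0.2 nm from its acceptor, so they are
    exempt).  A fraction ``attach_fraction`` of molecules is inserted as
    a hydrogen-bond donor to a random already-placed acceptor — donor
    oxygen at 0.30-0.34 nm with the O-H vector aimed at the acceptor —
    planting the orientational correlations of a liquid, without which
    random packings at insertable densities carry almost no geometric
    bonds.  The rest are placed at uniform random positions and
    orientations.  ``cluster_sugars`` biases sugar centres toward the
    box centre (Gaussian, sigma 0.2 L), emulating the aggregated state
    that thermal annealing produces.  Deterministic under the spec seed.
    """
    cell = UnitCell(spec.cell)
    L = cell.array
    rng = spec.rng()
    sugar = templates.sugar_template(sugar_kind)
    water = templates.water_template()

    placed_heavy: list[np.ndarray] = []
    parts: list[tuple[Topology, np.ndarray]] = []
    reg_acc: list[np.ndarray] = []      # wrapped acceptor-oxygen positions

    def heavy(topo: Topology, pos: np.ndarray) -> np.ndarray:
        return pos[[i for i, e in enumerate(topo.elements) if e != "H"]]

    def try_place(topo_t: Topology, local_pos: np.ndarray, confine: bool,
                  p_attach: float) -> None:
        acc_pool = np.concatenate(reg_acc) if reg_acc else None
        tree = (cKDTree(np.concatenate(placed_heavy), boxsize=L)
                if placed_heavy else None)
        for _ in range(max_retries):
            attach = (acc_pool is not None and topo_t.donor_groups
                      and rng.uniform() < p_attach)
            if attach:
                target = acc_pool[rng.integers(len(acc_pool))]
                n = rng.normal(size=3)
                n /= np.linalg.norm(n)
                d_oo = rng.uniform(0.30, 0.34)
                o_i, h_i = topo_t.donor_groups[
                    rng.integers(len(topo_t.donor_groups))]
                u = local_pos[h_i] - local_pos[o_i]
                u /= np.linalg.norm(u)
                rot = _axis_rotation(-n, rng.uniform(0, 2 * np.pi)) \
                    @ _rotation_aligning(u, -n)
                cand = (local_pos - local_pos[o_i]) @ rot.T + target + d_oo * n
            else:
                if confine:
                    origin = (0.5 * L + 0.2 * L * rng.normal(size=3)) % L
                else:
                    origin = rng.uniform(size=3) * L
                cand = local_pos @ _random_rotation(rng).T + origin
            cand_wrapped = cand % L
            if tree is not None:
                dmin, _ = tree.query(heavy(topo_t, cand_wrapped), k=1)
                if float(np.min(dmin)) < min_separation * (1 - 1e-9):
                    continue
            placed_heavy.append(heavy(topo_t, cand_wrapped))
            parts.append((topo_t, cand))
            if topo_t.acceptor_atoms:
                reg_acc.append(cand_wrapped[topo_t.acceptor_atoms])
            return
        raise PackingError(
            f"could not place molecule after {max_retries} tries at density "
            f"{composition.n_sugar} sugars + {composition.n_water} waters "
            f"in {cell.lengths} nm")

    # the aggregated (annealed) state both clusters sugars spatially and
    # bonds them to each other more often
    sugar_attach = max(attach_fraction, 0.9) if cluster_sugars else attach_fraction
    for _ in range(composition.n_sugar):
        try_place(sugar[0], sugar[1], cluster_sugars, sugar_attach)
    for _ in range(composition.n_water):
        try_place(water[0], water[1], False, attach_fraction)

    topo, pos = templates.merge_templates(parts)
    return topo, Frame(time=0.0, positions=pos, cell=cell)


def mixture_trajectory(composition: CompositionSpec, spec: SyntheticSpec,
                       n_frames: int = 3, **kw) -> Trajectory:
    """Independent packings stacked as frames (a static 'pseudo-trajectory').

    Frames are statistically independent configurations of the same
    composition; useful wherever an analysis averages over frames.
    """
    frames = []
    topo = None
    for k in range(n_frames):
        sub = SyntheticSpec(seed=spec.seed * 100003 + k, n_molecules=spec.n_molecules,
                            cell=spec.cell, d_rot=spec.d_rot)
        t, fr = toy_mixture_builder(composition, sub, **kw)
        topo = topo or t
        frames.append(Frame(time=float(k), positions=fr.positions, cell=fr.cell))
    return Trajectory(topology=topo, frames=frames,
                      water_mass_pct=composition.water_mass_pct)
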