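"""Free-energy post-processing: WHAM, well-tempered metadynamics, binding.

Conventions: distances in nm, energies in kJ/mol, kB = 0.0083144626
kJ/(mol K).  A potential of mean force w(z) is defined up to an additive
constant; every routine states its zero convention, and the binding free
energy is invariant to that constant by construction.

The binding free energy is the ratio of Boltzmann-weighted integrals over
the bound region B = [z_min, boundary] and unbound region
U = (boundary, z_max]:

    dG = -kB T ln( int_B exp(-w/kB T) dz / int_U exp(-w/kB T) dz )

with the bound-state boundary defaulting to 1.5 nm and the profile
extending to 1.7 nm in the reference workflow.  No 4 pi z^2 volume factor
is applied by default; ``volume_correction=True`` enables it for
sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (ConsistencyError, ConvergenceError, CoverageError,
                     GeometryError, SugarglassError)
from .units import KB, T_REF

__all__ = [
    "UmbrellaWindowData",
    "HillsRecord",
    "PMFProfile",
    "BindingResult",
    "DepthReport",
    "wham_pmf",
    "average_pmf",
    "metad_fes",
    "metad_fes_reweighted",
    "binding_free_energy",
    "pmf_depth_report",
    "read_hills",
    "write_hills",
    "read_colvar",
    "write_colvar",
    "read_pmf",
    "write_pmf",
]


@dataclass
class UmbrellaWindowData:
    """One umbrella window: harmonic restraint k/2 (z - center)^2."""

    center: float                  # nm
    k: float                       # kJ/(mol nm^2)
    series: np.ndarray             # sampled collective variable, nm
    temperature: float = T_REF

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if self.series.size == 0:
            raise ValueError("empty umbrella series")
        if self.k < 0:
            raise ValueError("force constant must be >= 0")


@dataclass
class HillsRecord:
    """Deposited metadynamics Gaussians (PLUMED-style HILLS content)."""

    times: np.ndarray              # ps
    centers: np.ndarray            # nm
    sigmas: np.ndarray             # nm
    heights: np.ndarray            # kJ/mol, as deposited (tempered)
    bias_factor: float
    temperature: float = T_REF

    def __post_init__(self):
        for name in ("times", "centers", "sigmas", "heights"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        if not (self.centers.size == self.sigmas.size == self.heights.size == n):
            raise ValueError("hills columns must have equal length")
        if n and (np.any(self.sigmas <= 0) or np.any(self.heights <= 0)):
            raise ValueError("sigmas and heights must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")

    @property
    def n_hills(self) -> int:
        return self.times.size


@dataclass
class PMFProfile:
    """Potential of mean force w(z) on a distance grid."""

    z: np.ndarray                  # nm
    w: np.ndarray                  # kJ/mol
    zero_convention: str = "min"
    source: str = "analytic"       # {wham, metadynamics, analytic}
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.z.shape != self.w.shape:
            raise ValueError("z and w must share a shape")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("PMF must be finite on its grid")


@dataclass
class BindingResult:
    dg: float                      # kJ/mol
    bound_region: tuple[float, float]
    unbound_region: tuple[float, float]
    temperature: float


@dataclass
class DepthReport:
    """First-minimum depths under the plateau-zero convention."""

    order: list[str]               # labels, deepest first
    depths: dict[str, float]       # kJ/mol (negative = bound)
    minima_positions: dict[str, float]
    depth_sum: float
    excluded: list[str]            # monotone profiles with no interior minimum


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def wham_pmf(windows: list[UmbrellaWindowData], bin_width: float = 0.01,
             tolerance: float = 1e-8, max_iter: int = 100_000,
             min_count: int = 10) -> PMFProfile:
    """Self-consistent WHAM over binned umbrella-window histograms.

    Iterates the standard update for the unbiased bin probabilities and
    the per-window free-energy constants f_i until the largest change in
    any f_i falls below ``tolerance`` (kJ/mol).  Bins visited fewer than
    ``min_count`` times total are treated as unsampled and dropped from
    the profile (a near-empty tail bin carries kBT-scale noise).  The PMF
    is zeroed at its largest-z retained bin.  Adjacent windows whose
    sampled ranges do not overlap raise :class:`CoverageError`.
    """
    if not windows:
        raise SugarglassError("no umbrella windows supplied")
    T = windows[0].temperature
    beta = 1.0 / (KB * T)
    z_lo = min(w.series.min() for w in windows)
    z_hi = max(w.series.max() for w in windows)
    n_bins = max(int(np.ceil((z_hi - z_lo) / bin_width)), 1)
    edges = z_lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.series, bins=edges)[0] for w in windows])
    n_i = counts.sum(axis=1).astype(float)
    total = counts.sum(axis=0).astype(float)

    # adjacent windows (by center) must overlap along z; isolated empty
    # bins in sparse tails merely drop out of the profile
    order = np.argsort([w.center for w in windows])
    for i0, i1 in zip(order, order[1:]):
        lo, hi = windows[i0], windows[i1]
        if lo.series.max() < hi.series.min():
            raise CoverageError(
                f"windows at z0={lo.center:.3f} and z0={hi.center:.3f} nm do not "
                f"overlap: gap ({lo.series.max():.3f}, {hi.series.min():.3f}) nm")

    bias = 0.5 * np.asarray([w.k for w in windows])[:, None] \
        * (centers[None, :] - np.asarray([w.center for w in windows])[:, None]) ** 2
    boltz = np.exp(-beta * bias)            # (n_windows, n_bins)

    f = np.zeros(len(windows))
    for _ in range(max_iter):
        denom = (n_i[:, None] * np.exp(beta * f)[:, None] * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        norm = (boltz * p[None, :]).sum(axis=1)
        f_new = -np.log(norm) / beta
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last residual {delta:.3e} kJ/mol)")

    ok = total >= max(min_count, 1)
    with np.errstate(divide="ignore"):
        w = np.where(ok & (p > 0), -np.log(np.where(p > 0, p, 1.0)) / beta, np.nan)
    finite = np.flatnonzero(np.isfinite(w))
    w = w - w[finite[-1]]                   # zero at the largest-z finite bin
    return PMFProfile(z=centers[finite], w=w[finite],
                      zero_convention="largest_z", source="wham")


def _rezero_plateau(z: np.ndarray, w: np.ndarray, plateau_frac: float) -> np.ndarray:
    n_tail = max(int(round(plateau_frac * z.size)), 1)
    return w - w[-n_tail:].mean()


def average_pmf(profiles: list[PMFProfile],
                plateau_frac: float = 0.05) -> PMFProfile:
    """Average several PMFs after re-zeroing each at the shared plateau.

    Profiles are interpolated onto the common-z-range grid of the first
    profile; each is shifted so the mean over the last ``plateau_frac`` of
    the common grid is zero, making the average invariant to per-profile
    additive constants.
    """
    if len(profiles) < 2:
        raise SugarglassError("need at least 2 profiles to average")
    lo = max(p.z.min() for p in profiles)
    hi = min(p.z.max() for p in profiles)
    if lo >= hi:
        raise ConsistencyError("profiles have disjoint z ranges")
    base = profiles[0]
    grid = base.z[(base.z >= lo) & (base.z <= hi)]
    stack = np.stack([
        _rezero_plateau(grid, np.interp(grid, p.z, p.w), plateau_frac)
        for p in profiles])
    return PMFProfile(z=grid, w=stack.mean(axis=0), sd=stack.std(axis=0, ddof=0),
                      zero_convention=f"plateau (last {plateau_frac:.0%})",
                      source=profiles[0].source)


# ---------------------------------------------------------------------------
# well-tempered metadynamics reconstruction
# ---------------------------------------------------------------------------

def metad_fes(hills: HillsRecord, grid: np.ndarray,
              zero: str = "min",
              time_average_from: float | None = None,
              reflect: tuple[float, float] | None = None) -> PMFProfile:
    """Free energy from deposited hills: F(z) = -gamma/(gamma-1) V(z).

    V(z) is the sum of the deposited (already tempered) Gaussians.  With
    ``time_average_from`` = f in (0, 1) the estimator is averaged over all
    deposit times in the last (1-f) fraction of the run, which damps the
    O(h) bias-fluctuation noise of the instantaneous estimate while
    leaving the (arbitrary) additive constant unaffected.  ``reflect``
    gives the reflective-wall positions of the sampler, adding the
    mirror-image Gaussians the deposition used at those walls.  ``zero``
    is "min" (shift so min F = 0) or "none" (raw estimator).
    """
    grid = np.asarray(grid, dtype=float)
    gamma = hills.bias_factor
    n = hills.n_hills
    if n == 0:
        v = np.zeros_like(grid)
    else:
        centers = [hills.centers]
        if reflect is not None:
            lo, hi = reflect
            centers += [2.0 * lo - hills.centers, 2.0 * hi - hills.centers]
        gauss = sum(
            hills.heights[:, None] * np.exp(
                -((grid[None, :] - c[:, None]) ** 2)
                / (2.0 * hills.sigmas[:, None] ** 2))
            for c in centers)
        if time_average_from is None:
            v = gauss.sum(axis=0)
        else:
            k0 = min(int(time_average_from * n), n - 1)
            m = n - k0
            # mean over checkpoints t = k0..n-1 of V_t = sum_{i<=t} g_i:
            # deposits before k0 weigh 1, later ones (n - i)/m
            weights = np.ones(n)
            weights[k0:] = (n - np.arange(k0, n)) / m
            v = (weights[:, None] * gauss).sum(axis=0)
    fes = -(gamma / (gamma - 1.0)) * v
    if zero == "min":
        fes = fes - fes.min()
    elif zero != "none":
        raise ValueError("zero must be 'min' or 'none'")
    return PMFProfile(z=grid, w=fes, zero_convention=zero, source="metadynamics")


def metad_fes_reweighted(hills: HillsRecord, series: np.ndarray,
                         grid: np.ndarray, from_fraction: float = 0.3,
                         reflect: tuple[float, float] | None = None,
                         smooth_bins: float = 2.0,
                         zero: str = "min") -> PMFProfile:
    """Histogram-reweighted free energy from a metadynamics run.

    In the quasi-stationary regime the walker samples
    rho(z) ~ exp(-beta (F + V)), so F = -kB T ln rho - V up to a constant.
    Using the sampled histogram over the last (1 - ``from_fraction``) of
    the run together with the time-averaged bias over the same window
    cancels the bias-fluctuation noise of the hill-sum estimator against
    the corresponding dips in the sampling.  The histogram is smoothed
    with a Gaussian kernel of ``smooth_bins`` bins (kept well below the
    hill width so the curvature bias stays negligible).
    """
    from scipy.ndimage import gaussian_filter1d

    grid = np.asarray(grid, dtype=float)
    beta = 1.0 / (KB * hills.temperature)
    gamma = hills.bias_factor
    fes_avg = metad_fes(hills, grid, zero="none",
                        time_average_from=from_fraction, reflect=reflect)
    v_avg = -fes_avg.w * (gamma - 1.0) / gamma
    tail = np.asarray(series, float)[int(from_fraction * len(series)):]
    bw = grid[1] - grid[0]
    edges = np.concatenate([grid - bw / 2, [grid[-1] + bw / 2]])
    hist = np.histogram(tail, bins=edges)[0].astype(float)
    if smooth_bins > 0:
        hist = gaussian_filter1d(hist, smooth_bins, mode="nearest")
    if np.any(hist <= 0):
        raise SugarglassError(
            "unsampled bins inside the requested grid; shrink the grid or "
            "extend the run")
    fes = -np.log(hist) / beta - v_avg
    if zero == "min":
        fes = fes - fes.min()
    elif zero != "none":
        raise ValueError("zero must be 'min' or 'none'")
    return PMFProfile(z=grid, w=fes, zero_convention=zero, source="metadynamics")


# ---------------------------------------------------------------------------
# binding free energy (bound/unbound Boltzmann-integral ratio)
# ---------------------------------------------------------------------------

def binding_free_energy(pmf: PMFProfile, boundary: float = 1.5,
                        temperature: float = T_REF,
                        volume_correction: bool = False) -> BindingResult:
    """Ratio-of-integrals binding free energy with trapezoidal quadrature.

    Invariant to additive shifts of w(z) and insensitive to grid
    refinement; the boundary point is inserted by linear interpolation so
    both regions integrate to their exact extents.
    """
    z, w = pmf.z, pmf.w
    if not (z.min() < boundary < z.max()):
        raise GeometryError(
            f"boundary {boundary} nm outside PMF grid [{z.min()}, {z.max()}]")
    beta = 1.0 / (KB * temperature)
    w = w - w.min()  # shift for numerical range only; result is shift-invariant
    wb = np.interp(boundary, z, w)
    mask_b = z <= boundary
    zb = np.append(z[mask_b], boundary)
    fb = np.append(w[mask_b], wb)
    zu = np.insert(z[~mask_b], 0, boundary)
    fu = np.insert(w[~mask_b], 0, wb)
    jac_b = 4.0 * np.pi * zb**2 if volume_correction else 1.0
    jac_u = 4.0 * np.pi * zu**2 if volume_correction else 1.0
    int_b = np.trapezoid(jac_b * np.exp(-beta * fb), zb)
    int_u = np.trapezoid(jac_u * np.exp(-beta * fu), zu)
    dg = -np.log(int_b / int_u) / beta
    return BindingResult(dg=float(dg),
                         bound_region=(float(z.min()), float(boundary)),
                         unbound_region=(float(boundary), float(z.max())),
                         temperature=temperature)


def pmf_depth_report(profiles: dict[str, PMFProfile],
                     plateau_frac: float = 0.05) -> DepthReport:
    """Rank profiles by the depth of their first interior minimum.

    Each profile is re-zeroed at its large-z plateau; the first local
    minimum (scanning from small z) defines the depth.  Monotone profiles
    with no interior minimum are flagged and excluded from the sum.
    """
    depths: dict[str, float] = {}
    positions: dict[str, float] = {}
    excluded: list[str] = []
    for label, p in profiles.items():
        w = _rezero_plateau(p.z, p.w, plateau_frac)
        interior = np.flatnonzero(
            (w[1:-1] < w[:-2]) & (w[1:-1] <= w[2:])) + 1
        if interior.size == 0:
            excluded.append(label)
            continue
        i = int(interior[0])
        depths[label] = float(w[i])
        positions[label] = float(p.z[i])
    order = sorted(depths, key=depths.get)
    return DepthReport(order=order, depths=depths, minima_positions=positions,
                       depth_sum=float(sum(depths.values())), excluded=excluded)


# ---------------------------------------------------------------------------
# PLUMED-style text I/O
# ---------------------------------------------------------------------------

def write_hills(hills: HillsRecord, path) -> None:
    """Whitespace-column HILLS: time center sigma height biasfactor."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS time center sigma height biasf\n")
        for t, c, s, h in zip(hills.times, hills.centers,
                              hills.sigmas, hills.heights):
            fh.write(f"{t:14.6f} {c:12.8f} {s:12.8f} {h:14.9f} "
                     f"{hills.bias_factor:8.3f}\n")


def read_hills(path, temperature: float = T_REF,
               heights_prescaled: bool = True) -> HillsRecord:
    """Parse a HILLS file.

    ``heights_prescaled=True`` (the PLUMED convention) means the height
    column already carries the well-tempered scaling; ``False`` treats the
    column as nominal heights and rescales by (gamma-1)/gamma, the
    convention of engines that log the unscaled height.  The chosen
    interpretation is logged.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.lstrip().startswith(("#", "@")):
                continue
            rows.append([float(x) for x in line.split()[:5]])
    if not rows:
        raise SugarglassError(f"{path}: no hills found")
    arr = np.asarray(rows)
    gamma = float(arr[0, 4]) if arr.shape[1] >= 5 else 50.0
    heights = arr[:, 3]
    if not heights_prescaled:
        warnings.warn("interpreting HILLS heights as nominal; "
                      "rescaling by (gamma-1)/gamma")
        heights = heights * (gamma - 1.0) / gamma
    return HillsRecord(times=arr[:, 0], centers=arr[:, 1], sigmas=arr[:, 2],
                       heights=heights, bias_factor=gamma,
                       temperature=temperature)


def write_colvar(times: np.ndarray, values: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("#! FIELDS time cv\n")
        for t, v in zip(times, values):
            fh.write(f"{t:14.6f} {v:14.9f}\n")


def read_colvar(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, comments=("#", "@"))
    data = np.atleast_2d(data)
    return data[:, 0], data[:, 1]


def write_pmf(pmf: PMFProfile, path) -> None:
    """XVG-compatible two-column output with a comment header."""
    with open(path, "w") as fh:
        fh.write(f"# sugarglass PMF  source={pmf.source}  "
                 f"zero={pmf.zero_convention}\n")
        fh.write("# z_nm  w_kJ_per_mol\n")
        for z, w in zip(pmf.z, pmf.w):
            fh.write(f"{z:12.6f} {w:14.8f}\n")


def read_pmf(path, source: str = "analytic") -> PMFProfile:
    data = np.atleast_2d(np.loadtxt(path, comments=("#", "@")))
    return PMFProfile(z=data[:, 0], w=data[:, 1], zero_convention="as_read",
                      source=source)
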