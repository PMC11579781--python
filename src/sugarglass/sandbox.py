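"""Reference free-energy sandbox: one double well, two reconstruction routes.

This module fixes the study conditions under which the WHAM and
well-tempered-metadynamics solvers are validated against an analytic
ground truth: an overdamped walker on a 10 kJ/mol double well with minima
at 0.3 and 1.7 nm, umbrella-sampled with 22 windows at k = 45
kJ/(mol nm^2) and 2x10^4 steps per window, or biased well-tempered with
bias factor 50, hill height 1.2 kJ/mol, width 0.05 nm, one deposit every
500 steps over 10^6 steps — the biasing settings of the reference
workflow.  The integrator step ratio dt/friction = 6x10^-4 is chosen for
weak-order accuracy at the well's stiffness; reflective walls sit at
0.15/1.85 nm, outside the window ladder.

Everything the two routes share (potential, domain, temperature, grids)
lives here so cross-method comparisons are apples to apples.
"""

from __future__ import annotations

import numpy as np

from .free_energy import (PMFProfile, UmbrellaWindowData, average_pmf,
                          metad_fes_reweighted, wham_pmf)
from .synthetic import (LangevinResult, ModelPotential, UmbrellaBias,
                        WellTemperedBias, langevin_1d)

__all__ = [
    "DOUBLE_WELL",
    "DOMAIN",
    "WINDOW_CENTERS",
    "run_umbrella_windows",
    "umbrella_pmf",
    "umbrella_pmf_averaged",
    "run_metad",
    "metad_pmf",
    "reference_profile",
]

DOUBLE_WELL = ModelPotential.double_well(10.0, (0.3, 1.7))
DOMAIN = (0.15, 1.85)
DT = 6e-4                 # ps
FRICTION = 1.0            # amu/ps
TEMPERATURE = 298.0       # K

WINDOW_CENTERS = np.linspace(0.3, 1.7, 22)
UMBRELLA_K = 45.0         # kJ/(mol nm^2)
#: the reference workflow pulls with five different restraint stiffnesses
#: and averages the resulting profiles
UMBRELLA_K_SET = (45.0, 35.0, 55.0, 25.0, 15.0)
WINDOW_STEPS = 20_000
WINDOW_BURN = 2_000       # discarded as equilibration (10%)

METAD_STEPS = 1_000_000
METAD_BIAS = WellTemperedBias(height=1.2, sigma=0.05, stride=500,
                              bias_factor=50.0)
METAD_TAIL_FROM = 0.3     # reweighting window start (fraction of run)

FES_GRID = np.linspace(0.3, 1.7, 141)


def run_umbrella_windows(seed: int, k: float = UMBRELLA_K,
                         potential: ModelPotential = DOUBLE_WELL,
                         ) -> list[UmbrellaWindowData]:
    """One umbrella ladder: 22 windows, ``WINDOW_STEPS`` steps each."""
    windows = []
    for i, c in enumerate(WINDOW_CENTERS):
        res = langevin_1d(potential, friction=FRICTION,
                          temperature=TEMPERATURE, dt=DT,
                          n_steps=WINDOW_STEPS, seed=(seed + i) % (2**31),
                          bias=UmbrellaBias(k=k, z0=float(c)),
                          z_init=float(c), domain=DOMAIN)
        windows.append(UmbrellaWindowData(center=float(c), k=k,
                                          series=res.z[WINDOW_BURN:],
                                          temperature=TEMPERATURE))
    return windows


def umbrella_pmf(seed: int, k: float = UMBRELLA_K,
                 potential: ModelPotential = DOUBLE_WELL) -> PMFProfile:
    return wham_pmf(run_umbrella_windows(seed, k=k, potential=potential))


def umbrella_pmf_averaged(seed: int,
                          potential: ModelPotential = DOUBLE_WELL) -> PMFProfile:
    """One PMF per restraint stiffness, averaged — the multi-pull route."""
    profiles = [umbrella_pmf((seed + 1000 * j) % (2**31), k=k,
                             potential=potential)
                for j, k in enumerate(UMBRELLA_K_SET)]
    return average_pmf(profiles)


def run_metad(seed: int,
              potential: ModelPotential = DOUBLE_WELL) -> LangevinResult:
    return langevin_1d(potential, friction=FRICTION, temperature=TEMPERATURE,
                       dt=DT, n_steps=METAD_STEPS, seed=seed % (2**31),
                       bias=METAD_BIAS, z_init=0.3, domain=DOMAIN)


def metad_pmf(seed: int, grid: np.ndarray | None = None,
              potential: ModelPotential = DOUBLE_WELL) -> PMFProfile:
    """Histogram-reweighted well-tempered FES on the shared grid."""
    grid = FES_GRID if grid is None else grid
    res = run_metad(seed, potential=potential)
    return metad_fes_reweighted(res.hills, res.z, grid,
                                from_fraction=METAD_TAIL_FROM, reflect=DOMAIN)


def reference_profile(grid: np.ndarray | None = None,
                      potential: ModelPotential = DOUBLE_WELL) -> PMFProfile:
    grid = FES_GRID if grid is None else grid
    return PMFProfile(z=grid, w=potential.energy(grid),
                      zero_convention="analytic", source="analytic")


def aligned_error(pmf: PMFProfile, reference: PMFProfile,
                  span: tuple[float, float] | None = None) -> np.ndarray:
    """Pointwise profile error after removing the free additive constant.

    Profiles are compared on the intersection of their grids (reference
    interpolated), optionally restricted to ``span``, with the mean
    difference subtracted — a PMF is defined only up to a constant.
    """
    lo = max(pmf.z.min(), reference.z.min())
    hi = min(pmf.z.max(), reference.z.max())
    if span is not None:
        lo, hi = max(lo, span[0]), min(hi, span[1])
    m = (pmf.z >= lo) & (pmf.z <= hi)
    err = pmf.w[m] - np.interp(pmf.z[m], reference.z, reference.w)
    return err - err.mean()
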