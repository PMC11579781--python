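# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Units and geometry

GROMACS conventions package-wide: nm, ps, kJ/mol, K, degrees at API
boundaries; k_B = 0.0083144626 kJ/(mol·K); masses in g/mol. Cells are
orthorhombic only (the target systems are cubic ~5 nm boxes with
isotropic coupling); triclinic input is rejected with a clear error.
Minimum-image components lie in (−L/2, L/2]. Atom indexing is 0-based in
memory and 1-based only inside GRO records.

## Model molecules

The disaccharide templates are rigid 23-site schematics — two six-membered
rings of scaffold carbons and hydroxyl oxygens, a ring-ether oxygen per
ring and one glycosidic oxygen — carrying the standard label set (eight
hydroxyl O–H groups such as `O2-H8`, three ether oxygens such as `O5`).
Trehalose declares mirror-pair symmetry classes
({O2-H8, O11-H22}, {O3-H9, O10-H21}, {O4-H10, O9-H20}, {O5-H11, O8-H19},
{O1, O7}, {O6}); sucrose none. The geometry is schematic, not a
force-field conformer: what the analyses need is the label inventory,
donor/acceptor declarations, a connected bond graph for rewrapping
molecules across periodic boundaries, and the property (by construction)
that no intramolecular pair satisfies the default hydrogen-bond
criterion, so planted bond counts stay exact. Water is a rigid 3-site
model (O–H 0.1 nm, 109.47°).

## Hydrogen bonds

A bond is a D–H···A triple with O···O ≤ 0.35 nm and ∠(H–D–A) ≤ 30°, the
defaults of the MD engine the target studies use; both cutoffs are
configuration-exposed because geometric definitions differ between
engines. Each triple counts once, so a water can donate twice.
Intramolecular sugar triples are counted (they are physical; the model
templates simply never produce one at the default criterion). Category
labels follow molecule kinds, water versus everything sugar-like.

Two normalisations coexist deliberately: whole-system counts are divided
by the number of **all** oxygens (sugar + water), per-group tables by the
number of group instances. The per-oxygen denominator choice (including
water oxygens) is the reading consistent with comparing systems of very
different sizes on one axis; it is logged in the series object.

Per-group tables attribute a bond to every selected group containing one
of its end atoms, excluding bonds internal to one group instance;
symmetry-class members are averaged into one row (class total / class
size), which is idempotent. Detection switches to a periodic
cell-list search above 1000 atoms; candidate pairs are evaluated by the
same arithmetic as the brute-force path, so results are bitwise
identical (tested).

## Structure

RDFs use shell normalisation 4πr²Δr·ρ_B with the self-atom excluded from
ρ_B when the selections overlap; default bins of 0.002 nm to 2.0 nm (or
half the cell). Contact scores replace the visual scoring of published
contact maps with an explicit reproducible rule:
score = 1 + round(9·log₁₀(max g / 1) / log₁₀(g_ceil / 1)), rounded
half-even and clipped to [1, 10], with g_ceil the largest maximum in the
profile set; all-flat sets score 1. Published score tables are therefore
not comparison targets — the rule, not the values, is the contract.

Dihedrals use the standard atan2 construction on minimum-image bond
vectors, right-handed IUPAC sign, range (−180°, 180°]; colinear frames
are skipped and counted. Radii of gyration are mass-weighted about the
centre of mass after making the molecule whole by bond-graph traversal —
a PBC-split molecule corrupts both dihedrals and R_g. Exact quadruplets
for real sugars depend on force-field topology files and are taken as
configuration.

## Rotational dynamics

The observable is the first-rank (P1) autocorrelation of O→H unit
vectors averaged over all time origins and groups (FFT-based). The
correlation time is the e-fold constant of a single-exponential fit —
the operational reading of "time to rotate by one radian" consistent
with an exponential-fit protocol; rank and fit window are exposed. The
fit is linearised log-least-squares with weights C², refined by one
nonlinear pass, over the window where C > 0.05; a C(t) that never decays
below 1/e is reported non-converged rather than raising. The synthetic
generator evolves unit vectors by tangential Gaussian increments of
variance 2 D_r dt per orthogonal axis (renormalised each step), giving
C(t) = exp(−2 D_r t) and τ = 1/(2 D_r); accuracy requires D_r·dt ≲ 0.01
and the generator refuses D_r·dt > 0.1.

## Langevin sandbox

Overdamped (Brownian) dynamics with unit mass and friction γ in amu/ps:
z ← z + dt·F/γ + √(2 k_BT dt/γ)·ξ, integrated with a Heun
predictor–corrector. The corrector matters: plain Euler–Maruyama carries
a stationary-density bias of order U″·dt/γ that corrupts both WHAM
(tilted basin depths) and metadynamics (amplified response to bias
roughness); the Heun step removes it to second order. Forces come from a
4001-point tabulated grid; reflective walls at the domain edges keep the
walker on the grid. Only the ratio dt/γ affects the dynamics.

Well-tempered deposition follows the standard rule: every `stride` steps
a Gaussian of width σ and height h₀·exp(−V(z)/k_B ΔT), ΔT = (γ_b−1)T, is
added and logged (time, centre, σ, deposited height, bias factor).
Deposits add mirror images at the reflective walls so the bias stays
consistent with the reflected walker density — without images the bias
near a wall is systematically under-filled for ~3σ, which shows up as
multi-kJ/mol artifacts at nearby minima.

## Free-energy estimators

**WHAM** iterates the standard two-equation update on 0.01 nm bins until
the largest change in any window constant falls below 1e−8 kJ/mol
(max 10⁵ iterations). Bins visited fewer than 10 times are treated as
unsampled (a near-empty bin carries k_BT-scale noise); adjacent windows
whose sampled ranges fail to overlap raise a coverage error naming the
gap. The profile is zeroed at its largest-z retained bin. The multi-pull
protocol (five restraint stiffnesses, one PMF per pull, averaged after
plateau re-zeroing) is provided alongside single-stiffness WHAM because
published tables are ambiguous about pooling; both paths are tested.

**Metadynamics** offers the plain estimator F = −γ_b/(γ_b−1)·V with
optional time-averaging over the last part of the run, and a
histogram-reweighted estimator F = −k_BT ln ρ̄ − V̄ over the
quasi-stationary tail (default: last 70% of the run, histogram smoothed
by a 2-bin Gaussian kernel, well below the 0.05 nm hill width). The
reweighted form cancels bias-fluctuation noise against the matching dips
in sampling and is the default route in the sandbox validation.

**Binding free energies** use the ratio of Boltzmann integrals over
bound ([z_min, 1.5 nm]) and unbound ((1.5, z_max]) regions with
trapezoidal quadrature and the boundary inserted by interpolation;
the result is invariant to additive shifts of w and stable under grid
refinement. No 4πz² volume factor is applied by default — the reference
workflow describes none — but a flag enables it for sensitivity checks.
Depth reports re-zero each profile at the mean of the last 5% of its
grid, take the first interior local minimum as the depth, exclude and
list monotone profiles, and report labels sorted by depth plus the sum.
Profiles are defined only up to a constant, so all cross-profile
comparisons first remove the mean difference.

## The validation sandbox

The reference ground truth is a quartic double well, barrier 10 kJ/mol,
minima at 0.3 and 1.7 nm, reflective walls at 0.15/1.85 nm, T = 298 K.
Umbrella sampling uses 22 windows from 0.3 to 1.7 nm at k = 45
kJ/(mol·nm²), 2×10⁴ steps per window with the first 10% discarded as
equilibration; metadynamics uses bias factor 50, hills of 1.2 kJ/mol and
σ = 0.05 nm every 500 steps over 10⁶ steps. The integration ratio
dt/γ = 6×10⁻⁴ keeps the stiffest sampled curvature (~280 kJ/mol/nm² near
the walls) well inside the weak-accuracy regime while giving each window
hundreds of relaxation times of effective sampling. The minima sit at
the ends of the window ladder so the restraint (45 kJ/(mol·nm²)) is
never overwhelmed by negative curvature at the barrier top — a narrower
well makes barrier-top windows bimodal with slow lobe hopping, which is
a sampling pathology, not an estimator defect. Typical recovery on this
geometry: WHAM RMSE 0.1–0.4 kJ/mol over the window span, metadynamics
error ≤ 0.4 kJ/mol near the minima, cross-method agreement within
0.5 kJ/mol.

## Synthetic mixtures and the study pipeline

The mixture builder inserts rigid templates at random positions subject
to a 0.3 nm minimum separation between inter-molecular heavy atoms.
Hydrogens are exempt: a donated hydrogen necessarily sits ~0.2 nm from
its acceptor, so an all-atom rule would forbid hydrogen bonding
outright. A configurable fraction of molecules (default 0.6) is inserted
as a donor to a randomly chosen placed acceptor — donor oxygen at
0.30–0.34 nm with the O–H vector aimed at it — planting the
orientational correlations of a liquid; purely random packings at
insertable densities carry almost no geometric bonds. The pipeline sizes
cubic cells per composition (~10 waters/nm³ of free volume, a model
sugar blocking ~2.2 nm³), the densest regime the random inserter fills
reliably.

The `preheated` protocol label emulates the aggregated state that
thermal annealing produces: sugar centres are biased toward the box
centre (Gaussian, σ = 0.2 L) and sugars attach to each other more often
(fraction 0.9). OH rotational dynamics per concentration is emulated by
rotational diffusion with D_r = 0.005 + 0.095·(wt%/100) rad²/ps, slowed
by a factor 0.7 under preheating below 70 wt% water. These produce
difference tables with the qualitative shape the real study reports
(more sugar–sugar bonds and slower OH rotation under preheating, more
sugar–water bonds without); they are qualitative emulations, not fits.

Pipeline runs are deterministic: one root seed is split per composition
and stage, reports carry a provenance block (config hash, seed, package
version) and serialise losslessly to JSON; a failing stage is recorded
and the remaining stages continue.

## What passing tests do and do not show

The synthetic systems validate the estimators and the plumbing exactly
— planted counts, analytic limits, parameter recovery — but static
packings are not thermal ensembles, the model sugars are not chemically
accurate, and desk-scale runs cannot reproduce published MD observables
(hydrogen-bond curves from 40–200 ns trajectories, correlation times of
5 000–18 500 ps, or real sugar–sugar PMFs). Those require force-field
trajectories; this package provides the ability to compute all of the
downstream quantities from such data via its text-file interfaces, and
demonstrates that path end to end on the sandbox.

## Known limitations

* Orthorhombic cells only; no XTC/TRR binary trajectories; no velocities.
* The composition row printed as "2 / 3700 / 99.95" is inconsistent with
  the mass-fraction identity (it recomputes to ≈98.98 wt%) and is
  treated as a typo: reproduced by formula, excluded from exact checks,
  and never tuned toward.
* Whether published per-oxygen curves include water oxygens in the
  denominator is inferred; both denominators are computable.
* The 1–10 contact scores use this package's explicit mapping, not the
  published visually-assigned scores.
* Single-exponential P1 fits only; stretched exponentials and P2
  correlations are out of scope.
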