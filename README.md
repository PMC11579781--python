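# sugarglass

Analysis toolkit for molecular-dynamics studies of disaccharide–water
mixtures (sucrose and trehalose across 0–100 wt% water): hydrogen-bond
statistics with the normalisations such studies report, structural
profiles (radial distribution functions, dihedral distributions, radii of
gyration), OH-group rotational correlation times, and free-energy
post-processing — WHAM over umbrella-sampling windows, well-tempered
metadynamics reconstruction, and bound/unbound binding free energies.

Because force-field trajectories of real sugars need cluster-scale
simulation, every analysis here is exercised end to end on **synthetic
systems with known ground truth**: planted hydrogen-bond configurations,
rotational diffusion with a prescribed coefficient, and overdamped
Langevin walkers on analytic potentials under umbrella restraints or
well-tempered hill deposition. The same code paths accept real data
through plain-text formats (GRO, an XYZ-with-box trajectory dialect,
PLUMED-style HILLS/COLVAR files).

## The quantities at the core

* **Hydrogen bond (geometric):** a donor–hydrogen–acceptor triple with
  O(D)···O(A) ≤ 0.35 nm and ∠(H–D–A) ≤ 30° under the minimum-image
  convention; counts are split into sugar–sugar, sugar–water and
  water–water, normalised per total oxygen count or per labelled
  O/OH-group (with symmetry-equivalent trehalose groups averaged).
* **RDF:** g(r) = ⟨n(r)⟩ / (4πr²Δr ρ), with a reproducible log-scale
  mapping of first-peak heights onto 1–10 contact scores.
* **Rotational correlation time:** τ from a single-exponential fit to the
  first-rank autocorrelation C(t) = ⟨u(t₀)·u(t₀+t)⟩ of O→H unit vectors;
  for isotropic rotational diffusion C(t) = exp(−2 D_r t), so τ = 1/(2 D_r).
* **WHAM:** self-consistent unbiasing of umbrella-window histograms with
  bias w_i(z) = k_i/2 (z − z_i)²,
  P(z) = Σᵢ nᵢ(z) / Σᵢ Nᵢ exp[(fᵢ − wᵢ(z))/k_BT].
* **Well-tempered metadynamics:** F(z) = −γ/(γ−1) V(z) from the deposited
  Gaussians (γ = bias factor), plus a histogram-reweighted estimator
  F = −k_BT ln ρ̄ − V̄ over the quasi-stationary tail of the run.
* **Binding free energy:**
  ΔG = −k_BT ln[ ∫_B e^(−w/k_BT) dz ÷ ∫_U e^(−w/k_BT) dz ],
  bound region B up to 1.5 nm, unbound U beyond, invariant to the
  arbitrary constant in w(z).

Units are GROMACS conventions throughout: nm, ps, kJ/mol, K, degrees,
k_B = 0.0083144626 kJ/(mol·K).

## Worked example

```python
>>> from sugarglass.synthetic import CompositionSpec
>>> round(CompositionSpec(9, 3206).water_mass_pct, 2)   # 9 sugars, 3206 waters
94.94

>>> from sugarglass import sandbox
>>> from sugarglass.free_energy import binding_free_energy
>>> pmf = sandbox.metad_pmf(seed=11)        # well-tempered run on the
...                                         # reference double well
>>> res = binding_free_energy(pmf, boundary=1.5)
>>> round(res.dg, 2), res.bound_region, res.unbound_region
(-0.92, (0.3, 1.5), (1.5, 1.7))
```

The first number is the water mass percent of a 9-disaccharide /
3206-water box (the composition grid rounds it to 95 wt%). The second
block reconstructs the free-energy profile of the sandbox double well
from 10⁶ biased Langevin steps (bias factor 50, hills of 1.2 kJ/mol and
0.05 nm every 500 steps) and integrates it into a binding free energy of
−0.92 kJ/mol for the bound region up to 1.5 nm; the reconstruction
deviates from the analytic potential by at most 0.27 kJ/mol on this run.

A command-line entry point mirrors the library:

```sh
sugarglass run --config study.yaml --out report.json   # concentration series
sugarglass hbond --traj mix.xyz --topology topo.yaml --criterion dist=0.35,angle=30
sugarglass metad-fes --hills HILLS --out fes.xvg
sugarglass bindfe --pmf fes.xvg --boundary 1.5
```

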