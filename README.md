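# pmfkit

Umbrella-sampling free-energy analysis for distance reaction coordinates:
WHAM unbiasing, the radial-coordinate entropic correction, Bayesian-bootstrap
error bars, binding-free-energy extraction, and per-window ligand occupancy
statistics — with a synthetic-data generator that samples biased windows from
analytically known surfaces so every stage can be validated against ground
truth.

## The problem

Sickle hemoglobin (HbS) polymerizes through a lateral fiber contact in which
Val-β6 of one tetramer lodges in a hydrophobic pocket (the Ala70 / Asp73 /
Thr84 / Phe85 / Leu88 region) of a neighboring β-globin.  A candidate
aggregation inhibitor — a cyclic peptide or a small molecule parked in that
pocket — should make dimerization thermodynamically unfavorable.  The
quantitative object is the potential of mean force (PMF) W(ξ) along the
pocket–Val-β6 center-of-mass distance ξ, computed from umbrella-sampling
windows, and the occupancy statistics of the ligand in the pocket along
those windows.  `pmfkit` implements the analysis side of that workflow; it
does not run molecular dynamics.

## The method

Umbrella sampling restrains ξ near a ladder of centers ξᵢ with harmonic
biases wᵢ(ξ) = K/2 (ξ − ξᵢ)².  WHAM combines the biased histograms cᵢ(b)
into one unbiased distribution by iterating to self-consistency

    P(ξ_b) = Σᵢ cᵢ(b) / Σᵢ nᵢ exp(β[Fᵢ − wᵢ(ξ_b)])
    Fᵢ     = −k_B T ln Σ_b P(ξ_b) exp(−β wᵢ(ξ_b))

The PMF is W(ξ) = −k_B T ln P(ξ) + 2 k_B T ln ξ + C for a radial distance
coordinate — the 2 k_B T ln ξ term removes the ξ² growth of the sampling
volume, so that a non-interacting pair gives a flat profile — with C chosen
to zero W over the large-separation plateau.  Statistical errors come from
a Bayesian bootstrap: Dirichlet(1,…,1) weights over the data units, a WHAM
re-solve per replicate, and per-bin standard deviations across replicates.
The binding (dimerization) free energy is the depth of the global minimum
of the plateau-zeroed profile; no standard-state volume correction is
applied.

Defaults mirror the HbS dimer setup: 80 windows, 0.05 nm spacing,
K = 1000 kJ mol⁻¹ nm⁻², T = 310 K, 200 bootstrap replicates.

## Worked example

```python
import pmfkit as pk

# analytically known surface: -32 kJ/mol contact well at 0.5 nm, a shallow
# solvent-separated well at 1.2 nm, flat beyond 2.5 nm (radial convention)
surface = pk.make_dimer_surface()
exp = pk.generate_experiment(surface, pk.GeneratorConfig(seed=0))

opts = pk.AnalysisOptions(apply_correction=True, plateau_region=(3.0, 4.0))
profile, boot = pk.bayesian_bootstrap_pmf(list(exp.windows), opts,
                                          n_boot=200, seed=1)
print(f"dG_dim = {pk.binding_free_energy(profile):.2f} "
      f"+- {boot.dg_std:.2f} kJ/mol")
for xi, depth in pk.find_minima(profile):
    print(f"minimum at {xi:.3f} nm, depth {depth:.2f} kJ/mol")
```

Output:

```
dG_dim = -32.03 +- 0.23 kJ/mol
minimum at 0.499 nm, depth -31.99 kJ/mol
minimum at 1.207 nm, depth -4.08 kJ/mol
```

The recovered dimerization free energy matches the constructed −32 kJ/mol
well within its bootstrap error, and both well positions land within one
0.01 nm bin of the surface's true minima.

The same pipeline runs from the shell:

```sh
pmfkit run --seed 0 --out results/demo       # simulate -> wham -> bootstrap -> report -> occupancy
pmfkit wham --windows-dir results/demo/windows --metadata results/demo/metadata.tsv --out pmf.tsv
pmfkit report pmf.tsv --out features.json
```

`run` leaves a fully reproducible artifact directory: window series
(xvg-dialect text), `pmf.tsv` (ξ, W, error), `pmf_bootstrap.json`,
`features.json`, `occupancy.tsv`, and the resolved `config.yaml` + manifest
with per-stage digests.

## Layout

- `pmfkit.geometry` — atom groups, centers of mass, ξ and minimum distances
- `pmfkit.io` — xvg-dialect window series, metadata TSV, PMF TSV
- `pmfkit.synthetic` — surfaces, Metropolis window sampler, labeled traces
- `pmfkit.wham` — histograms, WHAM solver, entropic correction, PMF
- `pmfkit.uncertainty` — Bayesian bootstrap, split-half convergence
- `pmfkit.binding` — ΔG, well detection, drugged-vs-undrugged comparison
- `pmfkit.occupancy` — window stats, abandonment, smoothing, residence times
- `pmfkit.cli` / `pmfkit.config` — subcommands, YAML config, provenance

See `docs/methods.md` for the model details, parameter choices, and
limitations.
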