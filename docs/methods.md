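# Methods

## Model and estimators

### Reaction coordinate and units

The reaction coordinate ξ is the Euclidean distance between the centers of
mass of two atom groups — in the HbS dimer application, the β₁-globin
hydrophobic pocket of the acceptor tetramer and Val-β6 of the donor.  Which
atoms enter each group (all atoms, heavy atoms, side chains) is left to the
caller: the geometry operations take explicit `AtomGroup`s, and the PDB
reader only resolves a selection string the caller supplies.  Units are
fixed throughout — nm, ps, kJ/mol, K, atomic mass units — with
k_B = 0.0083144621 kJ mol⁻¹ K⁻¹ and T defaulting to 310 K.  No
periodic-boundary imaging is performed; coordinates are assumed whole.

### WHAM

Each umbrella window i restrains ξ with wᵢ(ξ) = K/2 (ξ − ξᵢ)².  Windows are
histogrammed on one shared uniform grid whose edges sit on integer
multiples of the bin width, so a sample's bin never depends on which other
windows are present; samples on an interior edge go to the upper bin
(numpy's half-open convention).  The solver iterates the standard coupled
equations

    P(ξ_b) ∝ Σᵢ cᵢ(b) / Σᵢ nᵢ exp(β[Fᵢ − wᵢ(ξ_b)])
    Fᵢ     = −k_B T ln Σ_b P(ξ_b) exp(−β wᵢ(ξ_b)),    gauge F₀ = 0

until the largest per-window change |ΔFᵢ| falls below `tol`
(default 10⁻⁵ kJ/mol, cap 10⁵ iterations, optional over-relaxation).
Non-convergence returns a flagged result with the residual rather than
raising.  The per-bin denominator is normalized by its minimum before use;
besides numerical hygiene this makes the single-unbiased-window limit
reduce *exactly* (bitwise) to the normalized raw histogram.  Bias
Boltzmann factors that underflow to zero are harmless — they mean a bin is
unreachable by that window — but a window whose bias reaches no occupied
bin at all, or a histogram whose occupied support splits into blocks no
window bridges, is an error: WHAM cannot glue statistically disconnected
regions together.

Empty bins are masked (NaN in the profile), never imputed.  Counts are
used as recorded; no autocorrelation-based rescaling of nᵢ is applied, so
repeated runs reproduce counts exactly.

### Entropic (Jacobian) correction and zeroing

For a radial distance coordinate the sampling volume grows as ξ², so a
non-interacting pair has P(ξ) ∝ ξ².  The profile is therefore

    W(ξ) = −k_B T ln P(ξ) + 2 k_B T ln ξ + C.

The sign and coefficient of the correction are pinned operationally by the
flat-free-particle contract — applying the correction to the profile of a
free radial sampler must flatten it — which is unambiguous where
typographic sign conventions are not.  C is fixed by zeroing the mean of W
over a declared large-separation plateau region; every bin inside the
region must be occupied.  With that convention the binding (dimerization)
free energy is simply the minimum of W over occupied bins.  No standard
state (1 M) volume-entropy correction is applied; the reported ΔG is
relative to the separated pair at the plateau, and output metadata records
this.

### Bayesian bootstrap

Errors come from Dirichlet(1,…,1)-weighted replicates: weights are drawn
over data units, WHAM is re-solved (warm-started from the base solution's
Fᵢ — the fixed point is unchanged, the start point is not), the profile is
re-zeroed at the same plateau (independent re-shift by default; a
common-shift variant exists behind a flag), and per-bin standard deviations
are taken across replicates.  Unconverged replicates are dropped with a
warning; more than 10% dropped is a hard error.  The default unit is the
whole window histogram, which respects within-window autocorrelation.  Its
known blind spot: it cannot see shot noise inside a single window, so
errors in sparsely occupied tail bins (a few counts) are underestimated.
The per-point variant (`unit="point"`) captures shot noise and is what the
split-half diagnostic uses for its per-bin comparison.  The spread of the
binding free energy across replicates is reported alongside per-bin errors.

### Split-half convergence

Each window's post-burn-in series is split (default in half); both halves
are pushed through the full WHAM/PMF chain with the same plateau
convention, and the maximum |ΔW| over bins occupied in both is reported.
For stationary sampling the halves agree within their combined bootstrap
errors; a planted mid-series change of the generating surface produces
per-bin discrepancies many times those errors, which is the diagnostic's
detection case.

### Binding features and comparisons

Wells are local minima of W with prominence ≥ 1 kJ/mol (features shallower
than ~half k_B T at 310 K would be noise); the smallest-ξ well is labeled
the contact pair, the next the solvent-separated pair.  Positions and
depths are refined by a local parabolic fit over ±10 bins, which suppresses
the bin-level jitter of a raw argmin (at the cost of a slightly biased
depth for strongly anharmonic wells; the global ΔG always comes from the
unrefined bin minimum).  Drugged-vs-reference comparisons interpolate the
treated profile onto the reference grid over the overlapping occupied
range and report ΔΔG; "thermodynamically unfavorable" is operationalized
as ΔG_treated > −k_B T (no thermally significant well), with a ±0.1 k_B T
band flagged "marginal".  The cutoff is a package decision — the
qualitative notion needs a number — and is surfaced in configuration.

### Occupancy statistics

Pocket abandonment is classified per window from the ligand–pocket
minimum-distance trace by three strict thresholds, any of which suffices:
mean > 0.6 nm, standard deviation > 0.3 nm (the "large error bar"
signature), or mean over the final 20% of the trace > 0.6 nm (late
abandonment that a whole-trace mean dilutes).  Mean-only rules miss late
departures; std-only rules miss early permanent ones.  All three
thresholds are configuration.  The abandonment probability is the fraction
of windows classified abandoned — it is criterion-dependent by nature, so
recovery is only ever asserted against planted synthetic labels, not
against real-data fractions.  Moving averages are centered, time-based
(default 1 ns width) and edge-truncated — padding would invent data.
Residence segments are maximal runs with distance < 0.6 nm lasting at
least a minimum duration, reported as (start, end, duration).

## Synthetic data: what it emulates and what it does not

The generator exists because the downstream estimators need inputs with
known truth.  `make_dimer_surface` builds W(ξ) from three Gaussians
(contact well, inter-well barrier, solvent-separated well) whose amplitudes
solve a 3×3 linear system so the wells hit their requested depths exactly,
cross-terms included, with a cosine taper forcing W ≡ 0 beyond the plateau
onset.  Defaults mirror the dimer application: −32 kJ/mol at 0.5 nm,
−4 kJ/mol at 1.2 nm, plateau beyond 2.5 nm, support [0.3, 4.3] nm.  The
`barrier` parameter pins W at the inter-well midpoint; the surface's actual
local maximum sits slightly off the midpoint because the well tails
overlap.

Window series are Metropolis chains targeting exp(−β[W + wᵢ]) — times ξ²
when the surface is radial, so the generation-side volume factor appears
exactly when the analysis-side correction will be applied.  The proposal
width is tuned from the target's quadrature-estimated standard deviation
(≈2.4 σ, ~40% acceptance); `correlation_time` sets the autocorrelation
scale of the recorded series by thinning (below the raw-chain scale of ~6
steps) or step-shrinking (above it), emulating MD frame-to-frame
correlation.  Chains start at the target mode and discard a 10% burn-in on
top of the requested length.  Defaults follow the emulated setup: 80
windows, 0.05 nm spacing, K = 1000 kJ mol⁻¹ nm⁻², 310 K, 5000 recorded
samples per window — deliberately desk-scale rather than the 30–60 ns of
production MD.  Per-window seeds spawn deterministically from one root
seed; identical seeds give bit-identical outputs.

Distance traces are exact-discretization Ornstein–Uhlenbeck processes
about a bound level (0.3 nm, σ = 0.05 nm, τ = 50 ps), with labeled windows
switching their mean to the unbound level (1.5 nm) mid-trace and staying
there.  The 24 σ level separation makes label recovery exact by
construction under the default criteria — which is the point: these are
label-recovery tests, not simulations of marginal cases.

What passing these tests shows: the estimators are correct — unbiasing,
correction, zeroing, error bars and classifiers recover planted truth at
the stated tolerances.  What they do not show: anything about force
fields, sampling adequacy of real MD, slow orthogonal degrees of freedom,
or the actual HbS free-energy surface.  The synthetic sampler has no
hidden slow modes, its windows are perfectly equilibrated by construction,
and its noise is exactly the model the bootstrap assumes.

## Numerical choices

- Bin width 0.01 nm (five bins per window spacing); data-independent grid
  anchoring; top edge extended one bin when the maximum lands on it.
- WHAM tol 10⁻⁵ kJ/mol on max |ΔFᵢ|, max 10⁵ iterations; linear-space
  iteration with min-normalized denominators (see above) — on the default
  80-window problem convergence takes a few thousand iterations and well
  under a second.
- Burn-in 10% per window at analysis time (window files may carry residual
  equilibration), in addition to the generator's own 10%.
- Ties/degenerate inputs: samples on bin edges go up; exactly-at-cutoff
  occupancy comparisons are strict (not abandoned); a single bootstrap
  replicate reports zero error with a warning.
- Problem sizes in the test suite and the acceptance script (e.g.
  30 windows × 5000 samples for the double-well recovery; 10⁵ samples for
  the single-window checks; 20 regenerated experiments for bootstrap
  calibration) were chosen as the smallest sizes at which the targeted
  effects dominate their own statistical noise by a comfortable margin.

## Known limitations

- ΔG as a min-over-bins is slightly biased downward (~0.1–0.5 kJ/mol at
  default sizes) because the minimum of a noisy profile is an extreme-value
  statistic; the bias is within ~2 bootstrap standard deviations.
- Window-level bootstrap errors are underestimates in bins carried by a
  handful of samples (see above); use `unit="point"` when tail bins matter.
- One-dimensional only; no MBAR/TRAM, no umbrella integration, no
  standard-state conversion, no kinetics from the PMF.
- The sampler's `correlation_time` is an approximate scale, not an exact
  integrated autocorrelation time.
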