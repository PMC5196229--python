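# Methods

`aquadiff` models water diffusion in a centrifuged pellet of cells whose
membrane water permeability is altered by expressing a water channel
(aquaporin), and implements the analysis chain that turns diffusion-weighted
MRI measurements of such pellets into estimates of channel expression:
Monte Carlo simulation of restricted, exchanging water → apparent diffusion
coefficient (ADC) → membrane permeability → channels per cell →
concentration, together with the relaxometry fits and group statistics used
around such experiments.

## Pellet geometry

The pellet is a periodic face-centered-cubic (FCC) lattice of spherical
cells: a 3×3×3 supercell with 4 sites per cubic cell, i.e. 108 cells.
Radii are drawn from N(6.8, 1.2) μm (draws ≤ 0.5 μm redrawn).  The FCC
lattice constant is not a measured quantity; the default, a = 2√2 × 6.8 ≈
19.23 μm, makes mean-radius spheres touch, the densest arrangement
consistent with disjoint spheres of the stated mean radius, and is
configurable.  Because spheres must not overlap (walker compartment
membership must be unambiguous), any overlapping pair is shrunk
symmetrically — each sphere loses half the excess — until the packing is
valid.  With the stated radius spread this caps the intracellular volume
fraction at ≈ 0.50–0.53 (equal radii would give the FCC maximum 0.74);
this is a genuine geometric consequence of the radius distribution, not a
tunable choice, and it matters for the absolute ADC scale (see
Limitations).  Labels (`HIGH_PERM`/`LOW_PERM`) mark aquaporin-expressing
versus control cells; a requested labelled fraction is realised exactly,
rounding half away from zero.

## Random-walk engine

Walkers start uniformly over the periodic box (occupancy ∝ volume
fraction) and take per-axis Gaussian steps of scale σ = √(2Dτ), with
τ = 50 μs and free diffusivities D_in = 554.7 and D_ex = 1664.2 μm²/s
(water at the 12.9 °C bore temperature; cytoplasmic value reduced by
macromolecular crowding).  Coordinates are unwrapped; the periodic
geometry emulates an effectively infinite pellet.

When a step's path intersects a sphere surface the walker is transmitted
with probability

    p = P · √(π τ / D_in)

(P the membrane permeability in μm/ms) and otherwise specularly reflected.
This is the standard consistency condition equating the transmitted
fraction of the one-sided Gaussian-step wall flux, c·σ/(√(2π)·τ), to the
interface flux P·c.  The reference diffusivity is D_in for both crossing
directions (a `donor_side_reference` switch uses the departure-side D
instead; the symmetric-p choice deliberately satisfies detailed balance
only when D_in = D_ex, and the equilibrium-occupancy test is run under
that condition).  On transmission the residual step length is rescaled by
√(D_new/D_old); multiple surface events per step are iterated up to
`max_crossings` (10), beyond which the step is aborted at the last event
and counted as a diagnostic.  After every event the walker is nudged
1e-7 μm off the surface along the normal to keep membership well defined
at tangent contacts between touching spheres.

Performance: an event-free step needs only a cached clearance test
(distance to the nearest membrane, decremented by step lengths and
recomputed when exhausted); candidate spheres come from a precomputed
per-voxel neighbour grid.  The kernel is numba-compiled; ~10⁴ walkers ×
~8×10³ steps run in ~25 s on one core.

## ADC readout

The diffusion weighting follows the stimulated-echo convention: pulse
duration δ = 7 ms, interval Δ, effective diffusion time Δ_eff = Δ − δ/3,
b = (γδg)²(Δ − δ/3).  From simulated displacements x accumulated over
Δ_eff, the primary estimator is the narrow-pulse attenuation

    E = ⟨cos(γδg·x)⟩,  ADC = −ln(E)/b

evaluated at b = 800 s/mm² (the top of the experimental 0–800 range;
b·ADC ≲ 0.7 keeps E well resolved), averaged over the three gradient
axes, with the mean-square-displacement estimator ⟨x²⟩/(2Δ_eff) reported
as a cross-check (the two agree on Gaussian ensembles; exchange-induced
non-Gaussianity makes the attenuation estimator the physically faithful
one).  From measured decay curves, ADC is the negative slope of ln S
versus b by ordinary least squares, matching the experimental analysis; a
weighted option is deliberately omitted until needed.

## Campaigns and inversion

* **Permeability sweep** — for each uniform P on a grid, a fresh lattice
  and ensemble are simulated and ADC(Δ_eff) recorded, with Monte Carlo
  standard errors.  Default budgets: 10⁴ walkers per grid point (full
  study scale) with a ~9-point grid; desk-scale analyses in `analysis/`
  default to 4×10³ walkers.
* **Fraction sweep** — permeabilities fixed at 0.14 (labelled) and 0.039
  μm/ms (control); the labelled fraction is swept and ADC averaged over
  random label arrangements on a fixed geometry (default 12–100
  arrangements; the reference study used 3×10⁴, which the configuration
  accepts but a desk run does not need — the arrangement-to-arrangement
  standard error is reported so the budget is auditable).
* **Inversion** — ADC(P) is made non-decreasing by a pool-adjacent-
  violators fit (Monte Carlo noise can produce local inversions) and
  inverted by monotone piecewise-linear interpolation.
  `invert_adc_to_permeability` refuses extrapolation; the separate
  `invert_adc_with_trend_extrapolation` extrapolates the least-squares
  linear trend of the adjacent half of the curve when the measured ADC
  falls outside the simulated range, flagging that it did so.  The
  fallback exists because measured ADCs can exceed the simulated curve's
  ceiling (see Limitations); reporting a flagged extrapolation is more
  informative than refusing to answer.
* **Expression arithmetic** — flow = P × A with A = 380 μm² (CHO surface
  area); channels = flow / 6×10⁻⁵ μm³/ms (single-channel conductance);
  concentration = channels/(m·N_A·V).  The stated surface area is
  inconsistent with the 6.8 μm mean-radius sphere (581 μm²), so both
  volume conventions are exposed — V = 697 μm³ (sphere matching the 380
  μm² area, the default) and V = 1317 μm³ (r = 6.8 μm) — and the
  multimer factor m defaults to 1 (conductance per monomer); all
  assumptions are recorded in the result object rather than guessed away.

## Relaxometry and statistics

T1 is fitted by nonlinear least squares to saturation recovery
S = S0(1 − e^(−TR/T1)) on the variable-TR protocol grid (146.19 … 7500 ms);
an inversion-recovery variant is available by flag.  T2 is fitted to
S = S0·e^(−t/T2) on the first 19 of 63 echoes (TE = 11 ms), log-linearly by
default (nonlinear optional) — the 19-echo window excludes the late train
where noise floors and slow components distort a mono-exponential fit.

`compare_groups` reports the percent change relative to the control group,
a two-sided homoscedastic t-test (paired on request) as the primary
p-value, an F-test of variance homogeneity, Kolmogorov–Smirnov normality
screening per group (α = 0.01), and the Welch t-test as a sensitivity
variant.  Screening is reported, never used to switch the primary test
automatically.  Tumour volume is the calliper formula 0.52·s²·l.

## Synthetic data

The generators are exact inverses of the fitting operations at zero noise
(a property the tests enforce over randomized parameters).  Noise is
Gaussian by default — the pellet regime is high-SNR — with Rician
(magnitude) noise available; at low SNR Rician noise biases fitted T2
upward, and the tests assert that direction.  Replicate group studies draw
ADC = control·(1 + pct/100)·(1 + N(0, cv)) with control ADC 377.57 μm²/s
and cv = 20.86/377.57 ≈ 5.5%, the control group's observed relative
spread; default effects (54%, 187%) and n = 4 replicates mirror the
titration experiment.  What the generators do **not** emulate: Rician bias
in the ADC decay itself, inter-session drift, partial-volume and
registration effects — so passing statistical tests here validates the
analysis chain, not the acquisition.

## Numerical choices

Internal units are μm/ms (D in μm²/ms, P in μm/ms, b in ms/μm²); public
interfaces accept μm²/s, s/mm² and μs and convert at the boundary
(1 s/mm² = 10⁻³ ms/μm²).  Transmission probabilities above 1 raise a
configuration error prescribing a smaller τ, never a silent clamp.
Intersection roots are excluded below a parametric offset of 1e-10;
geometry uses minimum-image arithmetic throughout.  Seeds: every stochastic
entry point takes one; campaign seeds are spawned via `SeedSequence` and
recorded in outputs for exact replay.

## Limitations

* The absolute ADC scale of the simulation does not reproduce the measured
  control pellet.  Two model-independent bounds pin the simulated curve at
  Δ_eff = 398 ms to ≈ 470–940 μm²/s: at P = 0 the ~47% extracellular
  fraction alone yields ADC ≈ 470–535 (above the measured control value of
  377.57), and with transparent membranes the composite limit is ≈ 940
  (below 1083.6 = 377.57 × 2.87, the ADC implied by the largest measured
  increase).  Within this model family — disjoint FCC spheres with the
  stated radius distribution and diffusivities — no admissible lattice
  constant, initialization, estimator or transmission-reference choice
  moves either bound enough (all were tried).  Consequently inverted
  permeabilities for the measured ADC changes disagree with previously
  reported values: the low-dose inversion lands near 0.02–0.04 μm/ms and
  the high-dose point lies beyond the curve ceiling and is reported via
  the flagged trend extrapolation.  Relative predictions (monotonicity in
  P and labelled fraction, growth of contrast with diffusion time,
  measurable effect of 10% labelling) are unaffected and are what the
  property tests assert.
* A real pellet's intracellular fraction (likely > 0.8) cannot be reached
  by disjoint spheres on an FCC lattice; deformable/polydisperse packings
  are out of scope.
* No surface relaxation, organelles, flow, or finite-pulse-width gradient
  integration; the readout is the narrow-pulse limit.
* The membrane rule with a fixed D_in reference breaks detailed balance
  when D_in ≠ D_ex (equilibrium intracellular occupancy is enhanced by
  √(D_ex/D_in)); this follows the literal formulation and is switchable,
  and the consequence is quantified by the occupancy test run at
  D_in = D_ex.
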