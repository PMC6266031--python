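# Methods

`ionpb` is a CPU pencil-beam forward-calculation engine for scanned proton
and carbon-ion beams.  It computes physical dose, dose-averaged LET
(LET_d) and RBE-weighted dose (D_RBE) on a voxel phantom from a
spot-scanning plan and a per-energy beam database, and evaluates the
results with DVH metrics, a global 3-D gamma-index and a water-phantom
chamber-array QA statistic.  This note records the models, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Pencil-beam model

Each scanned spot is a pencil beam entering the phantom with an in-air
Gaussian fluence (FWHM interpolated from a per-energy machine table,
sigma = FWHM / (2 sqrt(2 ln 2))).  For a voxel at perpendicular distance
`r` from the spot axis and water-equivalent depth `z` along it, the dose is

    d = N * IDD(z) * L(r; sigma_i(z), w_i(z))

with `N` the spot particle number, `IDD` the integrated depth dose
(Gy mm^2 per primary) and `L` the normalised triple-Gaussian lateral
kernel

    L(r) = sum_i  w_i / (2 pi sigma_i^2) exp(-r^2 / (2 sigma_i^2)),
    w1 + w2 + w3 = 1,  sigma1 <= sigma2 <= sigma3.

The tabulated sigma_i(z) describe the in-water spread only; the in-air
sigma and any range-shifter widening are added in quadrature to each of
the three components alike (the per-component composition is this
package's documented choice; the alternative of composing onto a single
effective sigma is not used).

Radiological depth comes from exact Siddon raytracing at CT resolution
(half-open voxel convention, segment midpoints decide membership, so a ray
running along a voxel boundary books its chord to exactly one column);
dose is deposited on a coarser dose grid — the clinical two-grid scheme.
Default grids: 2 mm dose / CT-native raytracing; a 3 mm dose grid is the
conventional choice for pelvic-scale fields and is a pure configuration
value.  The perpendicular distance `r` is geometric, not water-equivalent.

**Lateral cutoff.**  The kernel is truncated at 3.5 x sigma3 (largest
composed component, per depth).  The truncated mass is ~2e-4 of the
kernel, consistent with the <=1% budget of the energy-conservation test.

**Summation order** is fixed (beam, spot, sub-beam, voxel-linear), so maps
are bit-reproducible and independent of any caller-side iteration order.

## Sub-beam splitting

In heterogeneous geometry a spot can be split into an m x m lattice of
sub-beams (m = ceil(sqrt(n_splits)); defaults 349 and 97 follow the
"~350 / ~100" convention for fine and coarse clinical settings) covering
[-3.5, +3.5] entrance sigma per axis.  The lattice discretises the
*entrance* fluence: each sub-beam carries the parent Gaussian mass of its
cell (renormalised to a total of exactly 1), sits at the cell's fluence
centroid, and adds the residual in-cell spread of the truncated Gaussian
to its own kernel in quadrature.  Centroid placement cancels the
first-order discretisation error and the in-cell variance term restores
the second moment, so in homogeneous water splitting reproduces the
unsplit calculation to well below 0.5% of the peak — the property that
justifies skipping splitting in water phantoms entirely.  Each sub-beam is
raytraced on its own axis, which is the point of the construction in
heterogeneous anatomy.

## Range shifter

A range shifter of water-equivalent thickness `wet` at `air_gap` mm from
the entry point (i) adds `wet` to every radiological depth and (ii) widens
the beam by sigma_rs = theta(E) * sqrt(wet / 30 mm) * (air_gap + depth),
where theta(E) is a Highland angular spread tabulated per energy for the
nominal 30 mm shifter (14.1 MeV z / pv * sqrt(x/X0) * (1 + 0.038 ln x/X0),
X0,water = 360.8 mm).  Adding a shifter therefore never narrows the beam
and never extends the range.

## Biological models

* **Protons:** D_RBE = 1.1 x dose, voxel-wise.  The proton chain never
  touches the alpha/beta/zstar accumulators; variable-RBE models are an
  extension point, not a default.
* **Carbon, LEM route:** the engine accumulates dose-weighted alpha and
  dose-weighted sqrt(beta) per voxel (Zaider–Rossi mixed-field rule);
  alpha_mix = sum(d alpha)/sum(d), beta_mix = (sum(d sqrt(beta))/sum(d))^2.
* **Carbon, MKM route:** dose-weighted saturation-corrected specific
  energy zstar_mix = sum(d zstar)/sum(d); alpha_mix = alpha0 + beta0 *
  zstar_mix with constant beta_mix = beta0.
* **Photon-equivalent dose:** E = alpha_mix D + beta_mix D^2 and
  D_RBE = (sqrt(alpha_x^2 + 4 beta_x E) - alpha_x) / (2 beta_x)
  (linear branch when beta_x = 0).

Biology tables depend on depth only; lateral variation of the mixed field
is deliberately not modelled — a stated approximation of this engine
class.  Default tissue parameters (alpha_x = 0.1 Gy^-1, beta_x = 0.05
Gy^-2; alpha0 = 0.13 Gy^-1, beta0 = 0.05 Gy^-2) are test/config defaults,
not clinical values; every acceptance property is invariant to them.  The
LEM-to-MKM clinical rescaling is represented only by the scalar applied in
`lem_mkm_ratio`, whose summary also reports the engine-derived factor
D_RBE,LEM,50 / D_RBE,MKM,50 over the ROI.

## Synthetic beam database

Clinically the depth tables come from Monte Carlo transport; here they are
generated analytically so the engine is testable end to end.  The
generator emulates the qualitative shapes of a clinical database — a
pristine Bragg peak per energy, sigmas growing with depth, biology rising
into the peak — with fixed, documented constants:

* **Range–energy:** R = a E^p with a = 0.022 mm/MeV^1.77, p = 1.77
  (protons, 60–250 MeV) and a = 0.0136, p = 1.65 (carbon, 115–400 MeV/u).
  The 150 MeV proton peak lands within 1% of the power law.
* **Depth dose:** stopping power S(z) ~ (R - z)^(1/p - 1) with exact
  per-cell integration of the singularity, convolved with Gaussian range
  straggling sigma = 0.012 R^0.935 (divided by 3.5 for carbon).  Units:
  IDD = S[MeV/mm] x 1.602e-7 Gy mm^2 (x12 for carbon, per-ion energy
  loss), so plans with absolute particle numbers yield Gy directly.
* **Carbon fragmentation tail:** a ramp rising to ~12% of the peak at
  z = R, decaying distally with a 40 mm constant — between 5% and 30% of
  the peak just past the peak, below 5% by the end of the table.
* **LET_d:** conv(S^2)/conv(S) under the same straggling kernel (the
  dose-averaged stopping power), tapered exponentially (3 sigma constant)
  once the primary dose falls below 1% of its peak; this produces the
  monotone rise into the peak, a single distal maximum at/just beyond the
  peak, and a falling tail.  For protons this is by construction the
  primary p/d/t component; no heavy-fragment LET enters the proton table.
* **Lateral parameters:** sigma1 = 0.8 mm + sigma_R (0.05 + 0.95 t^1.7),
  t = z/R clipped to [0, 1], with sigma_R = 0.294 R_cm^0.896 mm (Hong-type
  growth; /3 for carbon); sigma2 = 1.9 sigma1, sigma3 = 3 sigma1 + 3 mm;
  halo weights w2 = 0.12 + 0.05 t, w3 = 0.02 + 0.10 t, w1 the remainder.
* **Carbon biology:** alpha and zstar rise toward the peak on a 25 mm
  residual-range scale (alpha: 0.15 -> ~1.2 Gy^-1, i.e. an entrance-to-
  peak ratio of at least 2 at every tabulated energy, larger for lower
  energies whose entrance sits closer to the peak), relaxing to fragment-
  field values with a 15 mm constant beyond it; beta varies weakly
  (0.035–0.05 Gy^-2).
* **Machine tables:** FWHM-in-air decreasing with energy (protons
  18 -> 7 mm, carbon 10 -> 4 mm over their ranges); range-shifter theta(E)
  from the Highland formula above.  HU calibration: piecewise-linear nodes
  at air (-1024, 0.001), lung, soft tissue, water (0, 1.000 exactly) and
  bone up to (3000, 2.70).

The seed perturbs only second-order constants (straggling-level jitter on
the halo amplitude, sigma_R and peak alpha at the few-percent level); the
model shapes are fixed.  What the generator does **not** emulate: nuclear
build-up and fluence loss in the entrance channel, spot-shape asymmetry,
beamline divergence, measured-database noise, or any real facility's
absolute values.  Passing tests therefore demonstrate the *engine's*
numerical correctness (interpolation, raytracing, superposition, mixing
rules, metrics) under realistic shapes — not agreement with any measured
beam model.

**Interpolation.**  Depth lookups are linear on the (uniform) table grid;
beyond the table IDD and LET_d are zero while lateral/biological columns
hold their last value.  Untabulated energies are interpolated between the
bracketing entries after rescaling each depth axis by the ratio of peak
depths (peak alignment avoids the double-peak artifact of naive blending).

**Triple-Gaussian fitting** (`fit_triple_gaussian`) uses multi-start
bounded least squares (starts at sigma ratios 1:2:4 around a moment
estimate of the RMS radius, scales 0.5/1/2), amplitudes fitted freely and
normalised afterwards, components sorted by sigma, residuals weighted by
sqrt(r) to mirror the radial area element (the pure `r` weighting would
zero out the innermost sample).  Noiseless profiles round-trip to better
than 1% in every parameter.

## SOBP plan generation

`layout_spots` picks the database energies whose Bragg peaks tile the
target's water-equivalent depth extent (one extra layer proximal and
distal) and lays the same square lateral lattice (default 3 mm pitch, one
in-air-sigma margin) on every layer.  `optimize_sobp` is a damped
dose-ratio fixed point, not an inverse planner: each sweep recomputes
D_RBE — via an exact per-spot influence decomposition, since every
accumulator is linear in the spot weights — at all target voxels and at
each spot's own Bragg-peak point, scales each weight by
(prescription / peak-point D_RBE)^step (step <= 0.7, halved on rejection),
and then renormalises all weights by a scalar so that the target D50
equals the prescription (one pass for the linear fixed-RBE model, a
log-space secant solve for the superlinear LQ models).  A sweep is
accepted only if the worst target deviation max |D_RBE - prescription|
does not increase, so the recorded trace is monotone; iteration stops on
stagnation (<0.1% objective improvement) or `max_iter`, and a run that
ends with D50 outside tolerance raises with the trace attached.  Given
identical inputs the optimiser is bit-deterministic.

## Evaluation

* **DVH / D_x:** exact sample-based cumulative curves; D_x uses Hazen
  plotting positions (sample k of n carries fraction (n - k + 0.5)/n above
  it) with linear interpolation between order statistics — 100 voxels at
  1..100 Gy give D50 = 50.5.  Planning systems differ here; the tests pin
  this convention.  LET_d,x uses the same machinery on the LET volume
  histogram.
* **Gamma-index:** global normalisation to the reference maximum, default
  2%/2 mm with a 10% low-dose threshold; the evaluated map is probed by
  trilinear interpolation on a sphere of radius 3 x DTA at DTA/10 steps,
  visiting offsets in increasing radius with early termination once the
  geometric term alone exceeds every remaining voxel's current gamma.
  Computed on the dose grid.  The global norm makes the index asymmetric
  under swapping the maps; voxels with gamma = 0 remain 0 either way.
* **QA statistic:** trilinear dose at each chamber position; differences
  (measured - calculated) normalised by the computed field maximum;
  verdict passes iff |mean| <= 5% and sample standard deviation (n - 1
  denominator; the protocol text does not specify the denominator) < 5%.

## Problem sizes and defaults

The shipped demonstration (and the acceptance recomputation) uses a
100 x 100 x 200 mm water tank at 2 mm voxels, a 3 cm cubic target with its
proximal face at 12 cm, ~8 energy layers at 4 mm peak spacing and a 4 mm
lateral pitch (~800 spots) — sizes chosen so a full run completes in well
under a minute on one core while leaving the plateau homogeneous at the
percent level.  All of these are `RunConfig` values.

## Known limitations

No Monte Carlo transport and no nuclear-interaction physics beyond the
parametric fragment tail; no lateral mixed-field biology; no spot-shape
asymmetry or beamline divergence beyond the linear air projection; no
DICOM import (grids, masks and plans use the package's JSON/CSV formats);
the SOBP optimiser has no OAR constraints and no robustness handling.
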