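# Methods

This note documents the models, algorithms and design choices behind
`rfdosim`, in the order the pipeline runs.

## Phantoms and tissue properties

A phantom is a 3-D integer tissue-label grid (0 = background/air) with
isotropic voxels (default 2 mm), an origin, a designated long (superior–
inferior) axis, a boolean head mask, and an *alignment plane*: the
body-frame coordinate of the central heart level, which is placed at the
coil centre in the standard position. Physical positions are voxel
centres, `origin + (index + 0.5)·h`. On disk a phantom is a raw
little-endian int16 volume plus a JSON sidecar (the source of truth for
shape and geometry) and a uint8 head-mask plane; NIfTI export is offered
for viewers only.

Tissue tables carry (name, label, σ [S/m], ε′ [–], ρ [kg/m³]) with
invariants: unique labels, exactly one background row (σ = ρ = 0), tissue
rows with σ ≥ 0, ε′ ≥ 1, ρ > 0. Two constant tables ship with the
package: a detailed 18-tissue table of approximate literature values at
64 MHz and a 6-row homogenized-group table; both are annotated per-row
with their provenance in a `source` column.

Tissue mass is voxel count × voxel volume × density. Homogenization
replaces a group of tissues by one material whose complex permittivity is
the mass-weighted mean of its constituents'; because the weighting is
linear, σ and ε′ are each mass-weighted means,

    σ_hom = Σ σᵢ mᵢ / Σ mᵢ ,    ε′_hom = Σ ε′ᵢ mᵢ / Σ mᵢ .

Group **density** is mass-weighted the same way. This is a design choice:
homogenization is defined for the dielectrics, but the forward model also
needs ρ, and mass weighting is the unique choice that preserves group
mass exactly when voxel counts are preserved.

Model comparison reports per-tissue and total weight deviations,
`(individual − reference)/reference × 100`, and Dice overlap
`2|X∩Y|/(|X|+|Y|) × 100` when both phantoms share a grid. Dice of two
empty sets is defined as 0 % (not NaN): an absent organ in both models is
reported as no overlap, and the case is documented rather than silent.

## Quasi-static forward SAR model

Full-wave electromagnetic solvers are the reference tool for coil
dosimetry but are far outside desk scale. `rfdosim` instead uses a
quasi-static induced-field model that keeps exactly the dependencies the
stochastic study needs — tissue conductivity and density, Z-shift through
the axial field profile, tilt through off-axis geometry — and runs in
~0.16 s per pose at 2 mm resolution:

* The coil is abstracted as a circularly polarized B1 field along the
  coil Z-axis with axial profile `w(z)`: 1 for |z − z_c| ≤ L/2, a cos²
  taper of length L_t beyond each end, 0 outside. Defaults L = 0.04 m,
  L_t = 0.18 m give a smooth bell-like profile over the desk-scale body,
  qualitatively like a birdcage's fringing B1. (A long uniform section
  makes the peak-SAR metric *exactly constant* over much of the Z-shift
  range on this body — a degenerate, information-free response — so the
  short-uniform/long-fringe shape is the physically sensible default
  here.)
* By Faraday's law a uniform rotating B1 induces E ∝ ω·B1·d/2 at
  perpendicular distance d from the axis; with the axial profile,
  `E(r) = (ω B1/2)·d(r)·w(z)`. B1 and E are **peak amplitudes**, so
  `SAR = σE²/(2ρ)`; RMS-convention users should halve the SAR.
* Pose transform: the body's long axis is parallel to the coil axis and
  offset below it by `table_offset` (default 0.05 m); the alignment plane
  sits at the coil centre; then the body is rotated by the tilt angle and
  translated by the Z-shift. Voxel *centres* are transformed rigidly;
  labels are never resampled, so tissue masses are exactly pose-invariant.
* Tilt axis: the default is a roll about the body's own long axis, which
  is dosimetrically active because that axis is offset from the coil
  axis. A pitch about the transverse axis through the alignment plane is
  available behind `tilt_axis="pitch"`; the choice between the two is a
  modelling convention, not an asserted fact about any particular
  scanner.

Absolute SAR values from this model are not comparable with full-wave
results; only relative and distributional statements are meaningful,
which is what the pipeline makes.

### SAR metrics

wbSAR and hdSAR are mass-weighted means `Σ SARᵢ mᵢ / Σ mᵢ` over the
tissue voxels and head-mask voxels. pSAR10g grows, around every tissue
voxel, centred cubes of odd voxel side (1, 3, 5, …) until the enclosed
tissue mass reaches the 10 g target; the outermost shell enters with the
linear fraction that makes the enclosed mass exactly 10 g:

    avg = (P_inner + f·(P_outer − P_inner)) / m_target ,
    f   = (m_target − M_inner) / (M_outer − M_inner) .

Background contributes zero mass and power. Voxels whose cube would
leave the grid before reaching the target are invalid and excluded. Ties
in the maximum resolve to the lexicographically smallest voxel index.
The implementation uses 3-D summed-volume tables (integral images) and a
lower bound on the feasible cube size; the test suite checks it against
an exhaustive per-voxel, per-cube brute-force oracle on random phantoms.
This cubical averaging with a fractional shell is a simplification of the
standards-grade algorithm (no face-extension refinements); the same rule
is used consistently everywhere, including the oracle.

Normalization: `raw_B1` (default) reports SAR at the configured B1;
`absorbed_power_1W` rescales so the total absorbed power Σ SARᵢmᵢ is
exactly 1 W. The latter approximates net-incident-power normalization —
without a coil circuit model the absorbed power is the only available
power reference, and all SAR *ratios* are invariant under it.

## Pose distribution and experimental design

Z-shift and tilt are independent truncated Gaussians; the defaults place
the motion limits at ±3 sd (shift sd 10⁄3 cm on ±10 cm, tilt sd 5⁄3° on
±5°). Latin hypercube sampling divides each marginal into N
equal-probability strata, draws one uniform point per stratum through the
truncated-normal inverse CDF, and permutes strata independently across
dimensions; the design is bit-reproducible given its seed.

For the polynomial weight the truncated Gaussians are standardized as
plain Gaussians, ξ = (x − μ)/σ. Truncation at ±3 sd discards ≈0.27 % of
probability mass, so the Hermite family remains very nearly orthonormal
under the true input law; sampling always respects the truncation. This
is a declared approximation.

## Sparse polynomial chaos with LAR and leave-one-out

The candidate basis is all tensor-product Hermite terms of total degree
≤ p (graded-lexicographic order), of size P = C(K+p, p); the univariate
factors are probabilists' Hermite polynomials normalized to unit norm
under the standard normal weight, evaluated by the stable orthonormal
recurrence Ht₊₁ = (x·Htₙ − √n·Htₙ₋₁)/√(n+1).

Fitting is hybrid LAR–OLS:

1. classic equiangular least-angle regression on the centred, unit-norm
   basis columns (intercept handled separately, ties to the lowest column
   index) fixes the order in which terms become active;
2. every model along the path is refit by ordinary least squares on its
   active columns;
3. the model minimizing the corrected leave-one-out error wins.

The leave-one-out error uses the hat-matrix identity: with leverages hᵢ
and OLS residuals rᵢ, the held-out prediction error at point i is
rᵢ/(1 − hᵢ), and ε_LOO is the mean of its square — algebraically equal to
refitting N times with one point removed (the test suite verifies the
identity against the literal refit loop). The finite-sample correction

    T = N/(N − P_active) · (1 + tr((ΦᵀΦ)⁻¹))

multiplies the estimate; the uncorrected estimator stays available for
oracle testing. Convergence is judged by 1 − Q² = ε_LOO/σ²_SAR with the
observation variance σ²_SAR.

Adaptive refinement iterates over a design-size schedule and, per design,
over candidate degrees, accepting the first fit with 1 − Q² ≤ threshold
(default 0.01, a repo choice — one of the defaults a user should revisit
for their own tolerance); failing that, the best fit is returned with a
warning flag, never an exception. Degenerate situations are explicit
errors: designs with rank below the input count, saturated models
(P_active ≥ N), interpolating points (hᵢ → 1), non-finite observations.

## The study

`run_study` anchors both phantoms at the standard position (deterministic
metrics and their deviations), evaluates **one shared** LHS design
through the forward model per phantom (sharing the design removes design
noise from the comparison), fits one surrogate per metric per phantom
(degree-adaptive at fixed N = 100), then pushes M = 10⁵ pose draws
through each surrogate. Reported percentiles are {5, 25, 50, 75, 95}
with linear interpolation between order statistics; percentile deviations
use the reference model in the denominator, the same convention as the
mass table. Identical configs (all seeds are explicit) reproduce the
report byte for byte.

A validation helper pushes the *same* pose samples through the surrogate
and the forward model directly and reports the relative percentile gaps;
on the synthetic bodies the converged surrogates agree with direct
Monte-Carlo to well under 2 % at the 50th and 95th percentiles.

## Synthetic phantom pair

The generator produces study inputs, not anatomy: a stylized body from
nested quadric primitives on a 64×64×160 grid at 2 mm (≈0.32 m tall,
≈0.84 kg — a desk-scale body; all conclusions are about the methodology,
not human-absolute SAR). From inferior to superior: two legs (skin/fat/
muscle shells, bone core), a **barrel-shaped trunk** (elliptic
cross-section, parabolic waist taper 20 %) with skin and fat layers,
muscle bulk, a spine (cortical shell, spongy core), paired lungs, heart,
liver (right), spleen (left), stomach, kidneys; two arms resting on the
abdomen; a neck; a spherical head with scalp, skull, brain and two eyes.
Overlaps resolve in painter's order (later primitives overwrite earlier).
Organ centres and all radii are jittered per seed, so seeds give distinct
but structurally identical bodies.

Three geometric choices matter dosimetrically and were made deliberately:
the liver/spleen offsets give a left–right asymmetry so tilt has a
nonzero effect; the barrel trunk makes the peak-SAR slice unique so the
peak moves smoothly under Z-shift (an extruded trunk has identical slices
and a pose-independent peak); and the arms lie on the abdomen — the
standard supine position — near the coil axis where the induced field
vanishes, so the two (symmetric) arms never become tied competitors for
the peak-SAR site, which would make the pose response non-smooth.

The individual counterpart is derived from the reference by
(1) relabelling detailed tissues to homogenized groups — all limb tissues
collapse to Muscle; (2) a seeded smooth radial scale per long-axis slice
(a constant mode of guaranteed magnitude, 50–100 % of the 4 % default
amplitude, plus two weaker cosine modes), applied by nearest-neighbour
resampling about the transverse grid centre — total mass changes by at
most ~2× the amplitude, comfortably below 10 %; (3) homogenizing the
dielectric table by mass weighting over the reference masses. The limb
rows carry **zero weight** in the homogenization: simplified limb voxels
*adopt* muscle's properties (the conservative high-conductivity
assumption) rather than diluting the muscle group with limb skin, fat and
bone.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: anatomical shape detail and organ registration
error (organ overlap between the pair is near-perfect here, unlike real
deformable-model registration); frequency-dependent dielectric dispersion
(single-frequency tables only); wave propagation, standing waves and coil
loading (quasi-static physics); human-scale absolute SAR levels.

## Problem sizes and numerics

Default study sizes: 100-point design, degrees 1–5, 10⁵ distribution
draws, ≈40 s per phantom pair end to end on one CPU. The test suite uses
a 4 mm-voxel variant of the same body (32×32×80) for pipeline-level
tests, and the full-resolution pair for the headline convergence checks.
Numerical conventions worth knowing: QR-based leverages and coefficient
solves; a rank guard rejects design matrices with near-zero pivots;
LAR stops when residual correlations fall below 1e-12 relative;
percentile interpolation is linear; psar10g location ties take the first
voxel in C order; all seeds derive from explicit config fields and stay
below 2³¹.

## Known limitations

* The forward model is first-order physics; it cannot rank coil designs
  or predict regulatory-scale absolute SAR.
* pSAR10g as a function of pose is only piecewise smooth: when two
  spatially separated sites compete for the maximum, the response has a
  kink that polynomial bases approximate slowly. The synthetic bodies
  are built so a single site dominates over the pose range; on bodies
  where sites trade places, expect larger leave-one-out errors for the
  peak metric than for the averaged ones — as observed here (≈1.7 % vs
  ≈0.2–0.5 %).
* The corrected LOO factor assumes a well-conditioned information
  matrix; with nearly collinear active sets the correction can be
  pessimistic.
* Truncated inputs are standardized as untruncated Gaussians for the
  basis weight (≈0.27 % of mass ignored).
* The geometric perturbation operates at voxel resolution: amplitudes
  below ≈2.5 % of a radius are invisible at 2 mm voxels, and the
  perturbed surface is stair-stepped like any voxel model.
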