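# Methods

## Physical model

A scintillating-fiber (SciFi) ribbon consists of six layers of 250 µm
polystyrene fibers at 275 µm in-layer pitch, adjacent layers staggered by
half a pitch.  Assuming each layer receives the same dose, the six layers
collapse into a single interleaved set of fiber centers with an effective
across-fiber sampling pitch of 137.5 µm.  Each fiber's light output is the
dose line-integrated along its length, so the ribbon measures the 1D
projection p(x) of the 2D dose field D(x, z) in the detector plane.  Optical
attenuation and scintillation efficiency along the fiber are taken as
uniform and folded into a single proportionality constant: the
reconstruction only ever uses relative signals, so a smooth multiplicative
efficiency would cancel in all reported metrics.

Ground-truth cone fields are modeled as a flat top with an error-function
penumbra, D(r) = D₀ · Φ((d/2 − r)/σ) with Φ the standard normal CDF — the
profile of a uniform disk blurred by an isotropic Gaussian.  This reproduces
the flat-top-plus-penumbra structure of measured small fields without Monte
Carlo transport; it does not model horns, spectral softening off-axis, or
depth dependence.  Square fields (used to validate the projection geometry)
are the product of two blurred edge pairs in the rotated frame.

### Generator defaults

* penumbra sigma: 0.8 mm (20–80% penumbra 2·0.8416·σ ≈ 1.35 mm, typical of
  6 MV cone collimators at the depth of dose maximum);
* relative peak doses of the seven-cone suite (4, 5, 6, 7.5, 10, 12.5,
  15 mm): 0.65, 0.74, 0.81, 0.87, 0.92, 0.96, 1.00 — realistic relative
  outputs for 6 MV stereotactic cones, decreasing toward small fields
  because of source occlusion and loss of lateral electron equilibrium;
* camera: 68.75 µm pixels (2 px per effective fiber pitch), one Gaussian
  stripe per fiber with exact total-intensity normalization.  The stripe
  width is a free parameter of the camera model (the fiber-to-pixel optics
  are not specified by the detector geometry); the default σ = 0.09 mm is
  the 250 µm fiber face (second moment 0.25/√12 ≈ 0.072 mm) blurred by a
  modest lens PSF.  At this width the rendered fiber comb leaves < 0.1%
  ripple on the integrated profile; much narrower stripes alias against the
  5-pixel binning blocks (the binned pitch is exactly 2.5 fiber pitches) and
  imprint a ~1% oscillation on p(x), which the ill-conditioned inversion
  amplifies near the axis;
* noise: Gaussian read noise plus sparse single-pixel impulses (radiation
  hitting the in-vault camera), both driven by one seed.  Negative pixels
  are clamped to zero, as a camera would.

What the generator does **not** emulate: fiber-to-fiber gain variation, dead
fibers, optical cross-talk, camera vignetting, dose-rate drift between
acquisitions.  Passing the recovery tests therefore shows the chain is
correct and stable under read/impulse noise at realistic levels — not that
it is robust to every artifact of a physical acquisition.

## Measurement chain

Order of operations: 3×3 median filter (impulse removal must precede any
averaging), 5×5 mean binning (SNR gain 10·log₁₀25 ≈ 14 dB; the mean keeps
amplitudes pitch-independent), y-axis integration to p(x), background
subtraction (median of the outer 10% of samples on each side, negatives
clamped — the inversion assumes S from non-negative dose), linear resampling
to the 200 µm reconstruction grid, and symmetric folding about the field
center into S_i = ½(p(c+x_i) + p(c−x_i)), x_i = (i−1)·0.2 mm, i = 1…123
(24.6 mm support).  The field center c is the intensity centroid of p over
samples ≥ 5% of the maximum; sub-grid centers are handled by linear
interpolation during folding.  In the simulation chain the per-column light
totals are rescaled by (effective pitch · f²/binned pitch) so that p(x) is
the projected dose ∫D dz in the phantom's dose units; on real images this
factor is an arbitrary constant and cancels in all metrics.

## Inversion

Disk radii follow the recurrence R_{j+1} = R_j + 0.2 mm seeded at
R₀ = 0.4 mm, giving the m = 122 unknown disks R_j = 0.6 … 24.8 mm (R₀ is
the seed, not a disk, which keeps all radii strictly positive).  With
n = 123 ≥ m the chord-length system is overdetermined.  SIRT with inverse
row/column-sum preconditioning and a per-iteration non-negativity clamp runs
for exactly 7000 iterations from β = 0; the iteration cap is the
regularizer.  Zero rows or columns of A (possible on non-default grids) get
zero weights and never update, with a warning.  All linear algebra is dense
double precision — the 123×122 system solves in well under a second, so no
sparsity is exploited.

Convergence note: smooth dose distributions converge quickly, but spike-like
thickness patterns (a single isolated disk) are the slowest-converging
targets and are *not* fully resolved at 7000 iterations — that slow
convergence of high-frequency components is precisely what makes the
iteration cap a regularizer.  On a reduced 20×19 system SIRT reaches the
non-negative least-squares solution (data-term difference < 10⁻³) by
7000 iterations for smooth targets and by ~30 000 for a single-disk spike.

### Dose profile vs. reprojection

Two radial profiles can be derived from the stack.  The physically
consistent dose is the stack height d(r) = Σ_j β_j·[r ≤ R_j]; it is the
default for all metrics.  The chord-weighted form
pr(x) = Σ_j [x ≤ R_j]·β_j·√(R_j² − x²) (half the forward projection) is kept
as `reprojection_profile` for residual diagnostics and comparison studies —
for a flat-top field it yields a semicircle-like shape whose FWHM is
(√3/2)·diameter, which is not a dose profile.  Both are selectable through
`profile_kind`.

### Sampling the reconstructed profile

The stack height is piecewise constant on the radial bins (R_{j−1}, R_j].
A bin's height estimates the dose at the bin *center*, so the pipeline
samples d at R_j − 0.1 mm; evaluating at bin edges instead imprints a
systematic +0.2 mm FWHM broadening (half a bin per side).  The innermost
disk (R₁ = 0.6 mm) is three bins wide, so its height is an average over the
central region rather than the axis dose, and the chord weighting makes the
individual near-axis heights oscillate by up to ~1%.  The on-axis sample is
therefore taken as the vertex of the even-symmetric parabola (zero slope at
r = 0, as any smooth radial profile must have) least-squares fitted through
the four innermost bin centers (r ≤ 1.1 mm).  Four points average the
oscillation while the parabola is still a good local model for fields
≥ 4 mm; without this estimator the on-axis dose of a 4 mm field is biased
low by ~2.5%, outside the method's own output-factor envelope.

## Metrics

Levels are referenced to the profile maximum (small fields have no plateau
to fit), crossings are located by linear interpolation between bracketing
samples, and the search walks outward from the global maximum so spurious
noise crossings far from the field are ignored.  Radial (half) profiles
report FWHM as twice the one-sided width and their single edge stands for
both (equal) edges of the penumbra average.  The output factor is the
on-axis dose ratio to the named reference field (15 mm cone by default) and
requires both fields to share the same calibration chain.  All metrics are
invariant under positive rescaling; FWHM and penumbra are translation
invariant, the centroid is translation equivariant.

## Problem sizes and tolerances

The test suite and the acceptance script use: 10⁶-pixel images for the
binning SNR measurement; dose-field grids of 50 µm spacing (projection
quadrature errors < 0.5% of peak against the closed-form chord length);
the full 123×122 system at 7000 iterations for all recovery studies; the
seven-cone suite noiseless plus 20 noise seeds at 1% of image peak for the
output-factor study; and a 20×19 reduced system for the NNLS oracle
comparison.  Recovery envelopes: FWHM within ±0.3 mm of ground truth,
output factors within ±1.6%, center reproducibility ≤ 0.02 mm — the
engineering tolerances the chain is designed to meet.

## Known limitations

* The method assumes rotational symmetry; elliptic or MLC-shaped fields
  violate the disk model and are out of scope (they would need multi-angle
  tomographic reconstruction).
* Penumbra of reconstructed fields is systematically slightly wider
  (~+0.1 mm) than ground truth: the camera/binning blur and the finite
  radial bin width both broaden edges, and no deconvolution is attempted.
* Absolute dosimetry is out of scope: every output is relative to the
  profile maximum or to a reference field.
* The innermost 0.6 mm of the radial grid limits on-axis resolution; fields
  below ~3 mm diameter would need a finer inner radius grid than the
  default recurrence provides.
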