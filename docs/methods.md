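# Methods

This note documents the physical model behind the package, the parameters
that matter, the numerical choices, and the limits of what the synthetic
tests demonstrate.

## Forward model

**Geometry.**  Images are 2D pixel grids (0-based, pixel centers at integer
coordinates, x right, y down); emitters live in 3D sample coordinates (nm)
with `z = 0` the focal plane.  Defaults: 65 nm pixels, 230 nm illumination
stripe period, pattern directions 0°/60°/120°.  These defaults are
engineering choices on the scale of a high-NA system, not physics claims,
and are configurable.

**Detection PSF.**  A separable Gaussian in peak-response form,

    w(dx, dy, dz) = exp(−4 ln2 (dx²+dy²)/FWHM_lat²) · exp(−4 ln2 dz²/FWHM_ax²),

with wide-field FWHM 230 nm lateral / 670 nm axial and half those values in
"SR" mode.  The Gaussian is chosen for analytic testability (every cross-talk
weight in the accuracy analysis has a closed form); a vectorial high-NA PSF
would change the headline error percentages at the percent level, which is
why the PSF model is stated here rather than buried.

**Excitation.**  Each pattern direction k produces a sinusoidal intensity
`1 + M(z)·cos(k⃗_k·x⃗ + p)` at the emitter's position (phases p ∈ {0, π}) and
an excitation polarization `θ_k = pattern angle + π/2` (s-polarized beams:
the sample-plane field is perpendicular to the pattern wavevector).  A
wobbling dipole of in-plane orientation φ and modulation depth m responds
with weight `1 + m cos(2(θ_k − φ))`; averaged over the three equally spaced
angles this is 1, so polarization modulation conserves total signal.

**Pattern contrast decays with defocus.**  The illumination pattern is
projected through the same optics as the detection path, so its modulation
contrast at defocus z is taken as the axial response,
`M(z) = exp(−4 ln2 z²/FWHM_ax²)`.  This decay is the physical carrier of the
optical-sectioning information: without it a defocused layer would remain
fully modulated and HiLo could not reject it.  For laterally uniform planes
(`render_uniform_plane`) the detected brightness is additionally taken as
z-independent — a uniform fluorescent layer images to the same mean
intensity at any defocus (the wide-field "missing cone"), only its pattern
contrast dies.  Point emitters keep the peak-response PSF weight; their
lateral profile is not widened with defocus (a deliberate simplification —
see Limitations).

**Spectral channels.**  An emitter of emission ratio ρ splits its photons
between the numerator ("red") and denominator ("green") channel.  Two
conventions are implemented because the true instrument response is a
calibration matter:

* `equal_total`: fractions ρ/(1+ρ) and 1/(1+ρ) (channel sum = brightness),
* `equal_denominator`: fractions ρ and 1 (denominator channel = brightness).

Both are carried through the accuracy report; the default headline uses
`equal_denominator`.

**Noise.**  Poisson shot noise on the expected photon image, then additive
Gaussian read noise.  A seed is mandatory; identical seeds give bit-identical
stacks.

## Reconstruction

**HiLo (two-phase dialect).**  Per direction, `U = (I_0+I_π)/2` and
`D = (I_0−I_π)/2`; `Lo = (π/2)·LP[|D|]` (the π/2 compensates the 2/π mean of
a rectified cosine), `Hi = U − LP[U]`, output `clip(Hi + α·η·Lo, 0)` with
α = 1 throughout.  LP is a Gaussian low-pass with spectral sigma
`cutoff/√(2 ln 2)` (amplitude 1/2 at the cutoff); the default cutoff is half
the pattern frequency.  Low- and high-pass are exact complements, so the
spectrum is partitioned without gaps.  η is computed per frame pair as the
ratio of radially averaged FFT amplitudes of Hi and Lo in a ±10% band around
the cutoff; if either band amplitude is negligible (relative to the image DC,
e.g. for a strictly uniform field) η falls back to 1, which keeps the
sectioned mean of a fully modulated in-focus uniform field equal to its
uniform-image mean.  Clipping at zero is applied last.

**5-phase SIM adapter.**  For SIM acquisitions the uniform image is the mean
of the five phases and the structured image is the first phase; the
complementary π-pair member is synthesized as `2·uniform − structured` so the
same HiLo path serves both modes.  Full SIM band separation / Wiener
reconstruction is out of scope.

**Harmonic polarimetry.**  `a0 = mean_k I_k`, `a1 = (2/3) Σ_k I_k e^{−2iθ_k}`,
`m = |a1|/a0`, `φ = (−arg a1/2) mod π`.  The 2/3 normalization makes m equal
the true cosine modulation depth; the sign convention makes φ the excitation
angle of maximal response, measured from the image +x axis.  The estimator is
exact (machine precision) for equally spaced angles; unequally spaced angle
sets are rejected rather than solved by least squares, preserving that
contract.  Pixels with `a0 ≤ 0` are masked; the validity mask additionally
drops pixels whose raw `|a1|/a0` exceeds 1 by more than a tolerance
(default 0.1), since such excursions are noise artifacts.

**Registration and flat field.**  Beads are localized by thresholding +
connected components + intensity-weighted centroid over the component plus a
one-pixel dilation ring (≈0.01 px accuracy for noiseless Gaussian spots; no
Gaussian fitting needed at bead SNR).  Pairs are matched by mutual nearest
neighbor within a 5 px default radius — the two channels are assumed
pre-aligned to a few pixels, as on a real image splitter — and the 2×3
affine is the least-squares solution; fewer than three non-collinear pairs
is a hard error, and a fit residual above 1 px RMS aborts the pipeline.
The flat field is the Gaussian-smoothed (σ = image size/8, reflect boundary)
mean bead-slide image, normalized to unit mean; all six frames are divided
by it.

## The accuracy experiment

Two equal-intensity ideal dipoles: the in-focus target (emission ratio 1,
orientation 0°, z = 0) and a contaminant 300 nm deeper, shifted 50 nm in x
(ratio 0.5, orientation 60°).  The scene is rendered noiselessly on a 10 nm
grid (128² px) with both molecules on pixel centers; maps are built from
phase-averaged (uniform) images — the experiment isolates the effect of
*resolution*, not sectioning — and read at each molecule's true lateral
pixel.

With the Gaussian PSF the contaminant's weight at the target pixel is
w = 0.503 (WF) and 0.064 (SR), and every error has a closed form; the
implementation reproduces those closed forms to the pixelization limit.
Headline values (equal-denominator split, in-focus target): polarity
13.9% → 2.5%, phase 42.4% → 8.9%, orientation 8.4% → 0.9% going from WF to
SR.  The defocused molecule's own rows are also reported but are dominated
by its axial attenuation (its detection weight at 300 nm defocus is 0.57),
so they do not represent the "target molecule" reading.

**Orientation-error bound.**  Mixing two planar-dipole harmonic phasors 120°
apart in the doubled-angle space can rotate the argument of the sum by at
most 60°, i.e. the observed orientation by at most 30°, capping the
orientation mapping error at 100/6 ≈ 16.7% — and at the actual w = 0.503 the
error is 8.4%.  Reference values above this bound would require ingredients
this model excludes (out-of-plane dipole tilt, polarization-sensitive
detection, or region- rather than point-evaluated errors).  The accuracy
report and CLI print this caveat alongside the numbers rather than hiding
the shortfall.

The noise sweep repeats the same scene at given photon levels with seeded
Poisson/read noise and reports mean ± sd errors; at ≥10⁶ photons it converges
to the noiseless values within one percentage point.

## Statistics utilities

Polyline sampling steps at 1 px arc length with a perpendicular band of
half-width h, nearest-pixel lookup (no interpolation — the maps are
measured as displayed), masked pixels excluded.  Repeat acceptance uses
fluctuation = (max − min)/mean with an inclusive 0.15 bound — the strictest
common reading of "fluctuation within 15%".  Group ellipses are the sample
mean/covariance of (ratio, depth) points with σ and 2σ contours at
Mahalanobis distances 1 and 2; classification is exclusive: a point gets a
label only when inside exactly one σ contour, otherwise "ambiguous" (≥2) or
"unassigned" (0).

## Test scenes and what they show

The end-to-end recovery scenes place emitters on the **illumination crest
lattice**: positions where all three pattern wavevectors satisfy
k⃗_k·x⃗ ≡ 0 (mod 2π) simultaneously (the 0/60/120° wavevectors close under
subtraction, so this lattice exists), spaced ≥ 20 px apart.  This is
deliberate: for a *sub-period point object* the two-phase HiLo Lo band
carries a factor |cos(k⃗_k·x⃗_e)| that depends on where the emitter sits in
each direction's pattern, giving a direction-dependent gain for off-lattice
points.  Extended membranous structures — the actual imaging target — span
full pattern periods and average this factor out, but isolated point sources
do not.  On the crest lattice the gain is identical across directions and
the pipeline recovers (ρ, m, φ) essentially exactly; the recovery tolerances
(ρ within 2%, m within 0.05, φ within 2°) should therefore be read as
validating the estimator chain, not as a field-position-independent
guarantee for single molecules.  Orientation is compared only where the true
modulation depth is ≥ 0.1; below that φ is ill-conditioned and undefined at
m = 0.

Problem sizes used by the test suite and the acceptance script — 128–192 px
images, 20-emitter scenes, 10⁴-sample property checks, ≤4 noise
repetitions — were chosen as the smallest scenes that exercise every code
path with comfortable numerical margins; all runs complete in seconds.

## Limitations

* Dipoles are confined to the sample plane; no out-of-plane tilt, no
  polarization-sensitive detection.
* Point emitters are rendered at fixed lateral width regardless of defocus
  (peak-weight model); laterally uniform planes get the flux-conserving
  treatment instead.  Scenes mixing dense out-of-focus *point* clutter are
  therefore not faithfully sectioned in simulation.
* The HiLo dialect is the simplest consistent with a π-shifted pair
  (rectified-difference demodulation); local-contrast HiLo variants and full
  SIM reconstruction are out of scope.
* No fluorophore photokinetics (bleaching, blinking) and no conversion of
  emission ratio to absolute dielectric polarity (requires solvent
  calibration of the dye).
* Channel registration is a global 2D affine; higher-order chromatic
  distortion fields and time-lapse drift are not modeled.
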