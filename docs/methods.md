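# Methods

This note records the model, the parameter choices and the numerical
conventions behind `isimtwin`, and what the synthetic benchmarks do and do
not demonstrate about real instruments.

## Optical model

The instrument is reduced to a small parameter set (`OpticalConfig`):
objective NA and focal length, tube-lens focal length, excitation and
emission wavelengths, the lenslet/pinhole array geometry in the
intermediate image plane, the spot contraction factor, and the camera
sampling at the specimen.  Defaults describe the modelled microscope: a
1.49 NA objective (f = 3 mm) with an f = 350 mm tube lens (magnification
116.7×), a 222 µm-pitch square lenslet grid with 40 µm pinholes (sample
plane: 1902.9 nm focus pitch, 171.4 nm pinhole radius), contraction
factor 2, and 56.0 nm pixels (the as-built sampling; the 55.5 nm design
value is kept as a documented constant, selectable by setting
`sample_pixel_pitch`).

All point-spread functions are Gaussian.  This matches how such
instruments are characterised in practice — resolution is reported as the
FWHM of Gaussian fits to line profiles, and deconvolution PSFs are
specified as Gaussian FWHMs in pixels — and it makes the design laws
exact: the product of two Gaussians of width σ is a Gaussian of width
σ/√2.  The width convention is fixed at `FWHM = 2√(2 ln 2) σ`.  Default
widths are the standard conveniences `FWHM_lat = 0.51 λ/NA` and
`FWHM_ax = 1.77 n λ/NA²` (n = 1.515); any measured width can be
substituted.  Vectorial/Airy PSFs and aberrations (coma, chromatic offsets
from tilted thick optics) are out of scope.

All lengths are carried internally in nanometres; configuration fields
keep instrument-builder units (mm, µm, nm) and are converted once.
2D arrays are (y, x), 3D arrays (z, y, x); physical coordinates place the
origin on the centre voxel `(n−1)//2` of each axis.

## Image formation

*Widefield*: the sample convolved with the emission PSF (linear, FFT,
zero-padded — flux-preserving for interior structures).

*Raw multifocal frame* at scan offset `o`: the sample is multiplied by the
excitation field (unit-peak Gaussians on the square focus lattice
translated by `o`; the lattice may be rotated about the optical axis),
convolved with the emission PSF, then multiplied by the binary pinhole
mask — unit-transmission disks of the pinhole radius centred on the same
lattice.  Pinhole radii at or above half the pitch are rejected
(overlapping pinholes).  The pinhole transmission profile is a hard disk;
the radius is freely configurable.

*Pixel reassignment* (the shared kernel of the analog and digital paths):
every camera pixel's intensity is relocated from `x` to
`f + s·(x − f)`, where `f` is the nearest lattice focus for that pixel
and `s` the reassignment scale, and deposited with bilinear weights.
This flux-preserving scatter is the adjoint of linear-interpolation
patch contraction; it makes `s = 1` exactly the plain sum of frames,
keeps arbitrarily small scales well-defined on a raster (a pure
coordinate-warp reading drops nearly all flux once the contracted patch
falls below a pixel), and conserves photons.  The analog image
(`simulate_isim`) accumulates reassigned frames at
`s = 1/contraction_factor`; the digital reconstruction
(`digital_reconstruct`) applies a digital pinhole and the same kernel at a
user-chosen scale.  Their agreement is therefore exact up to floating
point, and is asserted at 1e-6 relative on beads, filaments and uniform
layers.

*3D stacks* are treated slice-wise: for each detection plane the sample is
first collapsed along z with the product of the Gaussian axial excitation
and emission profiles, then passed through the 2D lateral machinery.
This reproduces the axial product-PSF narrowing for point objects but
deliberately omits depth-dependent lateral spreading, so true
optical sectioning of laterally uniform 3D backgrounds is *not*
reproduced.  Axial z-steps of 0.25 µm or smaller keep stacks adequately
sampled for deconvolution.

*Noise*: `Poisson(photon_scale · I) + N(0, read_sigma)`, clipped at zero,
deterministic given its seed.  No sCMOS fixed-pattern terms.

## Scanning

2D unit-cell rasters (`ScanPattern.unit_cell`) generalise the physical 1D
mirror sweep; the step divides the focus pitch exactly, which is what
makes the pattern-averaged excitation spatially uniform (ripple
`2·exp(−2π²σ²/step²)`; with σ = 100 nm this is < 1e-6 for 16 steps per
1.8 µm pitch — scans coarser than ≈ σ leave visible modulation, which is
why the bundled pipeline configurations use dense steps).  The
1D sweep mode (`ScanPattern.line_sweep`) exists to reproduce scan-line
stripes: with a square grid a uniform layer images as bands at the focus
pitch; rotating the grid so successive lenslet columns stagger by
pitch/16 across the sweep axis (and sweeping ≳ 16 pitches) fills the
transverse axis and leaves the shallow residual ripple that flat-field
division or line-bin normalisation removes.  The stripe severity metric
is `std(line means)/grand mean`; the line-bin bin height defaults to 1.

## Reconstruction and deconvolution

`ReconSettings.scale` multiplies distances from the focus: **0.5 is the
half-displacement reassignment**, equivalent to the instrument's
contraction by 2 (stated explicitly to avoid the ½-vs-2 ambiguity).
`scan_scale_factors` brute-forces the scale over a grid on a point-source
stack and returns the FWHM table and its argmin; with equal
excitation/emission widths the image variance is quadratic in the scale
with the minimum exactly at 0.5 for any pinhole radius (the reassigned
mean `(o+x)/2` is independent of the truncated difference `x−o`).  The
scan accepts scale 0 (all pinholed flux collapses onto the foci) so the
optimum is bracketed from both sides; an effectively open digital pinhole
makes the scale-1.0 row reproduce the widefield width.

Richardson–Lucy is the plain multiplicative update
`est ← est · [(image / (est⊗psf)) ⊗ psf_flipped]` with: reflective
padding by one PSF half-support (interior flux conserved well within
0.1 % over 40 iterations), epsilon 1e-12 in the ratio, initial estimate
flat at the data mean (any flat level gives the same trajectory from
iteration 1), and no acceleration — the fixed point `est = truth` when
`image = truth⊗psf` then holds exactly, which the tests exploit.  The
Gaussian deconvolution PSF is parameterised by per-axis FWHM in pixels
(x, y, z); 4 × 4 × 9 px at 56 nm sampling is the default, matching the
instrument's measured raw PSF.  Boundary/initialisation conventions of
other RL implementations differ; agreement with scikit-image's RL is
verified on interior pixels only.

## Measurement protocol

Lateral FWHM: select the brightest z-slice or the per-pixel maximum
projection, locate the feature by its intensity centroid, take the
profile perpendicular to the principal axis of the intensity
second-moment tensor (automating the manual line placement an operator
would do), and fit `offset + amplitude·Gaussian` by least squares.
Profiles are sampled with cubic-spline interpolation (bilinear sampling
biases diagonal profiles by ≈ 0.5 %).  Fit initialisation: amplitude =
max−min, centre = argmax, σ = span/4, σ bounded positive.  Fits report
the FWHM standard error from the covariance and r²; non-convergence
raises a typed error, never a silent fallback.  Axial FWHM fits the
z-profile through the lateral peak.  `resolution_report` combines
widefield / raw / deconvolved measurements into improvement ratios with
propagated standard errors; `summarize_fwhms` provides the conventional
mean ± sd over ~ten structures.

## Benchmarks and their scales

The acceptance benchmarks run on a **single-focus bead bench**: one
sub-diffractive bead, equal excitation and emission σ = 100 nm, 25 nm
pixels on a 97 × 97 grid, a 150 nm sample-plane pinhole radius, and a 2D
raster of ±500 nm in 50 nm steps (441 frames).  These sizes keep each
benchmark under a few seconds while sampling the PSF with ≈ 9 pixels per
FWHM.  The 150 nm pinhole stands in for the "small pinhole" limit: the
closed-form √2 anchor is independent of pinhole radius at equal PSF
widths, whereas a genuinely sub-pixel pinhole aliases on the raster.
Multi-focus scenes (equivalence, stripes, pipeline) use 64–128 px fields
with focus pitches of 0.9–1.9 µm.

Measured on this bench: widefield 235.5 nm, raw 167.8 nm (gain 1.403 vs
√2 = 1.414; the deficit is bilinear-deposit and raster discretisation),
and Richardson–Lucy with the matched Gaussian PSF passes the design
factor 2 within ~15 iterations.  On a noiseless point source RL keeps
contracting toward a delta, so the 40-iteration gain (≈ 3.7) overshoots
2; the factor-2 design claim is a bound achieved, not an asymptote, in
this setting.

## What passing tests do and do not show

The generators emulate geometry, not photophysics: no labelling
stochasticity, bleaching, or background; features are rendered by
hard nearest-voxel membership (a 25 nm filament at 56 nm sampling is one
pixel wide) so geometric oracles are exact at the cost of sub-voxel
fidelity.  Passing benchmarks demonstrate that the *processing chain*
(reassignment, reconstruction, deconvolution, measurement) realises the
design laws under the stated Gaussian model; they say nothing about a
physical instrument's alignment quality, aberrations, vignetting, or
noise-limited resolution, which is precisely why desk-scale acceptance is
anchored on the design laws rather than on any instrument's measured
numbers.
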