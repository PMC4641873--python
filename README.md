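# isimtwin

Forward simulation, pixel-reassignment reconstruction and resolution
measurement for **instant structured illumination microscopy (iSIM)** and
its digital predecessor, multifocal SIM (MSIM).

An iSIM excites the sample with a square grid of diffraction-limited foci
(a microlens array), detects the fluorescence through a matched pinhole
array, optically **contracts each pinholed spot image by a factor of 2**
about its focus, and sweeps the pattern across the field so the contracted
images integrate into a single super-resolved camera exposure.  This
package is a physically parameterised model of that machinery for people
who build, align or analyse such instruments: it lets you verify the
design laws on synthetic specimens, prototype reconstruction and
deconvolution settings, and sanity-check measurement protocols before
touching hardware.

## The model

With Gaussian excitation and emission PSFs, a point source at the origin
detected at camera position *x* while the excitation focus sits at *o* has
joint density

```
p(o, x) ∝ h_exc(o) · h_em(x − o') · P(|x − pinhole|)        (o' = source)
```

Pixel reassignment relocates each detected photon to `o + s·(x − o)`.
For equal PSF widths σ the reassigned coordinate at the half-displacement
scale `s = 1/2` is `(o + x)/2`, whose distribution is **exactly** Gaussian
with width `σ/√2` — the √2 lateral resolution gain of the raw image.
Because the optical transfer function support is doubled, Richardson–Lucy
deconvolution with the measured raw PSF recovers the remaining factor,
taking the total improvement to ≈ 2×.  The FWHM convention throughout is
`FWHM = 2√(2 ln 2)·σ` from least-squares Gaussian fits to line profiles.

The analog instrument and the digital reconstruction share one
reassignment kernel, so `simulate_isim(...)` and
`digital_reconstruct(stack, scale=0.5)` agree to floating point — the
package is its own cross-check.

## What's in the box

| module | contents |
| --- | --- |
| `isimtwin.optics` | `OpticalConfig` (NA, wavelengths, focal lengths, array pitches, sampling), Gaussian `PSFModel`, FWHM↔σ, PSF rendering |
| `isimtwin.samples` | synthetic beads, 25 nm filaments (microtubule stand-ins), uniform layers |
| `isimtwin.forward` | excitation focus grids, scan patterns, pinhole masks, widefield / raw-frame / analog-iSIM image formation, shot+read noise |
| `isimtwin.reconstruct` | digital pixel reassignment, reassignment-scale scans, stripe metric, flat-field and line-bin stripe correction |
| `isimtwin.deconv` | plain Richardson–Lucy with Gaussian PSF parameterisation (FWHM in pixels) |
| `isimtwin.measure` | line profiles, Gaussian fits with uncertainties, lateral/axial FWHM, resolution reports |
| `isimtwin.io` | 16-bit TIFF + plain-text sidecars, time-lapse conventions, the end-to-end pipeline runner |
| `isimtwin.cli` | `isim simulate / reconstruct / deconvolve / measure / pipeline / demo` |

## Worked example

`examples/01_resolution_gain.py` simulates one sub-diffractive bead with
equal excitation/emission PSFs (σ = 100 nm), images it in widefield and
analog iSIM mode, deconvolves the raw image with the matched Gaussian PSF,
and measures everything:

```
resolution report (lateral FWHM, Gaussian fits)
  widefield   : 235.5 +/- 0.0 nm (r2=1.0000)
  raw         : 167.8 +/- 0.2 nm (r2=0.9999)
  deconvolved : 63.1 +/- 0.1 nm (r2=0.9999)
  gain raw         (wf/raw)   : 1.403 +/- 0.002
  gain deconvolved (wf/decon) : 3.732 +/- 0.004
```

The widefield FWHM is `2√(2 ln 2)·100 ≈ 235.5` nm; the raw image shows
the √2 narrowing (1.403 measured vs 1.414 ideal — the 0.8 % deficit is
raster discretisation); on a noiseless point source Richardson–Lucy keeps
sharpening past the design factor of 2.

The other examples scan the reassignment scale (`02`, showing the minimum
at 0.5 and the widefield width recovered at scale 1.0), reproduce and
correct scan-line stripes from 1D sweeping (`03`), and run the
config-driven pipeline with TIFF/sidecar I/O (`04`).  A one-command tour:

```sh
isim demo --out demo_run
```

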