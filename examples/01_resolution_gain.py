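"""Resolution gain of pixel reassignment, measured on a synthetic bead.

Simulates a sub-diffractive bead three ways — widefield, raw
pixel-reassigned (the single-exposure analog image), and Richardson-Lucy
deconvolved — with equal Gaussian excitation/emission PSFs (sigma 100 nm),
then measures each lateral FWHM by Gaussian fit.  With equal PSF widths
the raw reassigned PSF is the product PSF, sigma/sqrt(2), so the expected
raw gain is sqrt(2) = 1.414; deconvolution with the matched raw PSF
pushes the total gain past 2.
"""

import numpy as np

import isimtwin as it
from isimtwin.deconv import default_psf_shape

# single excitation focus (6 um pitch >> field), 150 nm pinhole radius,
# 25 nm pixels
cfg = it.OpticalConfig(lenslet_pitch=700.0, pinhole_diameter=35.0, sample_pixel_pitch=25.0)
psf = it.PSFModel(sigma_lateral=100.0)
bead = it.make_beads(it.SampleSpec(kind="beads", positions=[(0.0, 0.0)]), (97, 97), 25.0)
scan = it.ScanPattern.raster(extent=500.0, step=50.0)

widefield = it.simulate_widefield(bead, cfg, em_psf=psf)
raw = it.simulate_isim(bead, cfg, scan, exc_psf=psf, em_psf=psf)

raw_fwhm = it.lateral_fwhm(raw)
matched = (raw_fwhm.fwhm / cfg.sample_pixel_pitch,) * 2
rl_psf = it.psf_from_fwhm_px(matched, default_psf_shape(matched))
decon = it.rl_deconvolve(raw, rl_psf, iterations=40)

report = it.resolution_report(widefield, raw, decon)
print(report.to_text())
print(f"expected raw gain: sqrt(2) = {np.sqrt(2):.3f}")
print("The raw gain is the shift-and-sum (pixel reassignment) narrowing of")
print("the PSF; the deconvolved gain shows the recovery of the doubled")
print("optical-transfer-function support.")
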