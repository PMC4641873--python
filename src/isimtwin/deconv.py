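"""Richardson-Lucy deconvolution with Gaussian PSF parameterisation.

The reassigned raw image has a widened optical transfer function whose
high frequencies are attenuated; plain Richardson-Lucy (RL) iteration with
the measured (Gaussian-fitted) raw PSF restores them, taking the lateral
resolution gain from sqrt(2) toward the full factor of 2.

The implementation is the textbook multiplicative update

    est <- est * [ (image / (est conv psf)) conv psf_flipped ]

with reflective padding by one PSF support (so interior flux is conserved
to well under 0.1%), a 1e-12 epsilon guarding the ratio, and a flat
initial estimate at the data mean.  No acceleration is applied: the plain
update keeps the fixed point (est = truth when image = truth conv psf)
exact, which the tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .optics import FWHM_PER_SIGMA, ImageVolume

__all__ = ["DeconSettings", "psf_from_fwhm_px", "rl_deconvolve"]

_EPS = 1e-12


@dataclass(frozen=True)
class DeconSettings:
    """Iteration count and Gaussian PSF size (FWHM per axis, in pixels).

    The default PSF of 4 x 4 x 9 pixels (x, y, z) is the raw iSIM PSF of
    the modelled instrument expressed at its 56.0 nm lateral sampling.
    """

    iterations: int = 40
    psf_fwhm_px: tuple = (4.0, 4.0, 9.0)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if len(self.psf_fwhm_px) not in (2, 3) or any(f <= 0 for f in self.psf_fwhm_px):
            raise ValueError("psf_fwhm_px needs 2 or 3 positive components")


def psf_from_fwhm_px(fwhm_px, shape: tuple[int, ...]) -> ImageVolume:
    """Unit-sum Gaussian kernel from per-axis FWHMs given in pixels.

    ``fwhm_px`` is ordered (x, y) or (x, y, z); ``shape`` is the array
    shape (y, x) or (z, y, x), odd along every axis.  Pixel pitch metadata
    on the result is nominal (1 nm per pixel): the kernel lives in pixel
    units.
    """
    fwhm_px = tuple(float(f) for f in fwhm_px)
    if len(fwhm_px) != len(shape):
        raise ValueError(f"{len(fwhm_px)} FWHMs for a {len(shape)}D shape")
    if any(f <= 0 for f in fwhm_px):
        raise ValueError("FWHM components must be positive")
    if any(n <= 0 or n % 2 == 0 for n in shape):
        raise ValueError(f"shape must be odd along every axis, got {shape!r}")
    # axis order: shape is (y, x) / (z, y, x) but FWHMs arrive as (x, y[, z])
    sigmas = [f / FWHM_PER_SIGMA for f in fwhm_px]
    per_axis = list(reversed(sigmas))  # -> (y, x) or (z, y, x)

    out = np.ones((1,) * len(shape))
    for ax, (n, s) in enumerate(zip(shape, per_axis)):
        x = np.arange(n) - (n - 1) / 2
        g = np.exp(-(x**2) / (2 * s**2))
        sh = [1] * len(shape)
        sh[ax] = n
        out = out * g.reshape(sh)
    out = out / out.sum()
    return ImageVolume(out, 1.0, 1.0 if len(shape) == 3 else None)


def default_psf_shape(fwhm_px, support_fwhm: float = 3.0) -> tuple[int, ...]:
    """Odd kernel shape covering ``support_fwhm`` FWHMs per axis."""
    dims = []
    for f in reversed(tuple(fwhm_px)):
        half = max(2, int(math.ceil(support_fwhm * f / 2.0)))
        dims.append(2 * half + 1)
    return tuple(dims)


def rl_deconvolve(
    image: ImageVolume,
    psf: ImageVolume | np.ndarray,
    iterations: int = 40,
    initial: np.ndarray | None = None,
) -> ImageVolume:
    """Plain Richardson-Lucy deconvolution.

    Parameters
    ----------
    image : ImageVolume
        Non-negative 2D image or 3D stack.
    psf : ImageVolume or ndarray
        Non-negative kernel of the same dimensionality, normalised to unit
        sum (renormalised here if it is not, within 1e-6; otherwise an
        error).
    iterations : int
        Number of multiplicative updates (>= 1).
    initial : ndarray, optional
        Starting estimate; defaults to a flat image at the data mean.

    Returns
    -------
    ImageVolume
        Non-negative estimate with the input's pitch metadata.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    data = image.data
    kern = psf.data if isinstance(psf, ImageVolume) else np.asarray(psf, dtype=float)
    if kern.ndim != data.ndim:
        raise ValueError(f"PSF is {kern.ndim}D but image is {data.ndim}D")
    if np.any(kern < 0) or np.any(data < 0):
        raise ValueError("RL requires non-negative image and PSF")
    ksum = kern.sum()
    if ksum <= 0:
        raise ValueError("PSF must have positive total")
    if abs(ksum - 1.0) > 1e-6:
        kern = kern / ksum

    pad = tuple((n // 2 + 1, n // 2 + 1) for n in kern.shape)
    padded = np.pad(data, pad, mode="reflect")
    if initial is None:
        est = np.full_like(padded, max(float(data.mean()), _EPS))
    else:
        initial = np.asarray(initial, dtype=float)
        if initial.shape != data.shape:
            raise ValueError("initial estimate must match the image shape")
        est = np.pad(np.clip(initial, _EPS, None), pad, mode="reflect")
    flipped = kern[tuple(slice(None, None, -1) for _ in kern.shape)]
    for _ in range(iterations):
        conv = fftconvolve(est, kern, mode="same")
        ratio = padded / np.maximum(conv, _EPS)
        est = est * fftconvolve(ratio, flipped, mode="same")
        est = np.clip(est, 0.0, None)
    core = tuple(slice(p[0], p[0] + n) for p, n in zip(pad, data.shape))
    return image.with_data(est[core])
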