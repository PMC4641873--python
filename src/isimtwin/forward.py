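"""Image formation: widefield, multifocal raw frames, and analog iSIM.

The multifocal microscope excites the sample with a square grid of
diffraction-limited foci (pitch = lenslet pitch / magnification), detects
fluorescence through a matched pinhole array, and either

* records one camera frame per scan position (MSIM mode, a
  :class:`FrameStack` to be reconstructed digitally), or
* optically contracts each pinholed spot image about its focus by the
  contraction factor and accumulates all scan positions in a single
  exposure (analog iSIM mode, :func:`simulate_isim`).

The analog path is implemented with exactly the same pinholing and
pixel-reassignment kernel as the digital reconstruction, so the two are
numerically identical by construction — the digital-twin contract.

Pixel reassignment is flux-preserving: the intensity of each camera pixel
at position x is moved to ``f + s (x - f)`` (f = the nearest excitation
focus for that pixel, s = 1 / contraction_factor) and deposited with
bilinear weights.  With equal Gaussian excitation and emission PSFs of
width sigma, s = 1/2 yields an effective PSF of width sigma / sqrt(2): the
sqrt(2) lateral resolution gain of the raw image.

All convolutions are linear (FFT with zero padding via
``scipy.signal.fftconvolve``); emission kernels are rendered out to 4 sigma
so truncation is negligible.  3D stacks are handled slice-wise: for each
detection plane the sample is first collapsed along z with the product of
the Gaussian axial excitation and emission profiles (axial blur only — no
depth-dependent lateral spreading), then passed through the 2D lateral
machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .optics import (
    ImageVolume,
    OpticalConfig,
    PSFModel,
    render_psf,
    sample_plane_geometry,
)

__all__ = [
    "ScanPattern",
    "FrameStack",
    "NoiseSpec",
    "excitation_field",
    "pinhole_mask",
    "reassign_frame",
    "simulate_widefield",
    "raw_frame",
    "simulate_msim_stack",
    "simulate_isim",
    "add_noise",
]


# ---------------------------------------------------------------------------
# scan patterns and stacks


@dataclass(frozen=True)
class ScanPattern:
    """Ordered scan offsets (dx, dy) in nm applied to the excitation grid."""

    offsets: np.ndarray
    step: float

    def __post_init__(self) -> None:
        offsets = np.atleast_2d(np.asarray(self.offsets, dtype=float))
        if offsets.ndim != 2 or offsets.shape[1] != 2 or offsets.shape[0] == 0:
            raise ValueError("offsets must be a non-empty (N, 2) array of (dx, dy) nm")
        object.__setattr__(self, "offsets", offsets)
        if not np.isfinite(self.step) or self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step!r}")

    def __len__(self) -> int:
        return len(self.offsets)

    @classmethod
    def unit_cell(cls, cfg: OpticalConfig, n_per_axis: int) -> "ScanPattern":
        """n x n raster covering one lenslet unit cell; step = pitch / n.

        The step divides the pitch exactly, which is what makes the mean
        excitation over the full pattern spatially uniform.
        """
        if n_per_axis < 1:
            raise ValueError("n_per_axis must be >= 1")
        pitch, _ = sample_plane_geometry(cfg)
        step = pitch / n_per_axis
        ij = np.arange(n_per_axis) * step
        dx, dy = np.meshgrid(ij, ij, indexing="xy")
        return cls(np.column_stack([dx.ravel(), dy.ravel()]), step)

    @classmethod
    def line_sweep(
        cls,
        cfg: OpticalConfig,
        n_per_pitch: int,
        n_pitches: int = 1,
        axis: str = "y",
    ) -> "ScanPattern":
        """One-dimensional sweep along one axis, the analog scan-mirror mode.

        Covers ``n_pitches`` lenslet pitches in steps of ``pitch /
        n_per_pitch``.  With an unrotated grid the transverse direction is
        never filled in, which is what produces periodic scan-line (stripe)
        artifacts; combine with ``cfg.grid_rotation_deg`` to let successive
        lenslet rows cover the gaps.
        """
        if axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        if n_per_pitch < 1 or n_pitches < 1:
            raise ValueError("n_per_pitch and n_pitches must be >= 1")
        pitch, _ = sample_plane_geometry(cfg)
        step = pitch / n_per_pitch
        t = np.arange(n_per_pitch * n_pitches) * step
        zeros = np.zeros_like(t)
        offsets = np.column_stack([t, zeros] if axis == "x" else [zeros, t])
        return cls(offsets, step)

    @classmethod
    def raster(cls, extent: float, step: float) -> "ScanPattern":
        """Square raster of offsets in [-extent, extent] x [-extent, extent]."""
        if step <= 0 or extent < 0:
            raise ValueError("extent must be >= 0 and step > 0")
        n = int(math.floor(extent / step))
        t = np.arange(-n, n + 1) * step
        dx, dy = np.meshgrid(t, t, indexing="xy")
        return cls(np.column_stack([dx.ravel(), dy.ravel()]), step)


@dataclass
class FrameStack:
    """Descanned, co-registered raw frames plus their scan offsets."""

    frames: list
    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.atleast_2d(np.asarray(self.offsets, dtype=float))
        if len(self.frames) == 0:
            raise ValueError("FrameStack needs at least one frame")
        if len(self.frames) != len(self.offsets):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.offsets)} offsets"
            )
        first = self.frames[0]
        for fr in self.frames[1:]:
            if fr.shape != first.shape or fr.pixel_pitch_xy != first.pixel_pitch_xy:
                raise ValueError("all frames must share shape and pixel pitch")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def pixel_pitch_xy(self) -> float:
        return self.frames[0].pixel_pitch_xy

    @property
    def frame_shape(self) -> tuple[int, ...]:
        return self.frames[0].shape


@dataclass(frozen=True)
class NoiseSpec:
    """Shot + read noise model: Poisson(photon_scale * I) + N(0, read_sigma)."""

    photon_scale: float = 1.0
    read_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale < 0:
            raise ValueError("photon_scale must be >= 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")


# ---------------------------------------------------------------------------
# geometry helpers


def _centre_index(n: int) -> int:
    return (n - 1) // 2


def _pixel_coords(n: int, pitch: float) -> np.ndarray:
    """Pixel-centre coordinates [nm], origin at the centre voxel."""
    return (np.arange(n) - _centre_index(n)) * pitch


def foci_lattice(
    cfg: OpticalConfig,
    shape: tuple[int, int],
    pitch_xy: float,
    offset: tuple[float, float] = (0.0, 0.0),
    margin: float = 0.0,
) -> np.ndarray:
    """Excitation focus positions (x, y) [nm] covering the field plus margin.

    The lattice is square with the sample-plane pitch, rotated by
    ``cfg.grid_rotation_deg`` about the grid centre, translated by the scan
    ``offset``, and anchored so that one focus sits at the grid centre at
    zero offset.
    """
    pitch, _ = sample_plane_geometry(cfg)
    ny, nx = shape[-2], shape[-1]
    half_x = max(abs(_pixel_coords(nx, pitch_xy)[0]), abs(_pixel_coords(nx, pitch_xy)[-1]))
    half_y = max(abs(_pixel_coords(ny, pitch_xy)[0]), abs(_pixel_coords(ny, pitch_xy)[-1]))
    reach = math.hypot(half_x + margin + abs(offset[0]), half_y + margin + abs(offset[1]))
    nmax = int(math.ceil(reach / pitch)) + 1
    idx = np.arange(-nmax, nmax + 1)
    ii, jj = np.meshgrid(idx, idx, indexing="xy")
    theta = math.radians(cfg.grid_rotation_deg)
    c, s = math.cos(theta), math.sin(theta)
    fx = (ii * c - jj * s) * pitch + offset[0]
    fy = (ii * s + jj * c) * pitch + offset[1]
    keep = (
        (fx >= -half_x - margin)
        & (fx <= half_x + margin)
        & (fy >= -half_y - margin)
        & (fy <= half_y + margin)
    )
    return np.column_stack([fx[keep], fy[keep]])


def excitation_field(
    cfg: OpticalConfig,
    shape: tuple[int, int],
    pitch_xy: float,
    offset: tuple[float, float] = (0.0, 0.0),
    exc_psf: PSFModel | None = None,
    periodic: bool = False,
) -> ImageVolume:
    """Multifocal excitation intensity pattern at one scan offset.

    A unit-peak Gaussian of the excitation PSF width is placed on every
    lattice focus; the field is their sum.  With ``periodic=True`` (axis
    aligned grids only) distances are wrapped on a torus whose period is
    the field extent, which makes the total intensity exactly independent
    of the scan offset when the extent is a multiple of the pitch.
    """
    pitch, _ = sample_plane_geometry(cfg)
    if pitch <= 2 * pitch_xy:
        raise ValueError(
            f"foci pitch {pitch:.1f} nm must exceed two pixels ({2 * pitch_xy:.1f} nm)"
        )
    sigma = (exc_psf or cfg.psf_model("exc")).sigma_lateral
    ny, nx = shape
    x = _pixel_coords(nx, pitch_xy)
    y = _pixel_coords(ny, pitch_xy)
    if periodic:
        if cfg.grid_rotation_deg != 0.0:
            raise ValueError("periodic excitation requires an unrotated grid")
        wx, wy = nx * pitch_xy, ny * pitch_xy
        for width in (wx, wy):
            k = width / pitch
            if abs(k - round(k)) > 1e-6:
                raise ValueError(
                    "periodic excitation requires the field extent to be an "
                    f"integer number of foci pitches (extent {width:.1f} nm, "
                    f"pitch {pitch:.1f} nm)"
                )

        def comb(coords, width, off):
            # exactly one centre per lattice cell on the torus
            centres = np.arange(round(width / pitch)) * pitch + off
            d = coords[:, None] - centres[None, :]
            d = d - width * np.round(d / width)
            return np.exp(-(d**2) / (2 * sigma**2)).sum(axis=1)

        field_ = np.outer(comb(y, wy, offset[1]), comb(x, wx, offset[0]))
        return ImageVolume(field_, pitch_xy)
    data = np.zeros(shape, dtype=float)
    reach = 5.0 * sigma
    for fx, fy in foci_lattice(cfg, shape, pitch_xy, offset, margin=reach):
        gx = np.exp(-((x - fx) ** 2) / (2 * sigma**2))
        gy = np.exp(-((y - fy) ** 2) / (2 * sigma**2))
        data += np.outer(gy, gx)
    return ImageVolume(data, pitch_xy)


def pinhole_mask(
    cfg: OpticalConfig,
    shape: tuple[int, int],
    pitch_xy: float,
    offset: tuple[float, float] = (0.0, 0.0),
    radius: float | None = None,
) -> np.ndarray:
    """Binary detection mask: unit transmission inside each pinhole disk.

    Pinholes are centred on the (descanned) focus lattice at this scan
    offset; ``radius`` defaults to the physical pinhole radius referred to
    the sample plane and must stay below half the focus pitch so disks do
    not overlap.
    """
    pitch, r_phys = sample_plane_geometry(cfg)
    r = r_phys if radius is None else float(radius)
    if r <= 0:
        raise ValueError("pinhole radius must be positive")
    if r >= pitch / 2:
        raise ValueError(
            f"pinhole radius {r:.1f} nm >= half the foci pitch {pitch / 2:.1f} nm: "
            "pinholes would overlap"
        )
    ny, nx = shape
    x = _pixel_coords(nx, pitch_xy)
    y = _pixel_coords(ny, pitch_xy)
    mask = np.zeros(shape, dtype=float)
    for fx, fy in foci_lattice(cfg, shape, pitch_xy, offset, margin=r):
        jx = np.nonzero(np.abs(x - fx) <= r)[0]
        jy = np.nonzero(np.abs(y - fy) <= r)[0]
        if jx.size == 0 or jy.size == 0:
            continue
        d2 = np.add.outer((y[jy] - fy) ** 2, (x[jx] - fx) ** 2)
        sub = mask[np.ix_(jy, jx)]
        sub[d2 <= r**2] = 1.0
        mask[np.ix_(jy, jx)] = sub
    return mask


def reassign_frame(
    frame: np.ndarray,
    cfg: OpticalConfig,
    pitch_xy: float,
    offset: tuple[float, float],
    scale: float,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Pixel-reassign one 2D frame: move flux toward the nearest focus.

    Every camera pixel's intensity is relocated from x to
    ``f + scale * (x - f)`` where f is that pixel's nearest excitation
    focus at this scan offset, and deposited with bilinear weights
    (flux-preserving scatter).  ``scale = 0.5`` is the half-displacement
    reassignment; ``scale = 1`` leaves the frame unchanged.

    This single kernel serves both the analog forward model (which uses
    ``scale = 1 / contraction_factor``) and the digital reconstruction, so
    the two agree to floating-point precision.
    """
    if not (0.0 <= scale <= 1.0):
        raise ValueError(f"scale must lie in [0, 1], got {scale!r}")
    frame = np.asarray(frame, dtype=float)
    ny, nx = frame.shape
    if out is None:
        out = np.zeros_like(frame)
    iy, ix = np.nonzero(frame)
    if iy.size == 0:
        return out
    vals = frame[iy, ix]
    pitch, _ = sample_plane_geometry(cfg)
    cx, cy = _centre_index(nx), _centre_index(ny)
    x = (ix - cx) * pitch_xy
    y = (iy - cy) * pitch_xy
    theta = math.radians(cfg.grid_rotation_deg)
    ct, st = math.cos(theta), math.sin(theta)
    u = x - offset[0]
    v = y - offset[1]
    i = np.round((u * ct + v * st) / pitch)
    j = np.round((-u * st + v * ct) / pitch)
    fx = (i * ct - j * st) * pitch + offset[0]
    fy = (i * st + j * ct) * pitch + offset[1]
    dx = (fx + scale * (x - fx)) / pitch_xy + cx
    dy = (fy + scale * (y - fy)) / pitch_xy + cy
    j0 = np.floor(dx).astype(int)
    i0 = np.floor(dy).astype(int)
    wx = dx - j0
    wy = dy - i0
    for di, dj, w in (
        (0, 0, (1 - wy) * (1 - wx)),
        (0, 1, (1 - wy) * wx),
        (1, 0, wy * (1 - wx)),
        (1, 1, wy * wx),
    ):
        ii = i0 + di
        jj = j0 + dj
        ok = (ii >= 0) & (ii < ny) & (jj >= 0) & (jj < nx) & (w > 0)
        np.add.at(out, (ii[ok], jj[ok]), vals[ok] * w[ok])
    return out


# ---------------------------------------------------------------------------
# image formation


def _em_kernel_2d(sigma: float, pitch_xy: float) -> np.ndarray:
    half = max(1, int(math.ceil(4.0 * sigma / pitch_xy)))
    n = 2 * half + 1
    return render_psf(PSFModel(sigma_lateral=sigma), (n, n), pitch_xy).data


def _axial_weights(sigma_z: float, pitch_z: float) -> np.ndarray:
    half = max(1, int(math.ceil(4.0 * sigma_z / pitch_z)))
    z = np.arange(-half, half + 1) * pitch_z
    w = np.exp(-(z**2) / (2 * sigma_z**2))
    return w / w.sum()


def _axial_collapse(data3d: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Correlate along z with a normalised axial kernel (zero padded)."""
    from scipy.ndimage import correlate1d

    return correlate1d(data3d, weights, axis=0, mode="constant", cval=0.0)


def simulate_widefield(
    sample: ImageVolume,
    cfg: OpticalConfig,
    em_psf: PSFModel | None = None,
) -> ImageVolume:
    """Widefield image: uniform excitation, emission-PSF blur.

    Flux-preserving for structures supported away from the field edges.
    """
    em = em_psf or cfg.psf_model("em", axial=sample.is_3d)
    kern = _em_kernel_2d(em.sigma_lateral, sample.pixel_pitch_xy)
    if not sample.is_3d:
        return sample.with_data(_nonneg(fftconvolve(sample.data, kern, mode="same")))
    if em.sigma_axial is None:
        raise ValueError("3D widefield requires an emission PSF with sigma_axial")
    wz = _axial_weights(em.sigma_axial, sample.pixel_pitch_z)
    blurred_z = _axial_collapse(sample.data, wz)
    out = np.stack([fftconvolve(sl, kern, mode="same") for sl in blurred_z])
    return sample.with_data(_nonneg(out))


def _nonneg(a: np.ndarray) -> np.ndarray:
    # FFT convolution of non-negative arrays; clip the ~1e-16 ringing.
    return np.clip(a, 0.0, None)


def raw_frame(
    sample: ImageVolume,
    cfg: OpticalConfig,
    offset: tuple[float, float] = (0.0, 0.0),
    exc_psf: PSFModel | None = None,
    em_psf: PSFModel | None = None,
    apply_pinhole: bool = True,
    pinhole_radius: float | None = None,
) -> ImageVolume:
    """One descanned multifocal frame at a single scan offset.

    ``(sample x excitation field) conv emission PSF``, then multiplied by
    the pinhole mask centred on the focus lattice at this offset.  For 3D
    samples each detection plane first collapses the sample along z with
    the product of the axial excitation and emission profiles.
    """
    exc = exc_psf or cfg.psf_model("exc", axial=sample.is_3d)
    em = em_psf or cfg.psf_model("em", axial=sample.is_3d)
    shape2d = (sample.shape[-2], sample.shape[-1])
    field_ = excitation_field(cfg, shape2d, sample.pixel_pitch_xy, offset, exc_psf=exc).data
    kern = _em_kernel_2d(em.sigma_lateral, sample.pixel_pitch_xy)
    mask = (
        pinhole_mask(cfg, shape2d, sample.pixel_pitch_xy, offset, radius=pinhole_radius)
        if apply_pinhole
        else None
    )

    def form(sl2d: np.ndarray) -> np.ndarray:
        img = _nonneg(fftconvolve(sl2d * field_, kern, mode="same"))
        return img * mask if mask is not None else img

    if not sample.is_3d:
        return sample.with_data(form(sample.data))
    if exc.sigma_axial is None or em.sigma_axial is None:
        raise ValueError("3D imaging requires axial widths on both PSFs")
    wz_em = _axial_weights(em.sigma_axial, sample.pixel_pitch_z)
    z = (np.arange(len(wz_em)) - len(wz_em) // 2) * sample.pixel_pitch_z
    wz = wz_em * np.exp(-(z**2) / (2 * exc.sigma_axial**2))
    collapsed = _axial_collapse(sample.data, wz)
    return sample.with_data(np.stack([form(sl) for sl in collapsed]))


def simulate_msim_stack(
    sample: ImageVolume,
    cfg: OpticalConfig,
    pattern: ScanPattern,
    exc_psf: PSFModel | None = None,
    em_psf: PSFModel | None = None,
    apply_pinhole: bool = True,
    pinhole_radius: float | None = None,
) -> FrameStack:
    """Acquire one raw frame per scan offset (MSIM acquisition)."""
    frames = [
        raw_frame(
            sample,
            cfg,
            tuple(off),
            exc_psf=exc_psf,
            em_psf=em_psf,
            apply_pinhole=apply_pinhole,
            pinhole_radius=pinhole_radius,
        )
        for off in pattern.offsets
    ]
    return FrameStack(frames, pattern.offsets.copy())


def simulate_isim(
    sample: ImageVolume,
    cfg: OpticalConfig,
    pattern: ScanPattern,
    exc_psf: PSFModel | None = None,
    em_psf: PSFModel | None = None,
    pinhole_radius: float | None = None,
) -> ImageVolume:
    """Analog single-exposure iSIM image.

    For every scan offset the pinholed frame is contracted about each focus
    by ``cfg.contraction_factor`` and accumulated on the camera.  Equals
    the digital reconstruction of the corresponding frame stack at
    ``scale = 1 / contraction_factor`` to floating-point precision.
    """
    scale = 1.0 / cfg.contraction_factor
    out = None
    for off in pattern.offsets:
        fr = raw_frame(
            sample, cfg, tuple(off), exc_psf=exc_psf, em_psf=em_psf,
            apply_pinhole=True, pinhole_radius=pinhole_radius,
        )
        if out is None:
            out = np.zeros_like(fr.data)
        if fr.data.ndim == 2:
            reassign_frame(fr.data, cfg, sample.pixel_pitch_xy, tuple(off), scale, out=out)
        else:
            for k in range(fr.data.shape[0]):
                reassign_frame(
                    fr.data[k], cfg, sample.pixel_pitch_xy, tuple(off), scale, out=out[k]
                )
    return sample.with_data(out)


def add_noise(image: ImageVolume, noise: NoiseSpec) -> ImageVolume:
    """Apply shot and read noise; deterministic given ``noise.seed``."""
    if np.any(image.data < 0):
        raise ValueError("noise model requires a non-negative image")
    rng = np.random.default_rng(noise.seed)
    counts = rng.poisson(noise.photon_scale * image.data).astype(float)
    if noise.read_sigma > 0:
        counts += rng.normal(0.0, noise.read_sigma, size=image.shape)
    return image.with_data(np.clip(counts, 0.0, None))
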