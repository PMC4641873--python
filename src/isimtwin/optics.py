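"""Instrument parameterisation and Gaussian PSF models.

The instant structured illumination microscope (iSIM) is described here by a
small set of physical parameters: the excitation/emission wavelengths, the
objective NA, the tube/objective focal lengths (whose ratio is the system
magnification), the lenslet/pinhole array geometry in the intermediate image
plane, and the camera sampling at the specimen.  All derived geometry
(multifocal pitch and pinhole radius referred to the sample plane) follows
from these.

Conventions
-----------
* Every length handled internally is in **nanometres**; configuration fields
  keep the units in which an instrument builder would quote them (focal
  lengths in mm, array pitches in um, sampling in nm) and are converted at
  the boundary.
* PSFs are Gaussian.  The width convention is FWHM = 2*sqrt(2*ln 2) * sigma,
  matching the Gaussian-fit protocol used for all resolution measurements.
* 2D arrays are indexed (y, x); 3D arrays (z, y, x).  Physical coordinates
  place the origin at the geometric centre of the grid, with voxel *i* along
  an axis of length *n* centred at ``(i - (n - 1) / 2) * pitch``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "FWHM_PER_SIGMA",
    "OpticalConfig",
    "PSFModel",
    "ImageVolume",
    "sigma_from_fwhm",
    "fwhm_from_sigma",
    "system_magnification",
    "sample_plane_geometry",
    "render_psf",
]

#: FWHM of a Gaussian in units of its standard deviation: 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def sigma_from_fwhm(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its standard deviation.

    Parameters
    ----------
    fwhm : float
        Full width at half maximum, in any length unit; must be positive.

    Returns
    -------
    float
        ``fwhm / (2 * sqrt(2 * ln 2))`` in the same unit.
    """
    if not np.isfinite(fwhm) or fwhm <= 0:
        raise ValueError(f"FWHM must be positive and finite, got {fwhm!r}")
    return fwhm / FWHM_PER_SIGMA


def fwhm_from_sigma(sigma: float) -> float:
    """Inverse of :func:`sigma_from_fwhm`."""
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"sigma must be positive and finite, got {sigma!r}")
    return sigma * FWHM_PER_SIGMA


@dataclass(frozen=True)
class OpticalConfig:
    """Physical parameters of the multifocal microscope.

    Defaults describe the instrument this package models: a 1.49 NA
    objective (f = 3 mm) with an f = 350 mm tube lens, a square lenslet
    grid of 222 um pitch with a matched array of 40 um pinholes in the
    intermediate image plane, 2x contraction of each pinholed emission
    spot, and 56.0 nm camera sampling at the specimen.

    Attributes
    ----------
    numerical_aperture : float
        Objective NA, in (0, 1.7].
    lambda_exc, lambda_em : float
        Excitation / emission wavelengths [nm].
    f_objective, f_tube : float
        Objective and tube-lens focal lengths [mm]; magnification is
        ``f_tube / f_objective`` and must exceed 1.
    lenslet_pitch : float
        Pitch of the square excitation lenslet grid in the intermediate
        image plane [um].
    pinhole_diameter : float
        Pinhole diameter in the intermediate image plane [um].
    contraction_factor : float
        Factor by which each pinholed emission spot is contracted about its
        focus before summation on the camera (>= 1; 2 gives the standard
        half-displacement pixel reassignment).
    sample_pixel_pitch : float
        Lateral camera sampling referred to the specimen [nm].  The as-built
        value 56.0 nm is the default; the design value is
        :data:`DESIGN_PIXEL_PITCH`.
    z_step : float
        Axial step between slices of a z-stack [um].
    grid_rotation_deg : float
        Rotation of the lenslet grid about the optical axis relative to the
        scan axes [deg].  Zero for 2D unit-cell scanning; a small angle is
        used with one-dimensional sweeps so successive lenslet rows fill in
        the transverse direction.
    """

    numerical_aperture: float = 1.49
    lambda_exc: float = 488.0
    lambda_em: float = 525.0
    f_objective: float = 3.0
    f_tube: float = 350.0
    lenslet_pitch: float = 222.0
    pinhole_diameter: float = 40.0
    contraction_factor: float = 2.0
    sample_pixel_pitch: float = 56.0
    z_step: float = 0.25
    grid_rotation_deg: float = 0.0

    #: Nominal design sampling [nm]; the measured as-built value (56.0) is
    #: the default for `sample_pixel_pitch`.
    DESIGN_PIXEL_PITCH = 55.5

    def __post_init__(self) -> None:
        positive = {
            "lambda_exc": self.lambda_exc,
            "lambda_em": self.lambda_em,
            "f_objective": self.f_objective,
            "f_tube": self.f_tube,
            "lenslet_pitch": self.lenslet_pitch,
            "pinhole_diameter": self.pinhole_diameter,
            "sample_pixel_pitch": self.sample_pixel_pitch,
            "z_step": self.z_step,
        }
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not (0 < self.numerical_aperture <= 1.7):
            raise ValueError(
                f"numerical_aperture must lie in (0, 1.7], got {self.numerical_aperture!r}"
            )
        if self.contraction_factor < 1:
            raise ValueError(
                f"contraction_factor must be >= 1, got {self.contraction_factor!r}"
            )
        m = self.f_tube / self.f_objective
        if not np.isfinite(m) or m <= 1:
            raise ValueError(f"magnification f_tube/f_objective must be > 1, got {m!r}")

    # -- derived geometry ---------------------------------------------------

    @property
    def magnification(self) -> float:
        return system_magnification(self)

    @property
    def foci_pitch(self) -> float:
        """Pitch of the excitation focus grid at the sample plane [nm]."""
        return sample_plane_geometry(self)[0]

    @property
    def pinhole_radius(self) -> float:
        """Pinhole radius referred to the sample plane [nm]."""
        return sample_plane_geometry(self)[1]

    # -- default PSF widths -------------------------------------------------
    # The widefield lateral FWHM ~ 0.51 lambda / NA and the axial FWHM
    # ~ 1.77 n lambda / NA^2 (n = 1.515 immersion) are documented
    # conveniences for building Gaussian PSF models; any measured width may
    # be substituted.

    def widefield_fwhm_lateral(self, wavelength: float | None = None) -> float:
        lam = self.lambda_em if wavelength is None else wavelength
        return 0.51 * lam / self.numerical_aperture

    def widefield_fwhm_axial(self, wavelength: float | None = None) -> float:
        lam = self.lambda_em if wavelength is None else wavelength
        return 1.77 * 1.515 * lam / self.numerical_aperture**2

    def psf_model(self, channel: str = "em", axial: bool = False) -> "PSFModel":
        """Default Gaussian PSF model for the ``"exc"`` or ``"em"`` channel."""
        if channel not in ("exc", "em"):
            raise ValueError(f"channel must be 'exc' or 'em', got {channel!r}")
        lam = self.lambda_exc if channel == "exc" else self.lambda_em
        return PSFModel(
            sigma_lateral=sigma_from_fwhm(self.widefield_fwhm_lateral(lam)),
            sigma_axial=sigma_from_fwhm(self.widefield_fwhm_axial(lam)) if axial else None,
        )

    # -- flat key=value serialisation ----------------------------------------

    def to_file(self, path) -> None:
        """Write the configuration as flat ``key = value`` text."""
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in fields(self)]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "OpticalConfig":
        kwargs = {}
        names = {f.name for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in names:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                kwargs[key] = float(value)
        return cls(**kwargs)

    @classmethod
    def from_mapping(cls, mapping) -> "OpticalConfig":
        names = {f.name for f in fields(cls)}
        unknown = set(mapping) - names
        if unknown:
            raise ValueError(f"unknown optics keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def replace(self, **kwargs) -> "OpticalConfig":
        return replace(self, **kwargs)


def system_magnification(cfg: OpticalConfig) -> float:
    """Lateral magnification from sample to intermediate image plane."""
    if cfg.f_objective <= 0 or cfg.f_tube <= 0:
        raise ValueError("focal lengths must be strictly positive")
    return cfg.f_tube / cfg.f_objective


def sample_plane_geometry(cfg: OpticalConfig) -> tuple[float, float]:
    """Excitation-focus pitch and pinhole radius referred to the sample.

    Returns
    -------
    (foci_pitch, pinhole_radius) : tuple of float
        Both in nanometres: ``lenslet_pitch / M`` and
        ``(pinhole_diameter / 2) / M`` with M the system magnification.
    """
    m = system_magnification(cfg)
    foci_pitch = cfg.lenslet_pitch * 1e3 / m
    pinhole_radius = (cfg.pinhole_diameter * 1e3 / 2.0) / m
    return foci_pitch, pinhole_radius


@dataclass(frozen=True)
class PSFModel:
    """Gaussian point-spread-function model.

    ``sigma_axial`` may be omitted for purely 2D work.  Widths are standard
    deviations in nm; use :func:`sigma_from_fwhm` to build one from a
    measured FWHM.
    """

    sigma_lateral: float
    sigma_axial: float | None = None
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.kind != "gaussian":
            raise ValueError(f"only Gaussian PSF models are supported, got {self.kind!r}")
        if not np.isfinite(self.sigma_lateral) or self.sigma_lateral <= 0:
            raise ValueError(f"sigma_lateral must be positive, got {self.sigma_lateral!r}")
        if self.sigma_axial is not None and (
            not np.isfinite(self.sigma_axial) or self.sigma_axial <= 0
        ):
            raise ValueError(f"sigma_axial must be positive, got {self.sigma_axial!r}")

    @property
    def fwhm_lateral(self) -> float:
        return fwhm_from_sigma(self.sigma_lateral)

    @property
    def fwhm_axial(self) -> float | None:
        return None if self.sigma_axial is None else fwhm_from_sigma(self.sigma_axial)


@dataclass
class ImageVolume:
    """A 2D image or 3D stack of non-negative intensities with pixel pitch.

    This is the single image currency of the package: samples, raw frames,
    reconstructions and deconvolved stacks are all carried this way.
    """

    data: np.ndarray
    pixel_pitch_xy: float
    pixel_pitch_z: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"data must be 2D or 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("image contains negative intensities")
        if not np.isfinite(self.pixel_pitch_xy) or self.pixel_pitch_xy <= 0:
            raise ValueError(f"pixel_pitch_xy must be positive, got {self.pixel_pitch_xy!r}")
        if self.data.ndim == 3:
            if self.pixel_pitch_z is None:
                raise ValueError("3D volumes require pixel_pitch_z")
            if not np.isfinite(self.pixel_pitch_z) or self.pixel_pitch_z <= 0:
                raise ValueError(f"pixel_pitch_z must be positive, got {self.pixel_pitch_z!r}")

    @property
    def is_3d(self) -> bool:
        return self.data.ndim == 3

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """New volume sharing this one's pitches (and metadata copy)."""
        return ImageVolume(data, self.pixel_pitch_xy, self.pixel_pitch_z, dict(self.metadata))

    def total_flux(self) -> float:
        return float(self.data.sum())


def _axis_coords(n: int, pitch: float) -> np.ndarray:
    """Voxel-centre coordinates [nm] with origin at the grid centre."""
    return (np.arange(n) - (n - 1) / 2.0) * pitch


def render_psf(
    model: PSFModel,
    shape: tuple[int, ...],
    pitch_xy: float,
    pitch_z: float | None = None,
) -> ImageVolume:
    """Render a centred, unit-sum Gaussian PSF on an odd-sized grid.

    The Gaussian is sampled at voxel centres and renormalised so the
    rendered kernel sums to exactly 1.  An odd extent along every axis is
    required so a centre voxel exists.

    Parameters
    ----------
    model : PSFModel
        Widths in nm.  A 3D shape requires ``model.sigma_axial``.
    shape : tuple
        (ny, nx) or (nz, ny, nx), each entry odd.
    pitch_xy, pitch_z : float
        Voxel pitches in nm.
    """
    if len(shape) not in (2, 3):
        raise ValueError(f"shape must be 2D or 3D, got {shape!r}")
    if any(n <= 0 or n % 2 == 0 for n in shape):
        raise ValueError(f"all axes must have odd positive extent, got {shape!r}")
    if len(shape) == 3:
        if model.sigma_axial is None:
            raise ValueError("3D PSF requires sigma_axial")
        if pitch_z is None:
            raise ValueError("3D PSF requires pitch_z")

    def marginal(n: int, pitch: float, sigma: float) -> np.ndarray:
        x = _axis_coords(n, pitch)
        return np.exp(-(x**2) / (2.0 * sigma**2))

    ax = [marginal(shape[-2], pitch_xy, model.sigma_lateral),
          marginal(shape[-1], pitch_xy, model.sigma_lateral)]
    if len(shape) == 3:
        ax.insert(0, marginal(shape[0], pitch_z, model.sigma_axial))
    out = ax[0]
    for a in ax[1:]:
        out = np.multiply.outer(out, a)
    out /= out.sum()
    return ImageVolume(out, pitch_xy, pitch_z if len(shape) == 3 else None)
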