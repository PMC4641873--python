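"""Synthetic fluorophore density maps: beads, filaments, uniform layers.

These phantoms emulate the test specimens used to characterise a multifocal
microscope: point-like or micron-scale fluorescent beads, straight 25 nm-wide
filaments standing in for microtubules, and thin uniform fluorescent layers
used for illumination/flat-field checks.

Rendering is deliberately hard-edged: a voxel is inside a bead or filament
iff its centre satisfies the exact geometric membership test, with no
sub-voxel area weighting.  That keeps every generator bit-deterministic and
lets brute-force geometry oracles predict outputs exactly.

Coordinates are in nm with the origin at the *centre voxel* of the grid,
voxel index ``(n - 1) // 2`` along each axis.  (For even-sized grids this is
the voxel just below the geometric centre; anchoring features on a voxel
centre guarantees that sub-pixel-width structures still cover at least one
voxel.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .optics import ImageVolume

__all__ = ["SampleSpec", "make_beads", "make_filament", "make_uniform_layer", "random_bead_positions"]


@dataclass
class SampleSpec:
    """Parameters of a synthetic specimen.

    Attributes
    ----------
    kind : str
        One of ``"beads"``, ``"filament"``, ``"uniform_layer"``.
    positions : list of tuple
        Bead centres in nm relative to the grid centre voxel; (x, y) for 2D
        grids, (x, y, z) for 3D.
    bead_diameter : float
        Bead diameter [nm]; below one pixel pitch a bead renders as a single
        voxel.
    filament_width : float
        Top-hat cross-section width [nm]; default 25 nm, the width of a
        microtubule, i.e. sub-diffractive.
    filament_angle : float
        In-plane angle of the filament axis [deg]; 0 runs along +x.
    layer_thickness : float
        Uniform-layer thickness in z [nm] (ignored for 2D grids).
    intensity : float
        Photons per voxel at unit density.
    seed : int
        Seed for any randomised helper (e.g. random bead placement).
    """

    kind: str = "beads"
    positions: list = field(default_factory=lambda: [(0.0, 0.0)])
    bead_diameter: float = 0.0
    filament_width: float = 25.0
    filament_angle: float = 0.0
    layer_thickness: float = 0.0
    intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("beads", "filament", "uniform_layer"):
            raise ValueError(f"unknown sample kind {self.kind!r}")
        for name in ("bead_diameter", "filament_width", "layer_thickness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


def _centre_voxel_coords(n: int, pitch: float) -> np.ndarray:
    """Voxel-centre coordinates [nm], origin at voxel (n - 1) // 2."""
    return (np.arange(n) - (n - 1) // 2) * pitch


def _grid_coords(shape, pitch_xy, pitch_z):
    if len(shape) == 2:
        y = _centre_voxel_coords(shape[0], pitch_xy)
        x = _centre_voxel_coords(shape[1], pitch_xy)
        return None, y, x
    z = _centre_voxel_coords(shape[0], pitch_z)
    y = _centre_voxel_coords(shape[1], pitch_xy)
    x = _centre_voxel_coords(shape[2], pitch_xy)
    return z, y, x


def make_beads(
    spec: SampleSpec,
    shape: tuple[int, ...],
    pitch_xy: float,
    pitch_z: float | None = None,
) -> ImageVolume:
    """Render hard-sphere beads.

    Each bead fills every voxel whose centre lies within ``bead_diameter/2``
    of the bead centre; a bead smaller than one pitch renders as exactly the
    nearest voxel.  Total flux is therefore
    ``intensity * sum(voxel count per bead)``.
    """
    if len(shape) == 3 and pitch_z is None:
        raise ValueError("3D grid requires pitch_z")
    z, y, x = _grid_coords(shape, pitch_xy, pitch_z)
    data = np.zeros(shape, dtype=float)
    radius = spec.bead_diameter / 2.0
    for pos in spec.positions:
        pos = tuple(float(p) for p in pos)
        if len(shape) == 2:
            if len(pos) != 2:
                raise ValueError(f"2D grid needs (x, y) positions, got {pos!r}")
            px, py, pz = pos[0], pos[1], None
        else:
            if len(pos) != 3:
                raise ValueError(f"3D grid needs (x, y, z) positions, got {pos!r}")
            px, py, pz = pos
        if not (x[0] <= px <= x[-1]) or not (y[0] <= py <= y[-1]):
            raise ValueError(f"bead position {pos!r} lies outside the grid")
        if pz is not None and not (z[0] <= pz <= z[-1]):
            raise ValueError(f"bead position {pos!r} lies outside the grid")
        if radius < pitch_xy / 2.0:
            ix = int(np.argmin(np.abs(x - px)))
            iy = int(np.argmin(np.abs(y - py)))
            if len(shape) == 2:
                data[iy, ix] += spec.intensity
            else:
                iz = int(np.argmin(np.abs(z - pz)))
                data[iz, iy, ix] += spec.intensity
        else:
            if len(shape) == 2:
                d2 = np.add.outer((y - py) ** 2, (x - px) ** 2)
            else:
                d2 = (
                    ((z - pz) ** 2)[:, None, None]
                    + ((y - py) ** 2)[None, :, None]
                    + ((x - px) ** 2)[None, None, :]
                )
            data[d2 <= radius**2] += spec.intensity
    return ImageVolume(data, pitch_xy, pitch_z if len(shape) == 3 else None)


def make_filament(
    spec: SampleSpec,
    shape: tuple[int, ...],
    pitch_xy: float,
    pitch_z: float | None = None,
) -> ImageVolume:
    """Render a straight filament through the centre voxel.

    The filament axis lies in the xy-plane at ``filament_angle`` degrees
    from +x; its cross-section is a top-hat of ``filament_width`` nm.  In
    3D the filament occupies the central z-plane slab of the same top-hat
    width.
    """
    if spec.filament_width <= 0:
        raise ValueError("filament_width must be positive")
    if any(n <= 0 for n in shape):
        raise ValueError("grid must be non-empty")
    if len(shape) == 3 and pitch_z is None:
        raise ValueError("3D grid requires pitch_z")
    z, y, x = _grid_coords(shape, pitch_xy, pitch_z)
    theta = math.radians(spec.filament_angle)
    # perpendicular distance of each pixel centre to the line through the
    # origin with direction (cos t, sin t): |y cos t - x sin t|
    dist = np.abs(np.subtract.outer(y * math.cos(theta), x * math.sin(theta)))
    mask2d = dist <= spec.filament_width / 2.0
    if len(shape) == 2:
        data = np.where(mask2d, spec.intensity, 0.0)
        return ImageVolume(data, pitch_xy)
    zmask = np.abs(z) <= spec.filament_width / 2.0
    if not zmask.any():
        zmask[len(z) // 2] = True  # sub-pitch width: occupy the centre plane
    data = np.where(zmask[:, None, None] & mask2d[None, :, :], spec.intensity, 0.0)
    return ImageVolume(data, pitch_xy, pitch_z)


def make_uniform_layer(
    spec: SampleSpec,
    shape: tuple[int, ...],
    pitch_xy: float,
    pitch_z: float | None = None,
) -> ImageVolume:
    """Render a thin uniform fluorescent layer.

    2D grids are filled entirely; in 3D the layer is a slab of
    ``layer_thickness`` nm centred on the central z-plane (at least one
    plane is always filled).
    """
    if any(n <= 0 for n in shape):
        raise ValueError("grid must be non-empty")
    if len(shape) == 2:
        return ImageVolume(np.full(shape, spec.intensity, dtype=float), pitch_xy)
    if pitch_z is None:
        raise ValueError("3D grid requires pitch_z")
    z = _centre_voxel_coords(shape[0], pitch_z)
    zmask = np.abs(z) <= spec.layer_thickness / 2.0
    if not zmask.any():
        zmask[len(z) // 2] = True
    data = np.zeros(shape, dtype=float)
    data[zmask] = spec.intensity
    return ImageVolume(data, pitch_xy, pitch_z)


def random_bead_positions(
    n: int,
    extent_xy: float,
    seed: int,
    extent_z: float | None = None,
) -> list[tuple[float, ...]]:
    """Uniformly random bead centres inside +/- extent/2, deterministic in seed."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(-extent_xy / 2.0, extent_xy / 2.0, size=(n, 2))
    if extent_z is None:
        return [tuple(p) for p in xy]
    zc = rng.uniform(-extent_z / 2.0, extent_z / 2.0, size=(n, 1))
    return [tuple(p) for p in np.hstack([xy, zc])]


def make_sample(spec: SampleSpec, shape, pitch_xy, pitch_z=None) -> ImageVolume:
    """Dispatch on ``spec.kind``."""
    fn = {"beads": make_beads, "filament": make_filament, "uniform_layer": make_uniform_layer}
    return fn[spec.kind](spec, tuple(shape), pitch_xy, pitch_z)
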