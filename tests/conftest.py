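"""Shared simulation fixtures.

The heavy scenes are session-scoped so the whole suite simulates each one
once:

* ``bead bench`` — a single sub-diffractive bead under a single excitation
  focus with equal Gaussian excitation/emission PSFs (sigma = 100 nm),
  25 nm pixels, a 2D scan raster.  This is the scene on which the
  closed-form resolution anchors hold: the half-displacement raw image is
  exactly Gaussian with sigma/sqrt(2).
* ``grid scene`` — a multi-focus field at the instrument's real geometry
  (1902.9 nm focus pitch, 56 nm pixels) scanned over one lenslet unit
  cell, used for the analog/digital equivalence contract.
"""

import numpy as np
import pytest

import isimtwin as it

BENCH_SIGMA = 100.0  # nm, equal excitation and emission widths
BENCH_PITCH = 25.0  # nm per pixel
BENCH_SHAPE = (97, 97)
BENCH_PINHOLE_NM = 150.0  # physical pinhole radius at the sample
OPEN_PINHOLE_NM = 1000.0  # effectively open digital pinhole for scale scans


@pytest.fixture(scope="session")
def bench_cfg():
    # lenslet pitch 700 um -> 6000 nm focus pitch: one focus in the field
    return it.OpticalConfig(
        lenslet_pitch=700.0, pinhole_diameter=35.0, sample_pixel_pitch=BENCH_PITCH
    )


@pytest.fixture(scope="session")
def bench_psf():
    return it.PSFModel(sigma_lateral=BENCH_SIGMA)


@pytest.fixture(scope="session")
def bead_sample():
    spec = it.SampleSpec(kind="beads", positions=[(0.0, 0.0)])
    return it.make_beads(spec, BENCH_SHAPE, BENCH_PITCH)


@pytest.fixture(scope="session")
def bench_pattern():
    return it.ScanPattern.raster(500.0, 50.0)


@pytest.fixture(scope="session")
def bench_widefield(bead_sample, bench_cfg, bench_psf):
    return it.simulate_widefield(bead_sample, bench_cfg, em_psf=bench_psf)


@pytest.fixture(scope="session")
def bench_isim(bead_sample, bench_cfg, bench_pattern, bench_psf):
    return it.simulate_isim(
        bead_sample, bench_cfg, bench_pattern, exc_psf=bench_psf, em_psf=bench_psf
    )


@pytest.fixture(scope="session")
def bench_stack(bead_sample, bench_cfg, bench_pattern, bench_psf):
    return it.simulate_msim_stack(
        bead_sample, bench_cfg, bench_pattern, exc_psf=bench_psf, em_psf=bench_psf
    )


@pytest.fixture(scope="session")
def bench_stack_open(bead_sample, bench_cfg, bench_pattern, bench_psf):
    return it.simulate_msim_stack(
        bead_sample,
        bench_cfg,
        bench_pattern,
        exc_psf=bench_psf,
        em_psf=bench_psf,
        pinhole_radius=OPEN_PINHOLE_NM,
    )


# --- multi-focus grid scene -------------------------------------------------


@pytest.fixture(scope="session")
def grid_cfg():
    return it.OpticalConfig()  # 1902.9 nm pitch, 171.4 nm pinholes, 56 nm px


@pytest.fixture(scope="session")
def grid_pattern(grid_cfg):
    return it.ScanPattern.unit_cell(grid_cfg, 4)


@pytest.fixture(scope="session")
def grid_samples(grid_cfg):
    shape = (96, 96)
    px = grid_cfg.sample_pixel_pitch
    beads = it.make_beads(
        it.SampleSpec(kind="beads", positions=[(0.0, 0.0), (700.0, -400.0)]),
        shape,
        px,
    )
    filament = it.make_filament(
        it.SampleSpec(kind="filament", filament_width=25.0, filament_angle=30.0),
        shape,
        px,
    )
    layer = it.make_uniform_layer(it.SampleSpec(kind="uniform_layer"), shape, px)
    return {"beads": beads, "filament": filament, "uniform_layer": layer}
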