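"""Tests for the image-formation model (widefield, raw frames, analog iSIM)."""

import numpy as np
import pytest

import isimtwin as it
from isimtwin.forward import excitation_field, pinhole_mask, raw_frame


def _divisible_cfg(px=56.0, pitch_px=32):
    """Config whose foci pitch is an exact multiple of the pixel pitch."""
    pitch_nm = pitch_px * px
    m = 350.0 / 3.0
    return it.OpticalConfig(lenslet_pitch=pitch_nm * m / 1000.0, sample_pixel_pitch=px)


class TestExcitationField:
    def test_single_focus_equals_rendered_psf(self, bench_cfg, bench_psf):
        field = excitation_field(bench_cfg, (41, 41), 25.0, (0.0, 0.0), exc_psf=bench_psf)
        rendered = it.render_psf(bench_psf, (41, 41), 25.0)
        assert np.allclose(field.data / field.data.sum(), rendered.data, atol=1e-12)

    def test_pitch_below_sampling_limit_rejected(self):
        cfg = it.OpticalConfig(lenslet_pitch=10.0)  # 85.7 nm foci pitch
        with pytest.raises(ValueError, match="pitch"):
            excitation_field(cfg, (32, 32), 56.0)

    def test_integral_independent_of_offset_periodic_tiling(self):
        cfg = _divisible_cfg()
        pitch = cfg.foci_pitch
        totals = []
        for off in [(0.0, 0.0), (0.3 * pitch, 0.0), (0.71 * pitch, 0.11 * pitch)]:
            f = excitation_field(cfg, (128, 128), 56.0, off, exc_psf=it.PSFModel(100.0), periodic=True)
            totals.append(f.data.sum())
        totals = np.array(totals)
        assert np.ptp(totals) / totals.mean() < 1e-6

    def test_mean_over_unit_cell_is_uniform(self):
        # Riemann sum over the scan unit cell approximates the constant
        # integral of the Gaussian comb
        cfg = _divisible_cfg()
        pattern = it.ScanPattern.unit_cell(cfg, 16)
        psf = it.PSFModel(100.0)
        acc = np.zeros((128, 128))
        for off in pattern.offsets:
            acc += excitation_field(cfg, (128, 128), 56.0, tuple(off), exc_psf=psf, periodic=True).data
        acc /= len(pattern)
        assert np.ptp(acc) / acc.mean() < 1e-3


class TestWidefield:
    def test_delta_gives_emission_psf(self, bench_cfg, bench_psf):
        sample = it.make_beads(it.SampleSpec(positions=[(0.0, 0.0)]), (65, 65), 25.0)
        wf = it.simulate_widefield(sample, bench_cfg, em_psf=bench_psf)
        peak = np.unravel_index(np.argmax(wf.data), wf.data.shape)
        assert peak == (32, 32)
        assert wf.total_flux() == pytest.approx(1.0, rel=1e-9)  # flux conserved

    def test_linearity_for_two_displaced_deltas(self, bench_cfg, bench_psf):
        a = it.make_beads(it.SampleSpec(positions=[(-300.0, 0.0)]), (65, 65), 25.0)
        b = it.make_beads(it.SampleSpec(positions=[(400.0, 200.0)]), (65, 65), 25.0)
        ab = a.with_data(a.data + b.data)
        wa = it.simulate_widefield(a, bench_cfg, em_psf=bench_psf)
        wb = it.simulate_widefield(b, bench_cfg, em_psf=bench_psf)
        wab = it.simulate_widefield(ab, bench_cfg, em_psf=bench_psf)
        assert np.allclose(wab.data, wa.data + wb.data, atol=1e-12)

    def test_pitch_mismatch_not_an_issue_for_2d_but_3d_needs_axial(self, bench_cfg):
        sample = it.make_beads(
            it.SampleSpec(positions=[(0.0, 0.0, 0.0)]), (5, 17, 17), 56.0, pitch_z=250.0
        )
        with pytest.raises(ValueError, match="axial"):
            it.simulate_widefield(sample, bench_cfg, em_psf=it.PSFModel(100.0))


class TestRawFrame:
    def test_zero_sample_gives_zero_frame(self, bench_cfg, bench_psf):
        zero = it.ImageVolume(np.zeros((33, 33)), 25.0)
        frame = raw_frame(zero, bench_cfg, (0.0, 0.0), exc_psf=bench_psf, em_psf=bench_psf)
        assert np.all(frame.data == 0)

    def test_confocality_source_at_focus_beats_displaced(self, bench_cfg, bench_psf):
        pitch = bench_cfg.foci_pitch
        at_focus = it.make_beads(it.SampleSpec(positions=[(0.0, 0.0)]), (97, 97), 25.0)
        # half a pitch away laterally (still inside the grid)
        displaced = it.make_beads(it.SampleSpec(positions=[(pitch / 2 - 2000.0, 0.0)]), (97, 97), 25.0)
        f0 = raw_frame(at_focus, bench_cfg, (0.0, 0.0), exc_psf=bench_psf, em_psf=bench_psf)
        f1 = raw_frame(displaced, bench_cfg, (0.0, 0.0), exc_psf=bench_psf, em_psf=bench_psf)
        assert f0.data.sum() > f1.data.sum()
        peak = np.unravel_index(np.argmax(f0.data), f0.data.shape)
        assert peak == (48, 48)

    def test_frame_bounded_by_widefield_times_max_excitation(self, bench_cfg, bench_psf):
        sample = it.make_beads(
            it.SampleSpec(positions=[(-200.0, 100.0)], bead_diameter=300.0), (97, 97), 25.0
        )
        field = excitation_field(bench_cfg, (97, 97), 25.0, (0.0, 0.0), exc_psf=bench_psf)
        frame = raw_frame(sample, bench_cfg, (0.0, 0.0), exc_psf=bench_psf, em_psf=bench_psf)
        wf = it.simulate_widefield(sample, bench_cfg, em_psf=bench_psf)
        bound = wf.data * field.data.max()
        assert np.all(frame.data <= bound + 1e-12)

    def test_overlapping_pinholes_rejected(self):
        cfg = it.OpticalConfig(pinhole_diameter=250.0)  # radius > half pitch
        with pytest.raises(ValueError, match="overlap"):
            pinhole_mask(cfg, (64, 64), 56.0)


class TestMsimStack:
    def test_single_offset_stack_equals_raw_frame(self, bench_cfg, bench_psf, bead_sample):
        pattern = it.ScanPattern(np.array([[30.0, -40.0]]), step=30.0)
        stack = it.simulate_msim_stack(
            bead_sample, bench_cfg, pattern, exc_psf=bench_psf, em_psf=bench_psf
        )
        frame = raw_frame(bead_sample, bench_cfg, (30.0, -40.0), exc_psf=bench_psf, em_psf=bench_psf)
        assert len(stack) == 1
        assert np.array_equal(stack.frames[0].data, frame.data)

    def test_reversed_offsets_permute_frames(self, bench_cfg, bench_psf, bead_sample):
        offs = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
        fwd = it.simulate_msim_stack(
            bead_sample, bench_cfg, it.ScanPattern(offs, 50.0), exc_psf=bench_psf, em_psf=bench_psf
        )
        rev = it.simulate_msim_stack(
            bead_sample, bench_cfg, it.ScanPattern(offs[::-1], 50.0), exc_psf=bench_psf, em_psf=bench_psf
        )
        for a, b in zip(fwd.frames, rev.frames[::-1]):
            assert np.array_equal(a.data, b.data)

    def test_unmasked_frame_sum_equals_widefield_times_mean_excitation(self):
        # linearity: sum_k (S * E_k) conv h = (S * sum_k E_k) conv h, and the
        # unit-cell sum of excitations is uniform
        cfg = _divisible_cfg()
        psf = it.PSFModel(100.0)
        sample = it.make_beads(
            it.SampleSpec(positions=[(0.0, 0.0)], bead_diameter=500.0), (128, 128), 56.0
        )
        pattern = it.ScanPattern.unit_cell(cfg, 16)
        total = np.zeros((128, 128))
        mean_exc = np.zeros((128, 128))
        for off in pattern.offsets:
            fr = raw_frame(sample, cfg, tuple(off), exc_psf=psf, em_psf=psf, apply_pinhole=False)
            total += fr.data
            mean_exc += excitation_field(cfg, (128, 128), 56.0, tuple(off), exc_psf=psf, periodic=True).data
        wf = it.simulate_widefield(sample, cfg, em_psf=psf)
        expected = wf.data * mean_exc.mean()
        assert np.allclose(total, expected, atol=1e-6 * expected.max())

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            it.ScanPattern(np.zeros((0, 2)), 50.0)


class TestIsim:
    def test_zero_sample_gives_zero_image(self, bench_cfg, bench_psf):
        zero = it.ImageVolume(np.zeros((49, 49)), 25.0)
        pattern = it.ScanPattern.raster(100.0, 50.0)
        img = it.simulate_isim(zero, bench_cfg, pattern, exc_psf=bench_psf, em_psf=bench_psf)
        assert np.all(img.data == 0)

    def test_sqrt2_gain_on_gaussian_product_anchor(self, bench_widefield, bench_isim):
        # equal exc/em sigmas: the reassigned PSF is the product PSF,
        # sigma / sqrt(2)
        wf = it.lateral_fwhm(bench_widefield)
        raw = it.lateral_fwhm(bench_isim)
        assert wf.fwhm / raw.fwhm == pytest.approx(np.sqrt(2.0), rel=0.03)


class TestNoise:
    def test_zero_noise_gives_zero_image(self):
        img = it.ImageVolume(np.full((16, 16), 50.0), 56.0)
        out = it.add_noise(img, it.NoiseSpec(photon_scale=0.0, read_sigma=0.0, seed=1))
        assert np.all(out.data == 0)

    def test_same_seed_reproducible(self):
        img = it.ImageVolume(np.full((16, 16), 50.0), 56.0)
        spec = it.NoiseSpec(photon_scale=2.0, read_sigma=1.5, seed=7)
        a = it.add_noise(img, spec)
        b = it.add_noise(img, spec)
        assert np.array_equal(a.data, b.data)

    def test_mean_matches_expected_counts(self):
        # law of large numbers: 1000 draws of a constant-100 image
        img = it.ImageVolume(np.full((32, 32), 100.0), 56.0)
        scale = 5.0
        means = [
            it.add_noise(img, it.NoiseSpec(photon_scale=scale, seed=s)).data.mean()
            for s in range(1000)
        ]
        assert np.mean(means) == pytest.approx(100.0 * scale, rel=0.01)

    def test_negative_input_rejected(self):
        img = it.ImageVolume(np.ones((8, 8)), 56.0)
        img.data[0, 0] = -1.0  # mutate after construction-time validation
        with pytest.raises(ValueError):
            it.add_noise(img, it.NoiseSpec(seed=0))
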