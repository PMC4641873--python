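"""Tests for digital pixel reassignment and stripe correction."""

import numpy as np
import pytest

import isimtwin as it
from isimtwin.forward import raw_frame
from conftest import BENCH_PINHOLE_NM, OPEN_PINHOLE_NM


class TestDigitalTwin:
    """Central contract: analog iSIM == digital reconstruction at scale 0.5."""

    @pytest.mark.parametrize("kind", ["beads", "filament", "uniform_layer"])
    def test_analog_equals_digital_on_grid_scene(self, grid_cfg, grid_pattern, grid_samples, kind):
        sample = grid_samples[kind]
        analog = it.simulate_isim(sample, grid_cfg, grid_pattern)
        stack = it.simulate_msim_stack(sample, grid_cfg, grid_pattern)
        digital = it.digital_reconstruct(
            stack, grid_cfg, it.ReconSettings(pinhole_radius=grid_cfg.pinhole_radius, scale=0.5)
        )
        scale = max(analog.data.max(), 1e-300)
        assert np.abs(analog.data - digital.data).max() / scale < 1e-6

    def test_analog_equals_digital_on_bead_bench(self, bench_cfg, bench_isim, bench_stack):
        digital = it.digital_reconstruct(
            bench_stack, bench_cfg, it.ReconSettings(pinhole_radius=BENCH_PINHOLE_NM, scale=0.5)
        )
        assert np.abs(bench_isim.data - digital.data).max() / digital.data.max() < 1e-6


class TestDigitalReconstruct:
    def test_scale_one_open_pinhole_is_plain_frame_sum(self, bench_cfg, bench_stack_open):
        # the 2900 nm digital pinhole covers the whole (2.4 um) field: the
        # reassignment at scale 1 is the identity
        recon = it.digital_reconstruct(
            bench_stack_open, bench_cfg, it.ReconSettings(pinhole_radius=2900.0, scale=1.0)
        )
        plain = sum(f.data for f in bench_stack_open.frames)
        assert np.allclose(recon.data, plain, atol=1e-9 * plain.max())

    @pytest.mark.parametrize("scale", [0.3, 0.5, 1.0])
    def test_point_at_focus_is_fixed_point(self, bench_cfg, bench_psf, scale):
        sample = it.make_beads(it.SampleSpec(positions=[(0.0, 0.0)]), (97, 97), 25.0)
        frame = raw_frame(sample, bench_cfg, (0.0, 0.0), exc_psf=bench_psf, em_psf=bench_psf)
        stack = it.FrameStack([frame], np.array([[0.0, 0.0]]))
        recon = it.digital_reconstruct(
            stack, bench_cfg, it.ReconSettings(pinhole_radius=BENCH_PINHOLE_NM, scale=scale)
        )
        peak = np.unravel_index(np.argmax(recon.data), recon.data.shape)
        assert peak == (48, 48)

    def test_linearity_in_the_stack(self, bench_cfg, bench_psf):
        offs = np.array([[0.0, 0.0], [50.0, 50.0]])
        pattern = it.ScanPattern(offs, 50.0)
        a = it.make_beads(it.SampleSpec(positions=[(0.0, 0.0)]), (97, 97), 25.0)
        b = it.make_beads(it.SampleSpec(positions=[(200.0, -100.0)]), (97, 97), 25.0)
        settings = it.ReconSettings(pinhole_radius=BENCH_PINHOLE_NM, scale=0.5)

        def recon(sample):
            stack = it.simulate_msim_stack(sample, bench_cfg, pattern, exc_psf=bench_psf, em_psf=bench_psf)
            return it.digital_reconstruct(stack, bench_cfg, settings)

        ra, rb = recon(a), recon(b)
        rab = recon(a.with_data(a.data + b.data))
        assert np.allclose(rab.data, ra.data + rb.data, atol=1e-9 * rab.data.max())

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            it.ReconSettings(pinhole_radius=150.0, scale=0.0)
        with pytest.raises(ValueError):
            it.ReconSettings(pinhole_radius=150.0, scale=1.5)
        with pytest.raises(ValueError):
            it.ReconSettings(pinhole_radius=-10.0)

    def test_digital_pinhole_must_not_overlap(self, bench_cfg, bench_stack):
        settings = it.ReconSettings(pinhole_radius=bench_cfg.foci_pitch / 2 + 1, scale=0.5)
        with pytest.raises(ValueError, match="pinhole"):
            it.digital_reconstruct(bench_stack, bench_cfg, settings)

    def test_half_displacement_sharper_than_no_reassignment(self, bench_cfg, bench_stack):
        settings = lambda s: it.ReconSettings(pinhole_radius=BENCH_PINHOLE_NM, scale=s)
        f_half = it.lateral_fwhm(it.digital_reconstruct(bench_stack, bench_cfg, settings(0.5))).fwhm
        f_one = it.lateral_fwhm(it.digital_reconstruct(bench_stack, bench_cfg, settings(1.0))).fwhm
        assert f_half < f_one


class TestScaleScan:
    def test_optimum_at_half_displacement(self, bench_cfg, bench_stack_open):
        scales = np.round(np.arange(0.2, 0.81, 0.1), 2)
        rows, best = it.scan_scale_factors(
            bench_stack_open, bench_cfg, scales, pinhole_radius=OPEN_PINHOLE_NM
        )
        assert best == pytest.approx(0.5, abs=0.05)

    def test_table_is_unimodal(self, bench_cfg, bench_stack_open):
        scales = np.round(np.arange(0.1, 1.001, 0.1), 2)
        rows, best = it.scan_scale_factors(
            bench_stack_open, bench_cfg, scales, pinhole_radius=OPEN_PINHOLE_NM
        )
        fwhms = np.array([f for _, f in rows])
        sign_changes = np.count_nonzero(np.diff(np.sign(np.diff(fwhms))))
        assert sign_changes <= 1  # falls, then rises

    def test_scale_one_recovers_widefield_width(self, bench_cfg, bench_stack_open, bench_widefield):
        rows, _ = it.scan_scale_factors(
            bench_stack_open, bench_cfg, [1.0], pinhole_radius=OPEN_PINHOLE_NM
        )
        wf = it.lateral_fwhm(bench_widefield).fwhm
        assert rows[0][1] == pytest.approx(wf, rel=0.03)


class TestStripeCorrection:
    @staticmethod
    def _striped(amplitude=0.5, shape=(64, 64), period=8):
        rows = 1.0 + amplitude * np.sin(2 * np.pi * np.arange(shape[0]) / period)
        return it.ImageVolume(np.outer(rows, np.ones(shape[1])) * 100.0, 56.0)

    def test_flatfield_constant_reference_is_identity(self):
        img = self._striped()
        ref = it.ImageVolume(np.full(img.shape, 7.0), 56.0)
        out = it.flatfield_correct(img, ref)
        assert np.allclose(out.data, img.data)

    def test_flatfield_self_reference_is_constant(self):
        img = self._striped()
        out = it.flatfield_correct(img, img)
        assert np.ptp(out.data) < 1e-9 * out.data.mean()

    def test_flatfield_reduces_stripe_metric_tenfold(self):
        img = self._striped(amplitude=0.5)
        ref = self._striped(amplitude=0.5)  # same stripes, flat specimen
        before = it.stripe_metric(img, axis=0)
        after = it.stripe_metric(it.flatfield_correct(img, ref), axis=0)
        assert before / max(after, 1e-300) >= 10.0

    def test_flatfield_zero_reference_under_signal_rejected(self):
        img = it.ImageVolume(np.ones((8, 8)), 56.0)
        ref = it.ImageVolume(np.zeros((8, 8)), 56.0)
        with pytest.raises(ValueError):
            it.flatfield_correct(img, ref)

    def test_linebin_uniform_unchanged(self):
        img = it.ImageVolume(np.full((32, 32), 5.0), 56.0)
        out = it.linebin_correct(img, bin_height=1)
        assert np.allclose(out.data, img.data)

    def test_linebin_alternating_rows_flattened(self):
        data = np.empty((32, 16))
        data[0::2] = 3.0
        data[1::2] = 7.0
        img = it.ImageVolume(data, 56.0)
        out = it.linebin_correct(img, bin_height=1)
        assert np.ptp(out.data) < 1e-12
        assert out.data.mean() == pytest.approx(data.mean(), rel=1e-9)

    def test_linebin_reduces_stripe_metric_tenfold(self):
        img = self._striped(amplitude=0.4)
        out = it.linebin_correct(img, bin_height=1)
        assert it.stripe_metric(img) / max(it.stripe_metric(out), 1e-300) >= 10.0


@pytest.fixture(scope="module")
def sweep_cfg():
    # foci pitch = 32 px exactly, 96 px field = 3 pitches
    m = 350.0 / 3.0
    return it.OpticalConfig(lenslet_pitch=32 * 56.0 * m / 1000.0, sample_pixel_pitch=56.0)


class TestScanLineArtifact:
    """A 1D sweep of a uniform layer leaves periodic residual stripes."""

    def test_stripe_period_equals_foci_pitch(self, sweep_cfg):
        psf = it.PSFModel(100.0)
        layer = it.make_uniform_layer(it.SampleSpec(kind="uniform_layer"), (96, 96), 56.0)
        sweep = it.ScanPattern.line_sweep(sweep_cfg, 8, axis="x")
        img = it.simulate_isim(layer, sweep_cfg, sweep, exc_psf=psf, em_psf=psf)
        # sweeping x leaves row structure: horizontal stripes along y
        assert it.stripe_metric(img, axis=0) > 0.5
        assert it.stripe_period(img, axis=0) == pytest.approx(sweep_cfg.foci_pitch, rel=0.05)

    def test_grid_rotation_fills_the_transverse_axis(self, sweep_cfg):
        # the rotation-alignment design: staggering lenslet columns by
        # pitch/16 across a 16-pitch sweep turns dark bands into a shallow
        # ripple that line-binning removes
        import math

        psf = it.PSFModel(100.0)
        layer = it.make_uniform_layer(it.SampleSpec(kind="uniform_layer"), (96, 96), 56.0)
        square = it.simulate_isim(
            layer, sweep_cfg, it.ScanPattern.line_sweep(sweep_cfg, 16, axis="x"),
            exc_psf=psf, em_psf=psf,
        )
        rotated_cfg = sweep_cfg.replace(grid_rotation_deg=math.degrees(math.asin(1 / 16)))
        long_sweep = it.ScanPattern.line_sweep(sweep_cfg, 16, n_pitches=16, axis="x")
        rotated = it.simulate_isim(layer, rotated_cfg, long_sweep, exc_psf=psf, em_psf=psf)
        core = it.ImageVolume(rotated.data[8:-8, 8:-8], 56.0)
        m_square = it.stripe_metric(square, axis=0)
        m_rot = it.stripe_metric(core, axis=0)
        assert m_rot < 0.1 * m_square
        assert np.all(core.data > 0)  # no unswept rows remain
        corrected = it.linebin_correct(core, bin_height=1)
        assert it.stripe_metric(corrected, axis=0) < 0.1 * m_rot

    def test_full_2d_scan_has_no_stripes(self, sweep_cfg):
        # a fine 2D unit-cell scan fills the field in both axes; the 1D
        # sweep leaves the transverse comb structure behind
        psf = it.PSFModel(100.0)
        layer = it.make_uniform_layer(it.SampleSpec(kind="uniform_layer"), (96, 96), 56.0)
        sweep = it.ScanPattern.line_sweep(sweep_cfg, 16, axis="x")
        cell = it.ScanPattern.unit_cell(sweep_cfg, 16)
        img_1d = it.simulate_isim(layer, sweep_cfg, sweep, exc_psf=psf, em_psf=psf)
        img_2d = it.simulate_isim(layer, sweep_cfg, cell, exc_psf=psf, em_psf=psf)
        # interior rows only: edge roll-off is not a stripe
        core = lambda im: it.ImageVolume(im.data[16:-16, 16:-16], 56.0)
        assert it.stripe_metric(core(img_2d), axis=0) < 0.1 * it.stripe_metric(core(img_1d), axis=0)
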