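"""Reconstruction-stage contracts, with analytic and round-trip oracles."""

import dataclasses

import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from holophase import synthetic
from holophase.reconstruct import (
    CellExceedsROIError,
    DegenerateMaskError,
    Hologram,
    NoCarrierError,
    NoCellError,
    PhaseMap,
    ReconstructionParams,
    compensate_curvature,
    isolate_sideband,
    phase_to_opd,
    reconstruct,
    segment_and_crop,
    select_best_frame,
    unwrap_phase,
)

from conftest import centered_phantom


def itoh_unwrap(wrapped):
    """Independent row-column (Itoh) unwrap oracle for smooth fields."""
    out = np.array(wrapped, dtype=float)
    out[:, 0] = np.unwrap(out[:, 0])
    return np.unwrap(out, axis=1)


def make_hologram(phantom, cfg=None, holo_seed=0):
    if cfg is None:
        cfg = synthetic.OpticalConfig(noise_sigma=0.0)
    field = synthetic.render_phase_field(phantom, cfg.detector_shape)
    return synthetic.render_hologram(field, cfg, holo_seed), field


class TestIsolateSideband:
    def test_zero_phase_object_gives_constant_phase(self):
        # unquantized pure fringes: the spectrum is exactly three deltas
        cfg = synthetic.OpticalConfig(
            carrier_freq=(0.25, 0.25), noise_sigma=0.0, detector_shape=(256, 256)
        )
        intensity = synthetic.interference_intensity(np.zeros((256, 256)), cfg)
        field = isolate_sideband(Hologram(pixels=intensity))
        inner = np.angle(field)[32:-32, 32:-32]
        assert np.std(inner) < 1e-6

    def test_constant_image_has_no_carrier(self):
        holo = Hologram(pixels=np.full((128, 128), 7.0))
        with pytest.raises(NoCarrierError):
            isolate_sideband(holo)


class TestUnwrapPhase:
    def test_smooth_field_within_2pi_returned_up_to_constant(self, rng):
        yy, xx = np.mgrid[:100, :100] / 100.0
        true = 2.0 * np.sin(np.pi * yy) * np.sin(np.pi * xx)  # range < 2*pi
        wrapped = np.angle(np.exp(1j * true))
        out = unwrap_phase(wrapped)
        delta = out - true
        assert np.ptp(delta) < 1e-9

    def test_linear_ramp_recovered_exactly(self):
        """0 -> 6*pi ramp over 200 px: classic analytic unwrap oracle."""
        true = np.tile(np.linspace(0.0, 6 * np.pi, 200), (32, 1))
        wrapped = np.angle(np.exp(1j * true))
        out = unwrap_phase(wrapped)
        delta = out - true
        delta -= np.round(delta[0, 0] / (2 * np.pi)) * 2 * np.pi
        assert np.abs(delta).max() < 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_congruence_mod_2pi_for_arbitrary_input(self, seed):
        rng = np.random.default_rng(seed)
        wrapped = rng.uniform(-np.pi, np.pi, size=(64, 64))
        out = unwrap_phase(wrapped)
        cycles = (out - wrapped) / (2 * np.pi)
        assert np.abs(cycles - np.round(cycles)).max() < 1e-9

    def test_agrees_with_itoh_oracle_on_smooth_field(self):
        phantom = centered_phantom("MONO", 1, shape=(256, 256),
                                   texture_amplitude_rad=0.0)
        dome = synthetic.render_phase_field(phantom, (256, 256)).phase_rad
        yy, xx = np.mgrid[:256, :256]
        true = dome + 0.03 * xx + 0.02 * yy
        wrapped = np.angle(np.exp(1j * true))
        ours = unwrap_phase(wrapped)
        oracle = itoh_unwrap(wrapped)
        delta = ours - oracle
        delta -= np.round(delta.mean() / (2 * np.pi)) * 2 * np.pi
        assert np.abs(delta).max() < 1e-9

    def test_nonfinite_input_rejected(self):
        bad = np.zeros((64, 64))
        bad[3, 3] = np.nan
        with pytest.raises(ValueError):
            unwrap_phase(bad)


class TestCompensateCurvature:
    @staticmethod
    def quadratic_surface(shape, coeffs):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        y = yy / shape[0]
        x = xx / shape[1]
        a, b, c, d, e, f = coeffs
        return a + b * x + c * y + d * x**2 + e * x * y + f * y**2

    def test_exact_quadratic_removed_completely(self):
        surface = self.quadratic_surface((128, 128), (0.3, 1.2, -0.7, 2.0, 0.5, -1.1))
        residual = compensate_curvature(surface, np.ones((128, 128), dtype=bool))
        assert np.abs(residual).max() < 1e-8

    def test_dome_recovered_under_quadratic_background(self):
        phantom = centered_phantom("CD4", 2, shape=(256, 256),
                                   texture_amplitude_rad=0.0)
        dome = synthetic.render_phase_field(phantom, (256, 256)).phase_rad
        surface = self.quadratic_surface((256, 256), (0.5, -1.0, 2.0, 1.5, -0.8, 0.9))
        yy, xx = np.mgrid[:256, :256]
        r = np.hypot(yy - 127.5, xx - 127.5)
        annulus = r > phantom.radius_px + 5
        recovered = compensate_curvature(dome + surface, annulus)
        err = recovered - dome
        assert np.sqrt((err**2).mean()) < 0.02

    def test_zero_phase_stays_zero(self):
        residual = compensate_curvature(np.zeros((64, 64)), np.ones((64, 64), bool))
        assert np.abs(residual).max() < 1e-12

    def test_small_mask_rejected(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[:3] = True
        with pytest.raises(DegenerateMaskError, match="10%"):
            compensate_curvature(np.zeros((64, 64)), mask)

    def test_rank_deficient_mask_geometry_rejected(self):
        # two full rows: x^2 is a linear combination of 1 and x on two
        # distinct column... rows, so the quadratic design loses rank
        mask = np.zeros((20, 20), dtype=bool)
        mask[4] = True
        mask[15] = True
        with pytest.raises(DegenerateMaskError, match="rank"):
            compensate_curvature(np.zeros((20, 20)), mask)


class TestSegmentAndCrop:
    def test_centered_dome_crops_to_centered_roi(self):
        phantom = centered_phantom("MONO", 3, shape=(512, 512),
                                   texture_amplitude_rad=0.0)
        field = synthetic.render_phase_field(phantom, (512, 512))
        out = segment_and_crop(field, roi_size=220, floor_rad=0.0)
        assert out.phase_rad.shape == (220, 220)
        total = out.phase_rad.sum()
        rr, cc = np.mgrid[:220, :220]
        centroid = ((rr * out.phase_rad).sum() / total,
                    (cc * out.phase_rad).sum() / total)
        assert abs(centroid[0] - 109.5) <= 1.0 and abs(centroid[1] - 109.5) <= 1.0
        assert out.roi_origin == (146, 146)

    def test_empty_field_raises_no_cell(self):
        with pytest.raises(NoCellError):
            segment_and_crop(PhaseMap(np.zeros((512, 512))), 220, 0.0)

    def test_floor_zero_keeps_noiseless_signal_intact(self):
        phantom = centered_phantom("CD4", 1, shape=(512, 512),
                                   texture_amplitude_rad=0.0)
        field = synthetic.render_phase_field(phantom, (512, 512))
        out = segment_and_crop(field, roi_size=220, floor_rad=0.0)
        assert out.phase_rad.sum() == pytest.approx(field.phase_rad.sum())
        assert (out.phase_rad > 0).sum() == (field.phase_rad > 0).sum()

    def test_cell_larger_than_roi_rejected(self):
        phantom = centered_phantom("MONO", 0, shape=(512, 512), radius_px=115.0,
                                   texture_amplitude_rad=0.0)
        field = synthetic.render_phase_field(phantom, (512, 512))
        with pytest.raises(CellExceedsROIError):
            segment_and_crop(field, roi_size=220, floor_rad=0.0)


class TestReconstruct:
    def test_round_trip_integrated_phase_within_5_percent(self):
        phantom = centered_phantom("MONO", 7)
        holo, truth = make_hologram(phantom)
        pm = reconstruct(holo)
        r0, c0 = pm.roi_origin
        ref = truth.phase_rad[r0 : r0 + 220, c0 : c0 + 220]
        assert pm.phase_rad.sum() == pytest.approx(ref.sum(), rel=0.05)

    def test_zero_phase_hologram_never_fabricates_a_cell(self):
        """A hologram of an empty field must not come back as a
        believable cell: either a named no-cell/segmentation error, or a
        residual ROI whose mass is negligible next to any real cell
        (8-bit quantization leaves a structured sub-floor ripple, so the
        outcome depends on how it interacts with the noise floor)."""
        cfg = synthetic.OpticalConfig(noise_sigma=0.0)
        holo = synthetic.render_hologram(PhaseMap(np.zeros((512, 512))), cfg, 0)
        typical_cell = np.pi * 28**2 * 2.2 / 2  # CD4-like dome integral
        try:
            pm = reconstruct(holo)
        except (NoCellError, CellExceedsROIError):
            return
        assert pm.phase_rad.sum() < 0.01 * typical_cell

    def test_invariant_to_global_intensity_rescaling(self):
        phantom = centered_phantom("BCELL", 5)
        holo, _ = make_hologram(phantom)
        pm1 = reconstruct(holo)
        pm2 = reconstruct(Hologram(pixels=holo.pixels * 2.7,
                                   wavelength_m=holo.wavelength_m))
        assert pm1.roi_origin == pm2.roi_origin
        interior = binary_erosion(pm1.phase_rad > 0, iterations=2)
        diff = pm1.phase_rad - pm2.phase_rad
        assert np.sqrt((diff[interior] ** 2).mean()) < 0.02

    def test_phase_peak_2pi_maps_to_wavelength_opd(self):
        phantom = centered_phantom("MONO", 2, max_phase_rad=2 * np.pi,
                                   texture_amplitude_rad=0.0)
        holo, _ = make_hologram(phantom)
        pm = reconstruct(holo)
        opd = phase_to_opd(pm)
        assert opd.opd_m.max() == pytest.approx(532e-9, rel=0.02)


class TestPhaseToOPD:
    def test_half_wave_conversion(self):
        pm = PhaseMap(np.full((64, 64), np.pi), wavelength_m=532e-9)
        assert phase_to_opd(pm).opd_m[0, 0] == pytest.approx(266e-9)

    def test_zeros_preserved_and_linear(self):
        arr = np.zeros((64, 64))
        arr[10:20, 10:20] = 1.5
        pm = PhaseMap(arr, wavelength_m=532e-9)
        pm2 = PhaseMap(2 * arr, wavelength_m=532e-9)
        assert np.all(phase_to_opd(pm).opd_m[arr == 0] == 0.0)
        assert np.allclose(phase_to_opd(pm2).opd_m, 2 * phase_to_opd(pm).opd_m)

    def test_missing_wavelength_rejected(self):
        pm = PhaseMap(np.zeros((64, 64)), wavelength_m=None)
        with pytest.raises(ValueError, match="wavelength"):
            phase_to_opd(pm)


class TestSelectBestFrame:
    def test_picks_highest_modulation_frame_deterministically(self):
        phantom = centered_phantom("CD4", 1, shape=(256, 256))
        field = synthetic.render_phase_field(phantom, (256, 256))
        cfgs = [
            synthetic.OpticalConfig(reference_amplitude=a, noise_sigma=0.0,
                                    detector_shape=(256, 256))
            for a in (0.15, 1.0, 0.4)
        ]
        frames = [synthetic.render_hologram(field, cfg, 0) for cfg in cfgs]
        best = select_best_frame(frames)
        assert best == 1
        assert select_best_frame(frames) == best
        assert 0 <= best < len(frames)
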