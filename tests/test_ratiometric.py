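"""Ratiometric chain: each stage against constructed oracles, plus the
full-chain inversion of the synthetic generator."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from lamelloscope import synthetic as syn
from lamelloscope.core_io import BinaryMask, ChannelStack
from lamelloscope.ratiometric import (edge_body_ratio, make_cell_mask,
                                      ratio_map, ratiometric_movie,
                                      register_frames, shading_correct,
                                      subtract_background)


def _away_from_discontinuities(truth, margin_px=3.0):
    """Pixels at least margin_px inside a constant region of the true map."""
    band = truth.true_ratio_map == truth.params["gradient_peak"]
    body = truth.mask.pixels & ~band
    return ((ndi.distance_transform_edt(band) >= margin_px)
            | (ndi.distance_transform_edt(body) >= margin_px))


class TestShadingCorrect:
    def test_flat_blank_is_identity(self, rng):
        stack = ChannelStack(rng.random((2, 2, 16, 16)) + 1, ("a", "b"), 1, 1)
        out = shading_correct(stack, np.full((16, 16), 3.7))
        np.testing.assert_allclose(out.pixels, stack.pixels)

    def test_inverts_generator_shading_field(self):
        shaded, truth = syn.simulate_ratiometric_movie(
            shape=(64, 64), n_frames=2, shading_amplitude=0.3, noise_sd=0.0)
        flat, _ = syn.simulate_ratiometric_movie(
            shape=(64, 64), n_frames=2, shading_amplitude=0.0, noise_sd=0.0)
        corrected = shading_correct(shaded, truth.shading)
        np.testing.assert_allclose(corrected.pixels, flat.pixels, atol=1e-9)

    def test_blank_with_zeros_rejected(self, rng):
        stack = ChannelStack(rng.random((1, 1, 8, 8)), ("a",), 1, 1)
        blank = np.ones((8, 8))
        blank[3, 3] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            shading_correct(stack, blank)


class TestRegisterFrames:
    def test_zero_drift_estimates_zero(self):
        stack, _ = syn.simulate_ratiometric_movie(shape=(64, 64), n_frames=3,
                                                  noise_sd=0.0)
        _, shifts = register_frames(stack)
        assert np.linalg.norm(shifts, axis=1).max() < 0.1

    def test_recovers_planted_rigid_drift(self):
        stack, truth = syn.simulate_ratiometric_movie(
            shape=(96, 96), n_frames=4, drift_px_per_frame=(2, -1),
            noise_sd=0.0)
        registered, shifts = register_frames(stack)
        # estimated shift undoes the cumulative drift
        np.testing.assert_allclose(shifts, -truth.drift_px, atol=0.2)
        np.testing.assert_allclose(registered.pixels[3, 1],
                                   stack.pixels[0, 1], atol=1e-6)

    def test_single_frame_returned_unchanged(self, rng):
        stack = ChannelStack(rng.random((1, 1, 16, 16)), ("a",), 1, 1)
        out, shifts = register_frames(stack)
        np.testing.assert_array_equal(out.pixels, stack.pixels)
        np.testing.assert_array_equal(shifts, np.zeros((1, 2)))


class TestSubtractBackground:
    def test_bimodal_background_median_removed(self, rng):
        image = np.full((40, 40), 50.0)
        image[10:30, 10:30] = 500.0
        image += rng.normal(0, 1.0, image.shape)
        out, level = subtract_background(image)
        assert level == pytest.approx(50.0, abs=1.0)
        background = out[image < 200]
        assert np.median(background) == pytest.approx(0.0, abs=1.0)

    def test_already_subtracted_image_unchanged(self):
        image = np.zeros((20, 20))
        image[5:15, 5:15] = 100.0
        out, level = subtract_background(image)
        assert level == 0.0
        np.testing.assert_array_equal(out, image)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            subtract_background(np.full((10, 10), 7.0))

    def test_guide_channel_locates_background_set(self):
        # target channel has no contrast of its own; guide channel does
        guide = np.zeros((30, 30))
        guide[10:20, 10:20] = 1000.0
        target = np.full((30, 30), 40.0)
        target[10:20, 10:20] = 44.0
        _, level = subtract_background(target, background_from=guide)
        assert level == pytest.approx(40.0)


class TestMakeCellMask:
    def test_recovers_generator_footprint(self):
        stack, truth = syn.simulate_ratiometric_movie(noise_sd=0.0)
        mask = make_cell_mask(stack.pixels[0, 1])
        inter = (mask.pixels & truth.mask.pixels).sum()
        union = (mask.pixels | truth.mask.pixels).sum()
        assert inter / union >= 0.95

    def test_keeps_only_largest_component(self):
        image = np.zeros((60, 60))
        rr, cc = np.mgrid[0:60, 0:60]
        image[(rr - 20) ** 2 + (cc - 20) ** 2 <= 12 ** 2] = 100.0
        image[(rr - 45) ** 2 + (cc - 45) ** 2 <= 5 ** 2] = 100.0
        mask = make_cell_mask(image, min_object_px=10)
        assert mask.pixels[20, 20] and not mask.pixels[45, 45]

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError):
            make_cell_mask(np.zeros((20, 20)))


class TestRatioMap:
    def test_double_reporter_gives_ratio_two(self, disc_mask):
        reference = np.where(disc_mask, 100.0, 0.0)
        rmap = ratio_map(2 * reference, reference, BinaryMask(disc_mask),
                         denoise_sigma=0.0)
        np.testing.assert_allclose(rmap.pixels[disc_mask], 2.0)

    def test_zero_reference_region_flagged_not_infinite(self, disc_mask):
        reference = np.where(disc_mask, 100.0, 0.0)
        reference[45:55, 45:55] = 0.0
        rmap = ratio_map(reference * 1.5, reference, BinaryMask(disc_mask),
                         denoise_sigma=0.0)
        assert np.all(np.isnan(rmap.pixels[45:55, 45:55]))
        assert not np.isinf(rmap.pixels[np.isfinite(rmap.pixels)]).any()

    def test_shape_mismatch_rejected(self, disc_mask):
        with pytest.raises(ValueError):
            ratio_map(np.zeros((10, 10)), np.zeros((12, 12)),
                      BinaryMask(disc_mask))

    def test_invariant_to_global_rescaling(self, disc_mask, rng):
        reporter = np.where(disc_mask, rng.uniform(50, 150, disc_mask.shape), 0)
        reference = np.where(disc_mask, 100.0, 0.0)
        mask = BinaryMask(disc_mask)
        a = ratio_map(reporter, reference, mask)
        b = ratio_map(7.3 * reporter, 7.3 * reference, mask)
        np.testing.assert_allclose(b.pixels[disc_mask], a.pixels[disc_mask],
                                   rtol=1e-12)


class TestFullChain:
    def test_zero_noise_chain_inverts_generator(self):
        stack, truth = syn.simulate_ratiometric_movie(noise_sd=0.0)
        maps = ratiometric_movie(stack, register=False)
        safe = _away_from_discontinuities(truth)
        for m in maps:
            dev = np.abs(m.pixels - truth.true_ratio_map)[safe]
            assert np.nanmax(dev) < 1e-6

    def test_chain_with_shading_and_drift_inverts_generator(self):
        stack, truth = syn.simulate_ratiometric_movie(
            n_frames=4, shading_amplitude=0.3, drift_px_per_frame=(1, 2),
            noise_sd=0.0)
        maps = ratiometric_movie(stack, blank=truth.shading)
        safe = _away_from_discontinuities(truth)
        # later frames lose a drifted border strip; exclude it
        safe &= ndi.binary_erosion(truth.mask.pixels, iterations=2)
        for m in maps:
            dev = np.abs(m.pixels - truth.true_ratio_map)[safe]
            assert np.nanmax(dev) < 1e-3

    def test_shading_cancels_in_ratio_when_blank_shared(self):
        # multiplying both channels by the same field leaves the ratio alone
        stack, truth = syn.simulate_ratiometric_movie(
            shading_amplitude=0.4, noise_sd=0.0, background_level=0.0)
        maps_uncorrected = ratiometric_movie(stack, register=False)
        safe = _away_from_discontinuities(truth)
        dev = np.abs(maps_uncorrected[0].pixels - truth.true_ratio_map)[safe]
        assert np.nanmax(dev) < 1e-6


class TestEdgeBodyRatio:
    def test_uniform_map_gives_one(self, disc_mask):
        rmap = ratio_map(np.where(disc_mask, 100.0, 0.0),
                         np.where(disc_mask, 100.0, 0.0),
                         BinaryMask(disc_mask, 0.5), denoise_sigma=0.0)
        assert edge_body_ratio(rmap, 2.0, 0.5) == pytest.approx(1.0)

    def test_recovers_generator_contrast(self):
        stack, truth = syn.simulate_ratiometric_movie(gradient_peak=1.5,
                                                      noise_sd=0.0)
        maps = ratiometric_movie(stack, register=False)
        value = edge_body_ratio(maps[0], truth.params["edge_depth_um"],
                                stack.pixel_size_um)
        assert value == pytest.approx(1.5, abs=0.05)

    def test_band_larger_than_cell_rejected(self, disc_mask):
        rmap = ratio_map(np.where(disc_mask, 100.0, 0.0),
                         np.where(disc_mask, 100.0, 0.0),
                         BinaryMask(disc_mask, 0.5), denoise_sigma=0.0)
        with pytest.raises(ValueError):
            edge_body_ratio(rmap, 1000.0, 0.5)
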