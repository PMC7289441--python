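"""Disc quantification: projections, segmentation, focus calling, size classes."""

import dataclasses

import numpy as np
import pytest

from coprecip.disc_imaging import (
    DiscImageStack,
    call_caspase_foci,
    classify_disc_sizes,
    elav_fraction,
    estimate_basal_fluorescence,
    max_intensity_projection,
    quantify_disc,
    read_disc_stack,
    segment_disc,
    write_disc_stack,
)
from coprecip.errors import ContractError, NoDiscFoundError
from coprecip.synthetic_data import DiscSimConfig, FocusSpec, generate_disc_image, random_foci


def _stack(dapi, elav=None, caspase=None, pixel_size=0.5):
    dapi = np.asarray(dapi, dtype=float)
    fill = np.zeros_like(dapi)
    return DiscImageStack(
        channels={
            "dapi": dapi,
            "elav": np.asarray(elav, dtype=float) if elav is not None else fill,
            "caspase": np.asarray(caspase, dtype=float) if caspase is not None else fill,
        },
        pixel_size=pixel_size,
    )


class TestMip:
    def test_single_plane_is_identity(self):
        img = np.arange(12, dtype=float).reshape(1, 3, 4)
        mips = max_intensity_projection(_stack(img))
        np.testing.assert_array_equal(mips["dapi"], img[0])

    def test_pixelwise_max_by_hand(self):
        planes = np.array([[[1, 2], [3, 4]], [[4, 3], [2, 1]]], dtype=float)
        mips = max_intensity_projection(_stack(planes))
        np.testing.assert_array_equal(mips["dapi"], [[4, 3], [3, 4]])

    def test_mip_dominates_every_plane(self, rng):
        planes = rng.uniform(0, 100, size=(5, 16, 16))
        mip = max_intensity_projection(_stack(planes))["dapi"]
        assert (mip[None] >= planes).all()


class TestSegmentDisc:
    def test_area_is_pixel_count_times_pixel_area(self):
        img = np.full((150, 150), 5.0)
        img[25:125, 25:125] = 200.0  # 10,000 bright pixels
        mask, area = segment_disc(img, pixel_size=0.5)
        assert mask.sum() == 10_000
        assert area == pytest.approx(2_500.0)

    def test_blank_image_raises_no_disc(self):
        with pytest.raises(NoDiscFoundError):
            segment_disc(np.zeros((32, 32)), pixel_size=0.5)

    def test_largest_of_two_blobs_retained(self):
        img = np.zeros((64, 64))
        img[5:10, 5:10] = 100.0  # 25 px
        img[20:40, 20:40] = 100.0  # 400 px
        mask, _ = segment_disc(img, pixel_size=1.0)
        assert mask.sum() == 400
        assert mask[30, 30] and not mask[7, 7]

    def test_interior_holes_are_filled(self):
        img = np.zeros((64, 64))
        img[10:50, 10:50] = 100.0
        img[25:30, 25:30] = 0.0  # dark hole inside the disc
        mask, _ = segment_disc(img, pixel_size=1.0)
        assert mask[27, 27]
        assert mask.sum() == 1600

    def test_area_scales_with_pixel_size_squared(self):
        img = np.zeros((64, 64))
        img[10:40, 10:40] = 100.0
        _, a1 = segment_disc(img, pixel_size=0.3)
        _, a2 = segment_disc(img, pixel_size=0.6)
        assert a2 == pytest.approx(4 * a1)


class TestElavFraction:
    def _disc(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:50, 10:50] = True
        return mask

    def test_elav_filling_whole_disc_is_100pct(self):
        mask = self._disc()
        elav = np.where(mask, 180.0, 10.0)
        assert elav_fraction(elav, mask) == pytest.approx(100.0)

    def test_no_signal_above_background_is_0pct(self):
        mask = self._disc()
        elav = np.full(mask.shape, 10.0)
        assert elav_fraction(elav, mask) == pytest.approx(0.0)

    def test_planted_fraction_recovered(self):
        stack, truth = generate_disc_image(DiscSimConfig(image_shape=(128, 128), seed=2))
        res = quantify_disc(stack)
        assert res.elav_fraction == pytest.approx(truth.elav_fraction_pct, abs=2.0)

    def test_empty_mask_is_contract_error(self):
        with pytest.raises(ContractError):
            elav_fraction(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool))


class TestBasalEstimate:
    def _disc(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:50, 10:50] = True
        return mask

    def test_uniform_intensity_returned_exactly(self):
        mask = self._disc()
        assert estimate_basal_fluorescence(np.full(mask.shape, 100.0), mask) == 100.0

    def test_robust_to_sparse_bright_foci(self):
        mask = self._disc()
        img = np.full(mask.shape, 100.0)
        img[12:16, 12:16] = 1000.0  # 16 of 1600 in-mask pixels (1%)
        est = estimate_basal_fluorescence(img, mask)
        assert est == pytest.approx(100.0, rel=0.05)

    def test_unbiased_under_noise_many_seeds(self):
        mask = self._disc()
        ests = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            img = 100.0 + rng.normal(0, 10.0, size=mask.shape)
            ests.append(estimate_basal_fluorescence(img, mask))
        assert np.mean(ests) == pytest.approx(100.0, abs=1.0)


class TestCaspaseFoci:
    def _scene(self, spots, pixel_size=0.5, basal=100.0, shape=(128, 128)):
        """spots: list of (rowslice, colslice, multiple)."""
        mask = np.ones(shape, dtype=bool)
        img = np.full(shape, basal)
        for rs, cs, mult in spots:
            img[rs, cs] = mult * basal
        return img, mask

    def test_uniform_basal_image_has_no_foci(self):
        img, mask = self._scene([])
        assert call_caspase_foci(img, mask, basal=100.0, pixel_size=0.5) == []

    def test_upper_gate_rejects_large_focus(self):
        # areas 5, 30 and 70 um^2 at pixel_size 0.5 (4 px = 1 um^2)
        img, mask = self._scene([
            (slice(5, 10), slice(5, 9), 5.0),      # 20 px = 5 um^2
            (slice(30, 42), slice(30, 40), 5.0),   # 120 px = 30 um^2
            (slice(70, 98), slice(70, 80), 5.0),   # 280 px = 70 um^2
        ])
        foci = call_caspase_foci(img, mask, basal=100.0, pixel_size=0.5)
        assert sorted(f.area for f in foci) == [5.0, 30.0]

    @pytest.mark.parametrize("area_px, called", [
        (4, False),    # exactly 1.0 um^2: strict lower gate rejects
        (5, True),
        (239, True),
        (240, False),  # exactly 60.0 um^2: strict upper gate rejects
    ])
    def test_gate_bounds_are_strict(self, area_px, called):
        img = np.full((64, 64), 100.0)
        mask = np.ones((64, 64), dtype=bool)
        flat = np.zeros(64 * 64, dtype=bool)
        flat[: area_px] = True  # one 8-connected row-major strip
        img[flat.reshape(64, 64)] = 500.0
        foci = call_caspase_foci(img, mask, basal=100.0, pixel_size=0.5)
        assert (len(foci) == 1) is called

    def test_intensity_exactly_3x_basal_is_called(self):
        img, mask = self._scene([(slice(10, 14), slice(10, 14), 3.0)])
        foci = call_caspase_foci(img, mask, basal=100.0, pixel_size=0.5)
        assert len(foci) == 1
        assert foci[0].mean_fluorescence == pytest.approx(300.0)

    def test_just_below_3x_basal_not_called(self):
        img, mask = self._scene([(slice(10, 14), slice(10, 14), 2.99)])
        assert call_caspase_foci(img, mask, basal=100.0, pixel_size=0.5) == []

    def test_foci_outside_disc_mask_ignored(self):
        img = np.full((64, 64), 100.0)
        img[2:6, 2:6] = 500.0
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:60, 20:60] = True
        assert call_caspase_foci(img, mask, basal=100.0, pixel_size=0.5) == []

    def test_area_scales_with_pixel_size_squared(self):
        img, mask = self._scene([(slice(10, 14), slice(10, 14), 5.0)])
        f1 = call_caspase_foci(img, mask, basal=100.0, pixel_size=0.5)
        f2 = call_caspase_foci(img, mask, basal=100.0, pixel_size=1.0)
        assert f2[0].area == pytest.approx(4 * f1[0].area)

    def test_nonpositive_basal_is_contract_error(self):
        img, mask = self._scene([])
        with pytest.raises(ContractError):
            call_caspase_foci(img, mask, basal=0.0, pixel_size=0.5)


class TestEndToEndRecovery:
    def test_noise_free_recovery_of_all_planted_quantities(self, rng):
        cfg = DiscSimConfig(seed=21)
        cfg = dataclasses.replace(cfg, foci=random_foci(cfg, 6, rng))
        stack, truth = generate_disc_image(cfg)
        res = quantify_disc(stack)
        assert res.n_foci == len(truth.foci)
        assert res.disc_area == pytest.approx(truth.disc_area_um2, rel=0.02)
        assert res.elav_fraction == pytest.approx(truth.elav_fraction_pct, abs=2.0)
        planted_mean = np.mean([f.area_um2 for f in truth.foci])
        assert res.mean_focus_area == pytest.approx(planted_mean, rel=0.05)

    def test_tiff_round_trip_preserves_quantification(self, rng, tmp_path):
        cfg = DiscSimConfig(image_shape=(128, 128), seed=3)
        cfg = dataclasses.replace(cfg, foci=random_foci(cfg, 3, rng))
        stack, _ = generate_disc_image(cfg)
        path = write_disc_stack(stack, tmp_path / "d.tiff")
        back = read_disc_stack(path, pixel_size=cfg.pixel_size, z_step=cfg.z_step)
        r1, r2 = quantify_disc(stack), quantify_disc(back)
        assert r1.n_foci == r2.n_foci
        assert r1.disc_area == pytest.approx(r2.disc_area)
        assert r1.elav_fraction == pytest.approx(r2.elav_fraction)


class TestClassifyDiscSizes:
    def test_all_tests_at_control_mean(self):
        control = [90.0, 100.0, 110.0]
        assert classify_disc_sizes([100.0] * 5, control) == (0.0, 1.0, 0.0)

    def test_single_test_three_sd_above(self):
        rng = np.random.default_rng(0)
        control = list(rng.normal(100, 10, size=500))
        mean, sd = np.mean(control), np.std(control, ddof=1)
        below, within, above = classify_disc_sizes([mean + 3 * sd], control)
        assert (below, within, above) == (0.0, 0.0, 1.0)

    def test_normal_tail_mass_recovered(self):
        rng = np.random.default_rng(42)
        control = list(rng.normal(1000.0, 50.0, size=5000))
        test = list(rng.normal(1000.0, 50.0, size=10_000))
        below, within, above = classify_disc_sizes(test, control)
        assert below + above == pytest.approx(0.0455, abs=0.006)
        assert below + within + above == pytest.approx(1.0)

    def test_fewer_than_two_controls_is_contract_error(self):
        with pytest.raises(ContractError):
            classify_disc_sizes([100.0], [100.0])
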