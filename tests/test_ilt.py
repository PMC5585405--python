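"""The ILT directional filter: ramp, ray accumulation, pooling, thresholding."""

import math

import numpy as np
import pytest

from bodycomp.core import CTSlice
from bodycomp.ilt import (
    ILTParams,
    accumulate_direction,
    directional_accumulations,
    hu_to_lean_prob,
    ilt_response,
    inside_mask,
)
from bodycomp.reference import naive_ilt_response


class TestLeanProbabilityRamp:
    def test_ramp_endpoints_and_midpoint(self):
        assert hu_to_lean_prob(-30.0, -30, 20) == 0.0
        assert hu_to_lean_prob(20.0, -30, 20) == 1.0
        assert hu_to_lean_prob(-5.0, -30, 20) == pytest.approx(0.5)
        assert hu_to_lean_prob(-500.0, -30, 20) == 0.0
        assert hu_to_lean_prob(1200.0, -30, 20) == 1.0

    def test_inverted_levels_rejected(self):
        with pytest.raises(ValueError):
            hu_to_lean_prob(0.0, 20, -30)
        with pytest.raises(ValueError):
            ILTParams(L1=20, L2=-30)


class TestILTParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ILTParams(n_dir=3)
        with pytest.raises(ValueError):
            ILTParams(dir_percent=0.0)
        with pytest.raises(ValueError):
            ILTParams(dir_percent=1.2)
        with pytest.raises(ValueError):
            ILTParams(pm_threshold=1.5)
        with pytest.raises(ValueError):
            ILTParams(step_mm=0.0)

    def test_pooled_count_rounds_up(self):
        assert ILTParams(n_dir=32, dir_percent=0.5).n_pooled == 16
        assert ILTParams(n_dir=10, dir_percent=0.55).n_pooled == 6


class TestAccumulateDirection:
    def test_zero_probability_image_accumulates_zero(self):
        prob = np.zeros((16, 16))
        assert accumulate_direction(prob, (8, 8), (0, 1), 1.0, (1, 1)) == 0.0

    def test_constant_image_counts_in_bounds_samples(self):
        prob = np.ones((16, 16))
        # from col 8 along +col: samples at 9..15 -> 7 samples
        assert accumulate_direction(prob, (8, 8), (0, 1), 1.0, (1, 1)) == pytest.approx(7.0)
        # against -row from row 3: samples at rows 2, 1, 0 -> 3 samples
        assert accumulate_direction(prob, (3, 8), (-1, 0), 1.0, (1, 1)) == pytest.approx(3.0)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            accumulate_direction(np.ones((4, 4)), (1, 1), (0, 0), 1.0, (1, 1))

    def test_origin_outside_image_rejected(self):
        with pytest.raises(ValueError):
            accumulate_direction(np.ones((4, 4)), (9, 1), (0, 1), 1.0, (1, 1))

    def test_matches_independent_sampling_loop(self, rng):
        """Hand-rolled bilinear ray marching written inline as the oracle."""
        prob = rng.random((20, 24))
        spacing = (1.5, 0.9)
        for theta in (0.3, 2.0, 4.4):
            d = (math.cos(theta), math.sin(theta))
            got = accumulate_direction(prob, (7, 11), d, 0.8, spacing)
            expected, k = 0.0, 1
            while True:
                r = 7 + k * 0.8 * d[0] / spacing[0]
                c = 11 + k * 0.8 * d[1] / spacing[1]
                if not (0 <= r <= 19 and 0 <= c <= 23):
                    break
                r0, c0 = min(int(r), 18), min(int(c), 22)
                fr, fc = r - r0, c - c0
                expected += (
                    prob[r0, c0] * (1 - fr) * (1 - fc)
                    + prob[r0 + 1, c0] * fr * (1 - fc)
                    + prob[r0, c0 + 1] * (1 - fr) * fc
                    + prob[r0 + 1, c0 + 1] * fr * fc
                )
                k += 1
            assert got == pytest.approx(expected, abs=1e-9)


def _lean_disk_slice(size=33, radius=10.0):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    c = (size - 1) / 2
    hu = np.full((size, size), -1000.0)
    hu[(yy - c) ** 2 + (xx - c) ** 2 <= radius**2] = 50.0
    return CTSlice(hu, (1.0, 1.0), "abdomen"), int(c)


class TestILTResponse:
    def test_center_of_lean_disk_is_the_maximum(self):
        ct, c = _lean_disk_slice()
        resp = ilt_response(ct, ILTParams(n_dir=16))
        assert resp[c, c] == pytest.approx(1.0)
        assert resp.max() == pytest.approx(1.0)

    def test_air_corner_scores_below_disk_interior(self):
        ct, c = _lean_disk_slice()
        resp = ilt_response(ct, ILTParams(n_dir=16))
        disk = ct.pixels > 0
        assert resp[0, 0] < resp[disk].min()

    def test_all_air_image_maps_to_zero(self):
        ct = CTSlice(np.full((20, 20), -1000.0), (1, 1), "abdomen")
        resp = ilt_response(ct, ILTParams(n_dir=8))
        assert (resp == 0).all()

    def test_response_bounded_in_unit_interval(self, rng):
        hu = rng.uniform(-400, 200, size=(24, 24))
        resp = ilt_response(CTSlice(hu, (1, 1), "abdomen"), ILTParams(n_dir=8))
        assert resp.min() >= 0.0 and resp.max() <= 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_production_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hu = rng.uniform(-300, 120, size=(32, 32))
        ct = CTSlice(hu, (1.0, 1.0), "abdomen")
        params = ILTParams(n_dir=16, dir_percent=0.5)
        prod = ilt_response(ct, params)
        ref = naive_ilt_response(ct, params)
        assert np.abs(prod - ref).max() <= 1e-9

    def test_production_matches_naive_oracle_nearest_interp(self):
        rng = np.random.default_rng(5)
        hu = rng.uniform(-300, 120, size=(24, 24))
        ct = CTSlice(hu, (1.0, 1.0), "abdomen")
        params = ILTParams(n_dir=8, interp="nearest")
        assert np.abs(ilt_response(ct, params) - naive_ilt_response(ct, params)).max() <= 1e-9

    def test_anisotropic_spacing_matches_oracle(self):
        rng = np.random.default_rng(9)
        hu = rng.uniform(-300, 120, size=(20, 28))
        ct = CTSlice(hu, (2.0, 1.2), "abdomen")
        params = ILTParams(n_dir=12)
        assert np.abs(ilt_response(ct, params) - naive_ilt_response(ct, params)).max() <= 1e-9

    def test_single_pixel_image_rejected(self):
        ct = CTSlice(np.zeros((1, 1)), (1, 1), "abdomen")
        with pytest.raises(ValueError):
            ilt_response(ct, ILTParams())

    def test_monotone_in_pixel_probability(self, rng):
        """Raising one pixel's lean probability never lowers any pre-normalisation
        pooled response (sums of nonnegative terms; smallest-k pooling is
        weakly monotone)."""
        prob = rng.random((16, 16)) * 0.5
        params = ILTParams(n_dir=8, dir_percent=0.5)

        def pooled(p):
            acc, rows, cols = directional_accumulations(p, (1.0, 1.0), params)
            k = params.n_pooled
            out = np.zeros(p.shape)
            out[rows, cols] = np.sort(acc, axis=1)[:, :k].sum(axis=1)
            return out

        base = pooled(prob)
        bumped = prob.copy()
        bumped[8, 8] = 1.0
        assert (pooled(bumped) - base >= -1e-12).all()

    def test_annulus_interior_beats_exterior_at_equal_ring_distance(self):
        """For dir_percent=1 a pixel inside a closed lean ring accumulates the
        wall in every direction; an outside pixel at the same distance does not."""
        size = 41
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        c = (size - 1) / 2
        r = np.hypot(yy - c, xx - c)
        hu = np.full((size, size), -1000.0)
        hu[(r >= 10) & (r <= 13)] = 50.0
        ct = CTSlice(hu, (1, 1), "abdomen")
        resp = ilt_response(ct, ILTParams(n_dir=16, dir_percent=1.0))
        inside = resp[int(c), int(c - 5)]  # 5 px inside the ring
        outside = resp[int(c), int(c - 18)]  # 5 px outside the ring
        assert inside > outside


class TestInsideMask:
    def test_threshold_zero_selects_everything(self, rng):
        resp = rng.random((10, 10))
        assert inside_mask(resp, 0.0).all()

    def test_threshold_one_selects_only_the_maximum(self):
        resp = np.zeros((5, 5))
        resp[2, 3] = 1.0
        mask = inside_mask(resp, 1.0)
        assert mask.sum() == 1 and mask[2, 3]
        with pytest.raises(ValueError):
            inside_mask(resp, 1.0 + 1e-9)

    def test_largest_component_and_hole_filling(self):
        resp = np.zeros((12, 12))
        resp[1:3, 1:3] = 0.9  # small blob
        resp[5:11, 5:11] = 0.9  # large blob with a hole
        resp[7, 7] = 0.0
        mask = inside_mask(resp, 0.5, largest_component=True, fill_holes=True)
        assert not mask[1, 1]
        assert mask[7, 7]

    def test_calibrated_threshold_separates_annulus_interior(self):
        size = 41
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        c = (size - 1) / 2
        r = np.hypot(yy - c, xx - c)
        hu = np.full((size, size), -1000.0)
        hu[(r >= 12) & (r <= 15)] = 50.0
        ct = CTSlice(hu, (1, 1), "abdomen")
        resp = ilt_response(ct, ILTParams(n_dir=16, dir_percent=0.5))
        mask = inside_mask(resp, 0.1, largest_component=True, fill_holes=True)
        assert mask[r <= 11].all()  # cavity enclosed
        assert not mask[r >= 17].any()  # exterior excluded
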