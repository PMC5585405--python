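"""Thigh separation and per-thigh muscle/SAT/SFAT/IMAT segmentation."""

import numpy as np
import pytest

from bodycomp import config as cfg
from bodycomp.core import CTSlice
from bodycomp.errors import SegmentationError
from bodycomp.metrics import overlap
from bodycomp.phantom import ThighPhantomSpec, make_phantom
from bodycomp.thigh import (
    muscle_attenuation,
    segment_muscle_at,
    segment_thigh_slice,
    separate_thighs,
    sfat_imat_ilt,
    sfat_imat_morph,
    thigh_sat,
)


@pytest.fixture(scope="module")
def sides(thigh_phantom):
    left, right = separate_thighs(thigh_phantom.slice)
    return {"left": left, "right": right}


class TestSeparateThighs:
    def test_two_disks_match_truth_components(self, thigh_phantom, sides):
        for side, mask in sides.items():
            truth = (
                thigh_phantom.depot_mask("muscle", side)
                | thigh_phantom.depot_mask("adipose", side)
                | thigh_phantom.depot_mask("bone", side)
            )
            assert overlap(mask, truth).dice > 0.999

    def test_table_in_neither_thigh(self, thigh_phantom, sides):
        table = thigh_phantom.mask("table")
        assert table.any()
        for mask in sides.values():
            assert not (mask & table).any()

    def test_left_is_left_of_right(self, sides):
        assert np.nonzero(sides["left"])[1].mean() < np.nonzero(sides["right"])[1].mean()

    def test_bridged_thighs_split_by_opening(self):
        p = make_phantom(ThighPhantomSpec(seed=8, bridge=True))
        left, right = separate_thighs(p.slice)
        assert left.any() and right.any()
        assert not (left & right).any()

    def test_single_leg_slice_raises(self):
        hu = np.full((40, 40), -1000.0)
        hu[10:30, 10:30] = 45.0
        with pytest.raises(SegmentationError):
            separate_thighs(CTSlice(hu, (2, 2), "thigh"))


class TestSegmentMuscleAT:
    def test_marrow_is_bone_not_adipose(self, thigh_phantom, sides):
        ct = thigh_phantom.slice
        for side, mask in sides.items():
            muscle, adipose, bone = segment_muscle_at(mask, ct)
            marrow = thigh_phantom.depot_mask("bone", side) & thigh_phantom.mask("marrow")
            assert (bone & marrow).sum() / marrow.sum() > 0.99
            assert not (adipose & marrow).any()
            assert not (muscle & adipose).any()

    def test_masks_match_band_oracle_outside_bone(self, thigh_phantom, sides, bands):
        ct = thigh_phantom.slice
        mask = sides["left"]
        muscle, adipose, bone = segment_muscle_at(mask, ct)
        outside_bone = mask & ~bone
        hu = ct.pixels
        assert np.array_equal(adipose, ((hu >= -190) & (hu <= -30)) & outside_bone)
        assert np.array_equal(muscle, ((hu > -30) & (hu <= 151)) & outside_bone)

    def test_no_adipose_thigh_gives_empty_adipose(self):
        lean_fat = {"thigh_sat": (45.0, 5.0), "sfat": (45.0, 5.0), "imat": (45.0, 5.0)}
        p = make_phantom(ThighPhantomSpec(seed=9, hu_overrides=lean_fat))
        left, _ = separate_thighs(p.slice)
        _, adipose, _ = segment_muscle_at(left, p.slice)
        assert not adipose.any()


class TestThighSat:
    def test_concentric_phantom_sat_ring_recovered(self, thigh_phantom, sides):
        ct = thigh_phantom.slice
        for side, mask in sides.items():
            _, adipose, _ = segment_muscle_at(mask, ct)
            sat = thigh_sat(adipose, ct, cfg.THIGH_SAT_ILT, thigh=mask)
            assert overlap(sat, thigh_phantom.depot_mask("sat", side)).dice >= 0.99
            imat = thigh_phantom.depot_mask("imat", side)
            assert not (sat & imat).any()  # islands are not SAT

    def test_adipose_only_thigh_is_all_sat(self):
        # no muscle at all: the inside mask is empty and everything stays SAT
        overrides = {"thigh_muscle": (-95.0, 10.0), "fascia": (-95.0, 10.0),
                     "bone": (-95.0, 10.0), "marrow": (-95.0, 10.0)}
        p = make_phantom(ThighPhantomSpec(seed=10, n_imat=0, hu_overrides=overrides))
        left, _ = separate_thighs(p.slice)
        _, adipose, _ = segment_muscle_at(left, p.slice)
        with pytest.warns(UserWarning):
            sat = thigh_sat(adipose, p.slice, cfg.THIGH_SAT_ILT, thigh=left)
        assert np.array_equal(sat, adipose)


class TestSfatImatILT:
    def test_band_and_islands_separated(self, thigh_phantom, sides):
        ct = thigh_phantom.slice
        for side, mask in sides.items():
            _, adipose, _ = segment_muscle_at(mask, ct)
            sat = thigh_sat(adipose, ct, cfg.THIGH_SAT_ILT, thigh=mask)
            inner = adipose & ~sat
            sfat, imat = sfat_imat_ilt(inner, ct, cfg.THIGH_DEEP_ILT, thigh=mask)
            assert overlap(sfat, thigh_phantom.depot_mask("sfat", side)).dice >= 0.8
            assert overlap(imat, thigh_phantom.depot_mask("imat", side)).dice >= 0.8
            assert np.array_equal(sfat | imat, inner)
            assert not (sfat & imat).any()

    def test_no_islands_gives_empty_imat(self):
        p = make_phantom(ThighPhantomSpec(seed=13, n_imat=0))
        ct = p.slice
        left, _ = separate_thighs(ct)
        _, adipose, _ = segment_muscle_at(left, ct)
        sat = thigh_sat(adipose, ct, cfg.THIGH_SAT_ILT, thigh=left)
        _, imat = sfat_imat_ilt(adipose & ~sat, ct, cfg.THIGH_DEEP_ILT, thigh=left)
        assert imat.sum() == 0

    def test_empty_inner_adipose_gives_empty_outputs(self, thigh_phantom, sides):
        empty = np.zeros(thigh_phantom.slice.shape, bool)
        sfat, imat = sfat_imat_ilt(empty, thigh_phantom.slice, cfg.THIGH_DEEP_ILT)
        assert not sfat.any() and not imat.any()


class TestSfatImatMorph:
    def _disk_inner(self, radius=50.0, spacing=1.0, size=128):
        yy, xx = np.mgrid[0:size, 0:size].astype(float) * spacing
        c = size * spacing / 2
        return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2

    def test_analytic_disk_areas(self):
        """Eroding a radius-50 mm disk by 5 mm: rim and core areas match the
        closed-form annulus/disk areas to within pixelisation."""
        disk = self._disk_inner()
        sfat, imat = sfat_imat_morph(disk, np.zeros_like(disk), 5.0, (1.0, 1.0))
        assert sfat.sum() == pytest.approx(np.pi * (50.0**2 - 45.0**2), rel=0.02)
        assert imat.sum() == pytest.approx(np.pi * 45.0**2, rel=0.02)
        assert np.array_equal(sfat | imat, disk)

    def test_vanishing_depth_empties_sfat(self):
        disk = self._disk_inner()
        sfat, imat = sfat_imat_morph(disk, np.zeros_like(disk), 0.1, (1.0, 1.0))
        assert sfat.sum() == 0
        assert np.array_equal(imat, disk)

    def test_depth_beyond_radius_empties_imat_with_warning(self):
        disk = self._disk_inner(radius=20.0, size=60)
        with pytest.warns(UserWarning):
            sfat, imat = sfat_imat_morph(disk, np.zeros_like(disk), 60.0, (1.0, 1.0))
        assert imat.sum() == 0
        assert np.array_equal(sfat, disk)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            sfat_imat_morph(np.ones((4, 4), bool), np.zeros((4, 4), bool), 0.0, (1, 1))

    def test_methods_agree_on_clean_fascia_phantom(self, thigh_phantom, sides):
        ct = thigh_phantom.slice
        mask = sides["left"]
        muscle, adipose, _ = segment_muscle_at(mask, ct)
        sat = thigh_sat(adipose, ct, cfg.THIGH_SAT_ILT, thigh=mask)
        inner = adipose & ~sat
        _, imat1 = sfat_imat_ilt(inner, ct, cfg.THIGH_DEEP_ILT, thigh=mask)
        _, imat2 = sfat_imat_morph(inner, muscle, cfg.THIGH_DEPTH_MM, ct.spacing)
        assert overlap(imat1, imat2).dice >= 0.9


class TestMuscleAttenuation:
    def test_uniform_muscle(self):
        hu = np.full((20, 20), 45.0)
        ct = CTSlice(hu, (1, 1), "thigh")
        assert muscle_attenuation(ct, hu == 45.0) == 45.0

    def test_single_pixel(self):
        hu = np.full((4, 4), -100.0)
        hu[2, 2] = 60.0
        ct = CTSlice(hu, (1, 1), "thigh")
        mask = np.zeros((4, 4), bool)
        mask[2, 2] = True
        assert muscle_attenuation(ct, mask) == 60.0

    def test_noisy_muscle_mean_recovery(self):
        rng = np.random.default_rng(77)
        hu = rng.normal(45.0, 4.0, size=(100, 100))
        ct = CTSlice(hu, (1, 1), "thigh")
        assert muscle_attenuation(ct, np.ones((100, 100), bool)) == pytest.approx(45.0, abs=0.1)

    def test_empty_mask_rejected(self):
        ct = CTSlice(np.zeros((4, 4)), (1, 1), "thigh")
        with pytest.raises(ValueError):
            muscle_attenuation(ct, np.zeros((4, 4), bool))


class TestFullPipeline:
    def test_depot_conservation_both_methods(self, thigh_phantom):
        ct = thigh_phantom.slice
        for method in ("ilt", "morph"):
            results = segment_thigh_slice(ct, method=method, depth_mm=cfg.THIGH_DEPTH_MM)
            for side, r in results.items():
                _, adipose, _ = segment_muscle_at(
                    r.muscle | r.sat | r.sfat | r.imat | r.bone, ct
                )
                total = int(r.sat.sum()) + int(r.sfat.sum()) + int(r.imat.sum())
                left, right = separate_thighs(ct)
                mask = left if side == "left" else right
                _, adipose, _ = segment_muscle_at(mask, ct)
                assert total == int(adipose.sum())

    def test_mirroring_the_image_mirrors_all_outputs(self):
        p = make_phantom(ThighPhantomSpec(seed=14))
        ct = p.slice
        mirrored = CTSlice(ct.pixels[:, ::-1].copy(), ct.spacing, "thigh")
        res = segment_thigh_slice(ct, method="ilt")
        res_m = segment_thigh_slice(mirrored, method="ilt")
        for a_side, b_side in (("left", "right"), ("right", "left")):
            for depot in ("muscle", "sat", "sfat", "imat", "bone"):
                a = getattr(res[a_side], depot)
                b = getattr(res_m[b_side], depot)
                assert np.array_equal(a[:, ::-1], b), (a_side, depot)
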