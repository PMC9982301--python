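"""Initial mask generation: QC, colour rules, nucleus transfer."""

import numpy as np
import pytest
from skimage.draw import disk

from restainseg import maskgen
from restainseg.maskgen import (NucleusInstanceMap, TargetProfile,
                                build_rbc_mask, make_initial_mask,
                                qc_nuclear_correlation, rbc_color_mask,
                                segment_nuclei, suppress_rbc_false_positives,
                                transfer_to_nuclei)


class TestNuclearCorrelationQC:
    def test_identical_maps_keep(self):
        rng = np.random.default_rng(0)
        a = rng.random((64, 64))
        r, keep = qc_nuclear_correlation(a, a)
        assert r == pytest.approx(1.0) and keep

    def test_inverted_map_drops(self):
        rng = np.random.default_rng(0)
        a = rng.random((64, 64))
        r, keep = qc_nuclear_correlation(a, 1 - a)
        assert r == pytest.approx(-1.0) and not keep

    def test_independent_noise_drops(self):
        rng = np.random.default_rng(1)
        r, keep = qc_nuclear_correlation(rng.random((64, 64)),
                                         rng.random((64, 64)))
        assert abs(r) < 0.5 and not keep

    def test_constant_map_is_flagged_undefined(self):
        r, keep = qc_nuclear_correlation(np.zeros((8, 8)), np.ones((8, 8)))
        assert np.isnan(r) and not keep


class TestRbcRules:
    @pytest.mark.parametrize("rgb,expected", [
        ((150, 80, 90), True),     # red enough on every condition
        ((150, 140, 90), False),   # G >= 130
        ((90, 50, 80), False),     # R <= 100
        ((120, 80, 130), False),   # R <= B
        ((101, 129, 100), True),   # boundary: strict inequalities satisfied
        ((100, 50, 50), False),    # boundary: R not > 100
    ])
    def test_color_rule_truth_table(self, rgb, expected):
        px = np.array(rgb, dtype=np.uint8).reshape(1, 1, 3)
        assert rbc_color_mask(px)[0, 0] == expected

    def test_if_positive_without_red_is_empty(self):
        if_t = np.full((32, 32), 200.0)
        hne = np.full((32, 32, 3), (90, 90, 90), dtype=np.uint8)
        assert not build_rbc_mask(if_t, hne, 50).any()

    def test_red_disk_with_strong_if_is_kept(self):
        hne = np.full((64, 64, 3), 240, dtype=np.uint8)
        rr, cc = disk((32, 32), 10)
        hne[rr, cc] = (170, 90, 100)
        if_t = np.full((64, 64), 200.0)
        mask = build_rbc_mask(if_t, hne, 50)
        expect = np.zeros((64, 64), dtype=bool)
        expect[rr, cc] = True
        assert (mask == expect).all()

    def test_red_disk_with_weak_if_is_empty(self):
        hne = np.full((64, 64, 3), 240, dtype=np.uint8)
        rr, cc = disk((32, 32), 10)
        hne[rr, cc] = (170, 90, 100)
        assert not build_rbc_mask(np.full((64, 64), 10.0), hne, 50).any()


class TestRbcSuppression:
    def test_empty_prediction_is_identity(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2:8, 2:8] = True
        out = suppress_rbc_false_positives(mask, np.zeros_like(mask))
        assert (out == mask).all()

    def test_superset_prediction_empties_mask(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2:8, 2:8] = True
        assert not suppress_rbc_false_positives(mask, np.ones_like(mask)).any()

    def test_partial_overlap_arithmetic(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:10, 0:10] = True            # 100 px
        rbc = np.zeros_like(mask)
        rbc[0:4, 0:10] = True              # 40 px overlap
        out = suppress_rbc_false_positives(mask, rbc)
        assert out.sum() == 60

    def test_suppression_is_idempotent(self):
        rng = np.random.default_rng(3)
        mask = rng.random((32, 32)) > 0.5
        rbc = rng.random((32, 32)) > 0.7
        once = suppress_rbc_false_positives(mask, rbc)
        twice = suppress_rbc_false_positives(once, rbc)
        assert (once == twice).all()


class TestNucleusSegmentation:
    def test_blank_dapi_gives_zero_nuclei(self):
        inst = segment_nuclei(np.zeros((64, 64)))
        assert inst.n_nuclei == 0

    def test_well_separated_fixture_nuclei_are_all_found(self, plain_slide):
        _, _, if_img, truth = plain_slide
        inst = segment_nuclei(if_img[..., 0].astype(float))
        assert inst.n_nuclei == len(truth.nucleus_centers)

    def test_touching_nuclei_are_split_by_watershed(self):
        dapi = np.zeros((80, 80))
        rr, cc = disk((40, 28), 12)
        dapi[rr, cc] = 200
        rr, cc = disk((40, 50), 12)
        dapi[rr, cc] = 200
        inst = segment_nuclei(dapi, min_distance=8)
        assert inst.n_nuclei == 2


class TestNucleusTransfer:
    def test_forty_percent_rule_is_strict(self):
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[1:4, 1:4] = 1               # 10-px nucleus with a 3x3 core
        labels[4, 2] = 1
        signal = np.zeros((12, 12), dtype=bool)
        signal[1:3, 1:3] = True            # 4 positive px -> fraction 0.4
        inst = NucleusInstanceMap.from_labels(labels)
        assert not transfer_to_nuclei(inst, signal).any()
        signal[3, 1] = True                # 5 positive px -> 0.5 > 0.4
        assert transfer_to_nuclei(inst, signal).any()

    def test_single_erosion_of_square_nucleus(self):
        labels = np.zeros((9, 9), dtype=np.int32)
        labels[2:7, 2:7] = 1               # 5x5 nucleus, fully positive
        inst = NucleusInstanceMap.from_labels(labels)
        out = transfer_to_nuclei(inst, labels > 0)
        expect = np.zeros((9, 9), dtype=bool)
        expect[3:6, 3:6] = True            # 3x3 after one 3x3 erosion
        assert (out == expect).all()

    def test_transfer_mask_is_subset_of_nucleus_union(self, plain_slide):
        _, _, if_img, truth = plain_slide
        inst = NucleusInstanceMap.from_labels(truth.nucleus_labels)
        out = transfer_to_nuclei(inst, if_img[..., 1] > 25)
        assert not (out & ~(truth.nucleus_labels > 0)).any()


class TestInitialMaskDispatch:
    def test_area_mode_recovers_cytoplasmic_region(self, plain_slide):
        _, hne, if_img, truth = plain_slide
        profile = TargetProfile.for_target("aSMA")
        mask = make_initial_mask(if_img[..., 1], hne, profile,
                                 rbc_prediction=truth.rbc_mask)
        from restainseg.evaluate import pixel_dice
        assert pixel_dice(truth.true_mask, mask).dice > 0.9

    def test_nucleus_transfer_mode_masks_positive_nuclei_only(self):
        profile = TargetProfile("CD45", "nucleus_transfer", 25.0)
        from restainseg import fixtures as fx
        nspec = fx.FixtureSpec(image_height_px=768, image_width_px=768,
                               n_spots=1, nuclei_per_spot=30,
                               positive_fraction=0.5, stain_pattern="nuclear",
                               global_shift_px=(0.0, 0.0), rbc_count=0,
                               if_gradient=(120.0, 0.0), seed=11)
        nh, nif, ntruth = fx.generate_slide_pair(nspec)
        ninst = NucleusInstanceMap.from_labels(ntruth.nucleus_labels)
        mask = make_initial_mask(nif[..., 1], nh, profile, nuclei=ninst)
        hit = {int(k) for k in np.unique(ntruth.nucleus_labels[mask]) if k > 0}
        expected = {k + 1 for k in np.flatnonzero(ntruth.positive)}
        assert hit == expected

    def test_all_negative_fixture_gives_empty_mask(self):
        from restainseg import fixtures as fx
        spec = fx.FixtureSpec(image_height_px=512, image_width_px=512,
                              nuclei_per_spot=15, positive_fraction=0.0,
                              rbc_count=0, global_shift_px=(0.0, 0.0), seed=9)
        hne, if_img, truth = fx.generate_slide_pair(spec)
        profile = TargetProfile.for_target("aSMA")
        mask = make_initial_mask(if_img[..., 1], hne, profile)
        assert not mask.any()

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            TargetProfile("x", "bogus", 25.0)
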