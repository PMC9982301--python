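"""Consensus annotations, Dice machinery and morphometrics."""

import numpy as np
import pytest
from skimage.draw import polygon2mask

from restainseg.evaluate import (AnnotationSet, EvalReport, cell_dice,
                                 consensus_points, consensus_regions,
                                 hematoxylin_intensity, nearest_rbc_distance,
                                 pixel_dice, pooled_dice)


def _square(r0, c0, side):
    return np.array([[r0, c0], [r0, c0 + side], [r0 + side, c0 + side],
                     [r0 + side, c0]], dtype=float)


class TestConsensusRegions:
    def test_unanimous_polygons_reproduce_each_annotator(self):
        poly = _square(10, 10, 30)
        ann = AnnotationSet(polygons={a: [poly] for a in "ABC"})
        cons = consensus_regions(ann, (64, 64))
        assert (cons == polygon2mask((64, 64), poly)).all()

    def test_single_annotator_region_is_excluded(self):
        ann = AnnotationSet(polygons={"A": [_square(5, 5, 20)],
                                      "B": [], "C": []})
        assert not consensus_regions(ann, (64, 64)).any()

    def test_half_overlapping_squares_keep_only_the_intersection(self):
        a = _square(0, 0, 40)
        b = _square(0, 20, 40)
        ann = AnnotationSet(polygons={"A": [a], "B": [b]})
        cons = consensus_regions(ann, (64, 64))
        oracle = polygon2mask((64, 64), a) & polygon2mask((64, 64), b)
        assert (cons == oracle).all()

    def test_annotator_order_does_not_matter(self):
        rng = np.random.default_rng(0)
        polys = {a: [_square(*rng.integers(0, 20, 2), 25)] for a in "ABC"}
        c1 = consensus_regions(AnnotationSet(polygons=polys), (64, 64))
        rev = dict(reversed(list(polys.items())))
        c2 = consensus_regions(AnnotationSet(polygons=rev), (64, 64))
        assert (c1 == c2).all()


class TestConsensusPoints:
    def test_three_coincident_points_are_one_cell(self):
        ann = AnnotationSet(points={a: np.array([[10.0, 10.0]]) for a in "ABC"})
        out = consensus_points(ann)
        assert len(out) == 1 and np.allclose(out[0], (10, 10))

    def test_nine_pixel_separation_is_no_consensus(self):
        ann = AnnotationSet(points={"A": np.array([[10.0, 10.0]]),
                                    "B": np.array([[10.0, 19.0]])})
        assert len(consensus_points(ann)) == 0

    def test_eight_pixel_separation_is_consensus_inclusive(self):
        ann = AnnotationSet(points={"A": np.array([[10.0, 10.0]]),
                                    "B": np.array([[10.0, 18.0]])})
        out = consensus_points(ann)
        assert len(out) == 1 and np.allclose(out[0], (10, 14))

    def test_single_annotator_repeats_do_not_make_consensus(self):
        ann = AnnotationSet(points={"A": np.array([[5.0, 5.0], [6.0, 5.0]]),
                                    "B": np.empty((0, 2))})
        assert len(consensus_points(ann)) == 0


class TestPixelDice:
    def test_identical_nonempty_masks_score_one(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2:5, 2:5] = True
        assert pixel_dice(m, m).dice == 1.0

    def test_disjoint_nonempty_masks_score_zero(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[0, 0] = b[7, 7] = True
        assert pixel_dice(a, b).dice == 0.0

    def test_count_formula(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0] = True                   # |a| = 4
        b[:2, :2] = True              # |b| = 4, overlap 2
        rep = pixel_dice(a, b)
        assert (rep.tp, rep.fp, rep.fn) == (2, 2, 2)
        assert rep.dice == 0.5

    def test_both_empty_is_one_with_flag(self):
        rep = pixel_dice(np.zeros((4, 4)), np.zeros((4, 4)))
        assert rep.dice == 1.0 and rep.flagged

    def test_dice_is_symmetric_and_precision_recall_swap(self):
        rng = np.random.default_rng(1)
        a = rng.random((16, 16)) > 0.5
        b = rng.random((16, 16)) > 0.5
        ab, ba = pixel_dice(a, b), pixel_dice(b, a)
        assert ab.dice == ba.dice
        assert ab.precision == ba.recall and ab.recall == ba.precision


class TestCellDice:
    def test_mask_component_counting(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[2:6, 2:6] = True       # covers two GT points
        mask[20:24, 20:24] = True   # covers nothing -> FP component
        gt = np.array([[3.0, 3.0], [4.0, 4.0], [15.0, 15.0]])
        rep = cell_dice(gt, mask)
        assert (rep.tp, rep.fn, rep.fp) == (2, 1, 1)
        assert rep.dice == pytest.approx(2 * 2 / 6)

    def test_empty_prediction_scores_zero(self):
        gt = np.array([[3.0, 3.0]])
        assert cell_dice(gt, np.zeros((8, 8), dtype=bool)).dice == 0.0

    def test_one_component_per_point_scores_one(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[2:5, 2:5] = True
        mask[20:23, 20:23] = True
        gt = np.array([[3.0, 3.0], [21.0, 21.0]])
        assert cell_dice(gt, mask).dice == 1.0

    def test_point_prediction_matching_is_one_to_one(self):
        gt = np.array([[0.0, 0.0], [0.0, 6.0]])
        pred = np.array([[0.0, 3.0]])       # within 8 px of both GT points
        rep = cell_dice(gt, pred)
        assert (rep.tp, rep.fn, rep.fp) == (1, 1, 0)


class TestPooledDice:
    def test_single_image_equals_pixel_dice(self):
        rng = np.random.default_rng(2)
        a = rng.random((16, 16)) > 0.5
        b = rng.random((16, 16)) > 0.5
        rep = pixel_dice(a, b)
        assert pooled_dice([rep]) == rep.dice

    def test_pooled_differs_from_mean_of_per_image_dice(self):
        pooled = pooled_dice([(1, 0, 3), (3, 0, 1)])
        assert pooled == pytest.approx(2 * 4 / (8 + 0 + 4))      # 0.667
        mean = 0.5 * (2 * 1 / (2 + 3) + 2 * 3 / (6 + 1))
        assert mean == pytest.approx(0.6286, abs=1e-3)
        assert pooled != pytest.approx(mean, abs=1e-3)

    def test_all_empty_images_score_one(self):
        assert pooled_dice([(0, 0, 0), (0, 0, 0)]) == 1.0

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            pooled_dice([])


class TestMorphometrics:
    def test_white_region_has_near_zero_hematoxylin(self):
        white = np.full((16, 16, 3), 255, dtype=np.uint8)
        dark = np.zeros((16, 16, 3), dtype=np.uint8)
        dark[:] = (70, 50, 130)
        region = np.ones((16, 16), dtype=bool)
        assert hematoxylin_intensity(white, region) < \
            hematoxylin_intensity(dark, region)

    def test_dense_nucleus_exceeds_pale_nucleus(self, plain_slide):
        _, hne, _, truth = plain_slide
        nuclei = truth.nucleus_labels > 0
        background = ~nuclei & ~truth.rbc_mask
        assert hematoxylin_intensity(hne, nuclei) > \
            hematoxylin_intensity(hne, background)

    def test_full_patch_region_equals_global_mean(self):
        rng = np.random.default_rng(3)
        patch = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)
        from skimage.color import rgb2hed
        expect = rgb2hed(patch)[..., 0].mean()
        assert hematoxylin_intensity(
            patch, np.ones((16, 16), dtype=bool)) == pytest.approx(expect)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            hematoxylin_intensity(np.zeros((4, 4, 3), dtype=np.uint8),
                                  np.zeros((4, 4), dtype=bool))

    def test_cell_on_rbc_pixel_has_zero_distance(self):
        rbc = np.zeros((16, 16), dtype=bool)
        rbc[5, 5] = True
        px, um = nearest_rbc_distance((5, 5), rbc)
        assert px == 0.0 and um == 0.0

    def test_eight_pixel_distance_converts_to_one_point_seven_seven_um(self):
        rbc = np.zeros((32, 32), dtype=bool)
        rbc[10, 18] = True
        px, um = nearest_rbc_distance((10, 10), rbc)
        assert px == 8.0
        assert um == pytest.approx(1.766544)
        assert round(um, 2) == 1.77

    def test_matches_brute_force_nearest_pixel_scan(self):
        rng = np.random.default_rng(4)
        rbc = rng.random((24, 24)) > 0.9
        if not rbc.any():
            rbc[0, 0] = True
        cell = (12, 7)
        px, _ = nearest_rbc_distance(cell, rbc)
        coords = np.argwhere(rbc)
        brute = np.min(np.linalg.norm(coords - np.array(cell), axis=1))
        assert px == pytest.approx(brute)

    def test_empty_rbc_mask_is_infinite_with_warning(self):
        with pytest.warns(UserWarning):
            px, um = nearest_rbc_distance((0, 0), np.zeros((4, 4), dtype=bool))
        assert np.isinf(px)
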