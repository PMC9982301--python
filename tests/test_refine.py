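"""Cutoff refinement: positive detection, pooled Otsu, propagation, MCC search."""

import numpy as np
import pytest

from restainseg.maskgen import TargetProfile
from restainseg.refine import (detect_positive_patch, histogram_otsu,
                               neighborhood_otsu_cutoff,
                               optimize_overlap_cutoff, propagate_cutoffs,
                               run_refinement)
from tests.conftest import gradient_patch_samples, truth_oracle_predictor


class TestPositiveDetection:
    def test_probability_equal_to_intensity_sits_at_boundary(self):
        rng = np.random.default_rng(0)
        inten = rng.uniform(0, 255, (64, 64))
        prob = inten / 255.0
        beta, max_raw, pos = detect_positive_patch(inten, prob)
        assert beta == pytest.approx(1.0, abs=1e-3)
        assert not pos                       # coefficient must strictly exceed 1

    def test_doubled_slope_on_weak_patch_is_positive(self):
        rng = np.random.default_rng(1)
        inten = rng.uniform(0, 60, (64, 64))
        prob = np.clip(2 * inten / 255.0, 0, 1)
        beta, max_raw, pos = detect_positive_patch(inten, prob)
        assert beta == pytest.approx(2.0, abs=0.01)
        assert max_raw > 10 and pos

    def test_low_maximum_intensity_blocks_positivity(self):
        rng = np.random.default_rng(2)
        inten = rng.uniform(0, 8, (64, 64))
        prob = np.clip(3 * inten / 255.0, 0, 1)
        beta, max_raw, pos = detect_positive_patch(inten, prob)
        assert beta > 1 and max_raw <= 8 and not pos

    def test_rbc_pixels_are_excluded_from_fit_and_maximum(self):
        inten = np.zeros((32, 32))
        inten[:4] = 200.0                     # bright only inside the RBC zone
        rbc = np.zeros((32, 32), dtype=bool)
        rbc[:4] = True
        _, max_raw, pos = detect_positive_patch(inten, np.zeros((32, 32)), rbc)
        assert max_raw == 0.0 and not pos

    def test_all_rbc_patch_is_flagged_negative(self):
        _, _, pos = detect_positive_patch(np.full((8, 8), 100.0),
                                          np.ones((8, 8)),
                                          np.ones((8, 8), dtype=bool))
        assert not pos


def brute_force_otsu(values):
    """Independent oracle: exhaustive between-class-variance maximisation."""
    v = np.clip(np.round(np.asarray(values, dtype=float)), 0, 255).astype(int)
    best, ties = -1.0, []
    for t in range(256):
        lo, hi = v[v <= t], v[v > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(v), len(hi) / len(v)
        sb = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if sb > best + 1e-9:
            best, ties = sb, [t]
        elif abs(sb - best) <= 1e-9:
            ties.append(t)
    return float(np.mean(ties))


class TestNeighborhoodOtsu:
    def test_bimodal_histogram_thresholds_between_modes(self):
        values = np.array([5.0] * 500 + [60.0] * 300)
        t = neighborhood_otsu_cutoff(values, [])
        assert t == pytest.approx(32, abs=1.0)

    def test_low_bimodal_histogram_is_clipped_to_ten(self):
        values = np.array([2.0] * 500 + [8.0] * 300)
        assert neighborhood_otsu_cutoff(values, []) == 10.0

    def test_epithelium_reduction_is_twenty_percent_after_clipping(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(5, 1, 800),
                                 rng.normal(70, 5, 400)])
        plain = neighborhood_otsu_cutoff(values, [])
        epi = neighborhood_otsu_cutoff(values, [], epithelium=True)
        assert epi == pytest.approx(0.8 * plain)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate([rng.normal(rng.uniform(3, 20), 2, 500),
                                 rng.normal(rng.uniform(40, 90), 6, 200)])
        assert histogram_otsu(values) == pytest.approx(brute_force_otsu(values))

    def test_neighbors_beyond_k_are_ignored(self):
        patch = np.array([5.0] * 100 + [60.0] * 100)
        near = [patch.copy() for _ in range(8)]
        far = [np.full(200, 255.0)]
        with_far = neighborhood_otsu_cutoff(patch, near + far, k=8)
        without = neighborhood_otsu_cutoff(patch, near, k=8)
        assert with_far == without


class TestPropagation:
    def test_single_positive_dominates_everywhere(self):
        centers = np.array([[0, 0], [0, 5000], [9000, 9000]])
        out = propagate_cutoffs(centers, np.array([[0, 5000]]), np.array([30.0]))
        assert np.allclose(out, 30.0)

    def test_equidistant_pair_averages(self):
        centers = np.array([[0.0, 0.0]])
        pos = np.array([[0, -1000], [0, 1000]])
        out = propagate_cutoffs(centers, pos, np.array([20.0, 40.0]))
        assert out[0] == pytest.approx(30.0)

    def test_gaussian_weight_formula(self):
        centers = np.array([[0.0, 0.0]])
        pos = np.array([[0.0, 0.0], [0.0, 6000.0]])
        out = propagate_cutoffs(centers, pos, np.array([20.0, 40.0]),
                                sigma_px=3000.0)
        expect = (20 + 40 * np.exp(-2)) / (1 + np.exp(-2))
        assert out[0] == pytest.approx(expect)    # ~= 22.4

    def test_result_is_convex_combination_of_positive_cutoffs(self):
        rng = np.random.default_rng(4)
        centers = rng.uniform(0, 20000, (40, 2))
        pos = rng.uniform(0, 20000, (12, 2))
        cuts = rng.uniform(10, 50, 12)
        out = propagate_cutoffs(centers, pos, cuts)
        assert (out >= cuts.min() - 1e-9).all()
        assert (out <= cuts.max() + 1e-9).all()

    def test_no_positive_patches_raises(self):
        with pytest.raises(ValueError):
            propagate_cutoffs(np.zeros((3, 2)), np.empty((0, 2)), np.empty(0))


def brute_force_mcc(pred, cand):
    tp = np.count_nonzero(pred & cand)
    fp = np.count_nonzero(~pred & cand)
    tn = np.count_nonzero(~pred & ~cand)
    fn = np.count_nonzero(pred & ~cand)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if denom == 0 else (tp * tn - fp * fn) / denom


class TestOverlapOptimization:
    def test_exact_match_at_forty_percent(self):
        rng = np.random.default_rng(5)
        target = rng.random((32, 32)) > 0.6

        def candidates(rate):
            if abs(rate - 0.40) < 1e-9:
                return [target]
            return [rng.random((32, 32)) > 0.9]

        assert optimize_overlap_cutoff([target], candidates) == 0.40

    def test_equals_brute_force_grid_on_three_patch_toy(self):
        rng = np.random.default_rng(6)
        preds = [rng.random((16, 16)) > 0.5 for _ in range(3)]
        pool = {round(0.10 + 0.05 * i, 2): [rng.random((16, 16)) > 0.5
                                            for _ in range(3)]
                for i in range(15)}

        def candidates(rate):
            return pool[round(rate, 2)]

        result = optimize_overlap_cutoff(preds, candidates)
        # oracle: pooled-count MCC evaluated exhaustively per grid point
        best_rate, best = None, -np.inf
        for rate in sorted(pool):
            p = np.concatenate([m.ravel() for m in preds])
            c = np.concatenate([m.ravel() for m in pool[rate]])
            mcc = brute_force_mcc(p, c)
            if mcc > best:
                best, best_rate = mcc, rate
        assert result == pytest.approx(best_rate)

    def test_ties_break_toward_the_lower_rate(self):
        pred = np.ones((4, 4), dtype=bool)

        def candidates(rate):
            return [pred]                  # perfect at every rate

        assert optimize_overlap_cutoff([pred], candidates) == 0.10


class TestRefinementLoop:
    def test_zero_predictor_flags_slide_and_keeps_initial_cutoffs(
            self, gradient_slide):
        _, hne, if_img, truth = gradient_slide
        samples, _, _ = gradient_patch_samples(hne, if_img, truth)
        profile = TargetProfile.for_target("aSMA")
        res = run_refinement(samples, lambda s: np.zeros(s.if_target.shape),
                             profile, sigma_px=600.0)
        assert res.thresholds.flagged
        assert np.allclose(res.thresholds.cutoffs(), profile.initial_cutoff)

    def test_oracle_predictor_recovers_gradient_and_converges(
            self, gradient_slide):
        from scipy.stats import pearsonr

        from restainseg.evaluate import pixel_dice, pooled_dice
        _, hne, if_img, truth = gradient_slide
        samples, gts, true_cut = gradient_patch_samples(hne, if_img, truth)
        profile = TargetProfile.for_target("aSMA")
        res = run_refinement(samples, truth_oracle_predictor(truth), profile,
                             n_iterations=2, sigma_px=600.0)
        cut = np.array([res.thresholds.entries[s.patch_id].cutoff
                        for s in samples])
        assert pearsonr(cut, true_cut)[0] > 0.9
        dice = pooled_dice([pixel_dice(g, m) for g, m in zip(gts, res.masks)])
        assert dice > 0.95
        assert len(res.flip_fractions) == 2
        assert res.flip_fractions[1] <= res.flip_fractions[0]

    def test_contract_violation_aborts(self, gradient_slide):
        _, hne, if_img, truth = gradient_slide
        samples, _, _ = gradient_patch_samples(hne, if_img, truth)
        profile = TargetProfile.for_target("aSMA")
        with pytest.raises(ValueError, match="contract"):
            run_refinement(samples, lambda s: np.full(s.if_target.shape, 2.0),
                           profile, sigma_px=600.0)
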