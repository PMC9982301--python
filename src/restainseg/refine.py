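"""Iterative refinement of per-patch intensity cutoffs.

Restained sections stain unevenly, so one global IF cutoff per slide is
wrong.  Given any per-pixel probability predictor (in production a
trained segmentation network; in tests an oracle built from ground
truth), each round

1. detects patches that actually contain positive cells — a
   zero-intercept ridge regression of the smoothed probability map on
   the smoothed, [0,1]-normalised IF intensity (RBC pixels excluded); a
   patch is positive when the coefficient exceeds 1 and its maximum
   RBC-free raw intensity exceeds 10;
2. assigns each positive patch an Otsu cutoff pooled with its 8 nearest
   positive patches, clipped to [10, 50] (epithelium: then reduced 20%);
3. propagates cutoffs to every patch as a Gaussian-weighted mean
   (scale 3000 px) of its 16 nearest positive patches;
4. for nucleus-transfer targets, grid-searches the nucleus-overlap rate
   in [0.10, 0.80] (step 0.05) for maximal pooled Matthews correlation
   against the predictor's masks.

Two rounds suffice; the pixel-flip fraction between rounds reports
convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .maskgen import TargetProfile, make_initial_mask

CUTOFF_CLIP = (10.0, 50.0)
EPITHELIUM_REDUCTION = 0.8
POSITIVE_COEFF_MIN = 1.0
POSITIVE_INTENSITY_MIN = 10.0
PROPAGATE_SIGMA_PX = 3000.0


@dataclass
class PatchSample:
    """One registered patch as seen by the refinement loop."""

    if_target: np.ndarray                 # raw 8-bit IF target channel
    center_level0: tuple[float, float]
    hne: np.ndarray | None = None
    rbc_mask: np.ndarray | None = None
    nuclei: object | None = None          # NucleusInstanceMap for transfer targets
    patch_id: str = ""


@dataclass
class ThresholdEntry:
    cutoff: float
    regression_coefficient: float
    max_if_intensity: float
    is_positive: bool
    center_level0: tuple[float, float]


@dataclass
class ThresholdMap:
    entries: dict[str, ThresholdEntry] = field(default_factory=dict)
    flagged: bool = False                  # no positive patch found on the slide

    def cutoffs(self) -> np.ndarray:
        return np.array([e.cutoff for e in self.entries.values()])


def _smooth(img: np.ndarray, kernel: int = 11) -> np.ndarray:
    sigma = (kernel - 1) / 6.0
    radius = (kernel - 1) // 2
    return ndimage.gaussian_filter(np.asarray(img, dtype=float), sigma,
                                   truncate=radius / sigma)


def detect_positive_patch(if_intensity: np.ndarray, prob_map: np.ndarray,
                          rbc_mask: np.ndarray | None = None,
                          ridge_alpha: float = 1e-3,
                          blur_kernel: int = 11,
                          coeff_min: float = POSITIVE_COEFF_MIN,
                          intensity_min: float = POSITIVE_INTENSITY_MIN,
                          ) -> tuple[float, float, bool]:
    """Ridge-regression positive-cell detection for one patch.

    Returns (regression coefficient, max RBC-free raw intensity,
    is_positive).  The fit is y = beta * x with no intercept, x the
    [0,1]-normalised smoothed intensity and y the smoothed probability;
    beta = sum(xy) / (sum(x^2) + alpha).
    """
    inten = np.asarray(if_intensity, dtype=float)
    prob = np.asarray(prob_map, dtype=float)
    if inten.shape != prob.shape:
        raise ValueError("intensity and probability maps must share shape")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map must lie in [0, 1]")
    keep = np.ones(inten.shape, dtype=bool) if rbc_mask is None \
        else ~np.asarray(rbc_mask, dtype=bool)
    if not keep.any():
        return 0.0, 0.0, False
    x = _smooth(inten / 255.0, blur_kernel)[keep]
    y = _smooth(prob, blur_kernel)[keep]
    denom = float(x @ x) + ridge_alpha
    beta = float(x @ y) / denom if denom > 0 else 0.0
    max_raw = float(inten[keep].max())
    return beta, max_raw, bool(beta > coeff_min and max_raw > intensity_min)


def histogram_otsu(values: np.ndarray) -> float:
    """Otsu threshold of pooled 8-bit intensities, plateau ties at the centre.

    Maximises the between-class variance over all integer thresholds t
    (class 0: value <= t).  When the histogram has an empty gap between
    its modes every t inside the gap scores identically; the centre of
    the tied plateau is returned, so a bimodal histogram at 5 and 60
    thresholds near 32 rather than at the edge of the background mode.
    """
    v = np.clip(np.round(np.asarray(values, dtype=float)), 0, 255).astype(int)
    hist = np.bincount(v.ravel(), minlength=256).astype(float)
    total = hist.sum()
    if total == 0:
        return 0.0
    p = hist / total
    omega = np.cumsum(p)
    mu = np.cumsum(p * np.arange(256))
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    valid = (omega > 0) & (omega < 1)
    if not valid.any():
        return float(v.max())
    sigma_b[~valid] = -np.inf
    best = sigma_b.max()
    ties = np.flatnonzero(sigma_b >= best - 1e-10 * max(best, 1.0))
    return float(ties.mean())


def neighborhood_otsu_cutoff(patch: np.ndarray,
                             neighbor_patches: list[np.ndarray],
                             k: int = 8, epithelium: bool = False,
                             clip: tuple[float, float] = CUTOFF_CLIP,
                             reduction: float = EPITHELIUM_REDUCTION) -> float:
    """Otsu cutoff over the pooled histogram of a patch and its neighbours.

    ``neighbor_patches`` must already be sorted by distance; at most the
    first ``k`` are pooled (all of them when fewer are available).  The
    threshold is clipped to ``clip``; epithelium cutoffs are then
    reduced by 20% (nuclear pan-CK signal is weaker than cytoplasmic).
    """
    pool = [np.asarray(patch, dtype=float).ravel()]
    pool += [np.asarray(p, dtype=float).ravel() for p in neighbor_patches[:k]]
    t = histogram_otsu(np.concatenate(pool))
    t = float(np.clip(t, *clip))
    if epithelium:
        t *= reduction
    return t


def propagate_cutoffs(all_centers: np.ndarray, positive_centers: np.ndarray,
                      positive_cutoffs: np.ndarray, k: int = 16,
                      sigma_px: float = PROPAGATE_SIGMA_PX) -> np.ndarray:
    """Gaussian-weighted cutoff for every patch from its k nearest positives.

    w_i = exp(-d_i^2 / (2 sigma^2)) over the k nearest positive patches
    by centre distance; the result is a convex combination of positive
    cutoffs.  Raises when no positive patch exists.
    """
    all_centers = np.atleast_2d(np.asarray(all_centers, dtype=float))
    positive_centers = np.atleast_2d(np.asarray(positive_centers, dtype=float))
    positive_cutoffs = np.asarray(positive_cutoffs, dtype=float)
    if len(positive_centers) == 0:
        raise ValueError("no positive patches to propagate from")
    out = np.empty(len(all_centers))
    for i, c in enumerate(all_centers):
        d = np.linalg.norm(positive_centers - c, axis=1)
        order = np.argsort(d, kind="stable")[:k]
        w = np.exp(-d[order] ** 2 / (2.0 * sigma_px ** 2))
        if w.sum() == 0:          # numerically all-zero at extreme distance
            w = np.ones_like(w)
        out[i] = float(np.sum(w * positive_cutoffs[order]) / w.sum())
    return out


def _mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / denom)


def optimize_overlap_cutoff(prediction_masks: list[np.ndarray],
                            candidate_masks_fn,
                            rate_range: tuple[float, float] = (0.10, 0.80),
                            step: float = 0.05) -> float:
    """Nucleus-overlap rate maximising the pooled pixelwise MCC.

    ``candidate_masks_fn(rate)`` returns the candidate masks at a given
    overlap rate (same order/shapes as ``prediction_masks``).  Counts
    are pooled over all patches before computing one MCC per grid
    point; grid points with an undefined MCC score 0; ties break toward
    the lower rate.
    """
    n_steps = int(round((rate_range[1] - rate_range[0]) / step)) + 1
    rates = np.round(rate_range[0] + step * np.arange(n_steps), 10)
    best_rate, best_mcc = None, -np.inf
    for rate in rates:
        cands = candidate_masks_fn(float(rate))
        tp = fp = tn = fn = 0
        for pred, cand in zip(prediction_masks, cands):
            p = np.asarray(pred, dtype=bool)
            c = np.asarray(cand, dtype=bool)
            tp += int(np.count_nonzero(p & c))
            fp += int(np.count_nonzero(~p & c))
            tn += int(np.count_nonzero(~p & ~c))
            fn += int(np.count_nonzero(p & ~c))
        mcc = _mcc_from_counts(tp, fp, tn, fn)
        if mcc > best_mcc:
            best_mcc, best_rate = mcc, float(rate)
    return best_rate


# ---------------------------------------------------------------------------
# full loop
# ---------------------------------------------------------------------------

@dataclass
class RefinementResult:
    thresholds: ThresholdMap
    masks: list[np.ndarray]
    overlap_cutoff: float
    flip_fractions: list[float]


def run_refinement(samples: list[PatchSample], predictor,
                   profile: TargetProfile,
                   initial_masks: list[np.ndarray] | None = None,
                   n_iterations: int = 2, k_otsu: int = 8,
                   k_propagate: int = 16, sigma_px: float = PROPAGATE_SIGMA_PX,
                   clip: tuple[float, float] = CUTOFF_CLIP,
                   mcc_range: tuple[float, float] = (0.10, 0.80),
                   mcc_step: float = 0.05,
                   overlap_cutoff: float = 0.40) -> RefinementResult:
    """Run ``n_iterations`` of cutoff refinement over one slide's patches.

    ``predictor(patch_sample) -> probability map`` is any conforming
    per-pixel predictor.  Masks are regenerated from the propagated
    cutoffs after each round; the flip fraction (changed pixels /
    total) between consecutive mask generations reports convergence.
    """
    centers = np.array([s.center_level0 for s in samples], dtype=float)
    if initial_masks is None:
        masks = [make_initial_mask(s.if_target, s.hne, profile, nuclei=s.nuclei,
                                   rbc_prediction=s.rbc_mask)
                 for s in samples]
    else:
        masks = list(initial_masks)
    thresholds = ThresholdMap()
    flip_fractions = []

    for _ in range(n_iterations):
        probs = []
        for s in samples:
            p = np.asarray(predictor(s), dtype=float)
            if p.shape != s.if_target.shape[:2] or p.min() < 0 or p.max() > 1:
                raise ValueError("predictor violated its contract "
                                 "(shape mismatch or values outside [0, 1])")
            probs.append(p)

        entries = {}
        pos_idx = []
        for i, s in enumerate(samples):
            beta, max_raw, is_pos = detect_positive_patch(
                s.if_target, probs[i], s.rbc_mask)
            entries[s.patch_id or str(i)] = ThresholdEntry(
                cutoff=float("nan"), regression_coefficient=beta,
                max_if_intensity=max_raw, is_positive=is_pos,
                center_level0=s.center_level0)
            if is_pos:
                pos_idx.append(i)

        if not pos_idx:
            thresholds = ThresholdMap(entries=entries, flagged=True)
            for key in entries:
                entries[key].cutoff = profile.initial_cutoff
            break

        # per-positive-patch neighbourhood Otsu
        pos_centers = centers[pos_idx]
        pos_cutoffs = np.empty(len(pos_idx))
        for j, i in enumerate(pos_idx):
            d = np.linalg.norm(pos_centers - centers[i], axis=1)
            order = [pos_idx[m] for m in np.argsort(d, kind="stable")
                     if pos_idx[m] != i]
            neighbors = [samples[m].if_target for m in order]
            pos_cutoffs[j] = neighborhood_otsu_cutoff(
                samples[i].if_target, neighbors, k=k_otsu,
                epithelium=profile.epithelium_flag, clip=clip)

        propagated = propagate_cutoffs(centers, pos_centers, pos_cutoffs,
                                       k=k_propagate, sigma_px=sigma_px)
        for key, c in zip(entries, propagated):
            entries[key].cutoff = float(c)
        thresholds = ThresholdMap(entries=entries)

        if profile.mask_mode == "nucleus_transfer":
            def candidates(rate: float):
                return [make_initial_mask(s.if_target, s.hne, profile,
                                          nuclei=s.nuclei,
                                          rbc_prediction=s.rbc_mask,
                                          cutoff=propagated[i],
                                          overlap_cutoff=rate)
                        for i, s in enumerate(samples)]
            pred_masks = [p > 0.5 for p in probs]
            overlap_cutoff = optimize_overlap_cutoff(pred_masks, candidates,
                                                     mcc_range, mcc_step)

        new_masks = [make_initial_mask(s.if_target, s.hne, profile,
                                       nuclei=s.nuclei,
                                       rbc_prediction=s.rbc_mask,
                                       cutoff=propagated[i],
                                       overlap_cutoff=overlap_cutoff)
                     for i, s in enumerate(samples)]
        flips = sum(int(np.count_nonzero(a != b))
                    for a, b in zip(masks, new_masks))
        total = sum(m.size for m in masks)
        flip_fractions.append(flips / total if total else 0.0)
        masks = new_masks

    return RefinementResult(thresholds, masks, overlap_cutoff, flip_fractions)
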