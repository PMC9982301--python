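"""H&E <-> IF alignment cascade.

The IF image is registered onto its H&E counterpart using nuclear
content only: the hematoxylin component of the colour-deconvolved H&E
patch against the DAPI channel of the IF patch.  The cascade runs

1. whole-slide rigid (phase correlation) at a coarse pyramid level,
2. per-patch rigid at an intermediate level with a slide-wide KDE
   consensus over all per-patch translations,
3. two more per-patch rigid rounds at the intermediate and full levels,
4. histogram-matched Demons non-rigid refinement, and
5. a 20-px margin crop so no unregistered border survives,

producing (size - 40)^2 aligned patch pairs (984^2 for 1024-px patches).
Rigid estimates are integer-pixel; sub-pixel residuals are left to the
Demons stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates
from scipy.stats import gaussian_kde
from skimage.color import rgb2hed
from skimage.registration import phase_cross_correlation
from skimage.transform import downscale_local_mean

from .preprocess import PatchRecord


@dataclass
class TranslationEstimate:
    dy: float
    dx: float
    level: int = 0
    peak_response: float = 1.0

    def as_tuple(self) -> tuple[float, float]:
        return (self.dy, self.dx)


@dataclass
class RegisteredPair:
    hne_patch: np.ndarray          # RGB, cropped
    if_patch: np.ndarray           # 2-channel, cropped and aligned
    translation: TranslationEstimate
    deformation: np.ndarray        # (H, W, 2) field on the uncropped patch
    provenance: PatchRecord | None = None


class ImagePyramid:
    """Serves 1/2**level downsampled views of an in-memory full-resolution image."""

    def __init__(self, level0: np.ndarray):
        self.level0 = np.asarray(level0)
        self._cache: dict[int, np.ndarray] = {0: self.level0}

    def level(self, k: int) -> np.ndarray:
        if k not in self._cache:
            f = 2 ** k
            img = self.level0.astype(np.float32)
            if img.ndim == 2:
                down = downscale_local_mean(img, (f, f))
            else:
                down = downscale_local_mean(img, (f, f, 1))
            self._cache[k] = down
        return self._cache[k]


def alignment_channels(hne: np.ndarray, if_img: np.ndarray):
    """(hematoxylin, DAPI) maps in [0, 1] used to drive the registration."""
    hed = rgb2hed(np.clip(np.asarray(hne, dtype=float), 0, 255).astype(np.uint8))
    hema = hed[..., 0]
    lo, hi = hema.min(), hema.max()
    hema = (hema - lo) / (hi - lo) if hi > lo else np.zeros_like(hema)
    dapi = np.asarray(if_img, dtype=float)[..., 0] / 255.0
    return hema, dapi


def estimate_rigid_shift(fixed: np.ndarray, moving: np.ndarray,
                         level: int = 0) -> TranslationEstimate:
    """Integer translation that, applied to ``moving``, best aligns it to ``fixed``.

    Phase correlation; for a moving image that is the fixed image
    circularly shifted by (dy, dx) the estimate is exactly (-dy, -dx).
    Constant (zero-variance) inputs yield a zero shift flagged with
    ``peak_response`` 0.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must share shape")
    if fixed.std() == 0 or moving.std() == 0:
        return TranslationEstimate(0.0, 0.0, level, 0.0)
    shift, _, _ = phase_cross_correlation(fixed, moving, upsample_factor=1,
                                          normalization="phase")
    dy, dx = float(round(shift[0])), float(round(shift[1]))
    rolled = np.roll(moving, (int(dy), int(dx)), axis=(0, 1))
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(fixed.ravel(), rolled.ravel())[0, 1]
    peak = 0.0 if np.isnan(r) else float(max(r, 0.0))
    return TranslationEstimate(dy, dx, level, peak)


def consensus_shift(shifts: list[TranslationEstimate]) -> TranslationEstimate:
    """Slide-wide translation: the input shift of maximal Gaussian-KDE density.

    Bandwidth follows Scott's rule.  Degenerate point sets (all equal or
    collinear, where the KDE covariance is singular) fall back to the
    modal point.  Invariant to input ordering.
    """
    if not shifts:
        raise ValueError("need at least one shift")
    pts = np.array([[s.dy, s.dx] for s in shifts], dtype=float)
    if len(pts) == 1:
        s = shifts[0]
        return TranslationEstimate(s.dy, s.dx, s.level, s.peak_response)
    best_idx = None
    try:
        kde = gaussian_kde(pts.T)
        dens = kde(pts.T)
        best_idx = int(np.argmax(dens))
    except np.linalg.LinAlgError:
        vals, counts = np.unique(pts, axis=0, return_counts=True)
        mode = vals[int(np.argmax(counts))]
        d2 = ((pts - mode) ** 2).sum(axis=1)
        best_idx = int(np.argmin(d2))
    s = shifts[best_idx]
    return TranslationEstimate(s.dy, s.dx, s.level, s.peak_response)


# ---------------------------------------------------------------------------
# Demons
# ---------------------------------------------------------------------------

def demons_refine(fixed: np.ndarray, moving: np.ndarray,
                  shrink_factors=(8, 4, 2), smoothing_sigmas=(12.0, 8.0, 4.0),
                  learning_rate: float = 1.0, iterations: int = 20,
                  variant: str = "metric",
                  histogram_match: bool = True) -> np.ndarray:
    """Dense displacement field aligning ``moving`` onto ``fixed``.

    Three-level multi-resolution Demons (shrink 8/4/2, smoothing sigmas
    12/8/4).  The default "metric" variant optimises the Demons metric
    over a displacement-field transform by gradient descent (learning
    rate 1.0, 20 iterations); "filter" uses the classic Demons filter
    per pyramid level.  The moving image is histogram-matched to the
    fixed image first.  Returns an (H, W, 2) array of (dy, dx); warping
    ``moving`` with :func:`apply_deformation` realises the alignment.
    """
    fixed = np.ascontiguousarray(fixed, dtype=np.float32)
    moving = np.ascontiguousarray(moving, dtype=np.float32)
    F = sitk.GetImageFromArray(fixed)
    M = sitk.GetImageFromArray(moving)
    if histogram_match and moving.std() > 0 and fixed.std() > 0:
        M = sitk.HistogramMatching(M, F, numberOfHistogramLevels=256,
                                   numberOfMatchPoints=7,
                                   thresholdAtMeanIntensity=True)
    if variant == "metric":
        init = sitk.Image(F.GetSize(), sitk.sitkVectorFloat64)
        init.CopyInformation(F)
        tx = sitk.DisplacementFieldTransform(init)
        tx.SetSmoothingGaussianOnUpdate(varianceForUpdateField=0.0,
                                        varianceForTotalField=2.0)
        reg = sitk.ImageRegistrationMethod()
        reg.SetInitialTransform(tx)
        reg.SetMetricAsDemons(0.001)
        reg.SetShrinkFactorsPerLevel(list(shrink_factors))
        reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
        reg.SetOptimizerAsGradientDescent(learningRate=learning_rate,
                                          numberOfIterations=iterations)
        reg.SetInterpolator(sitk.sitkLinear)
        out_tx = reg.Execute(F, M)
        field_img = sitk.TransformToDisplacementField(
            out_tx, sitk.sitkVectorFloat64, F.GetSize(), F.GetOrigin(),
            F.GetSpacing(), F.GetDirection())
    elif variant == "filter":
        demons = sitk.DemonsRegistrationFilter()
        demons.SetNumberOfIterations(iterations)
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(2.0)
        field_img = None
        for shrink, sigma in zip(shrink_factors, smoothing_sigmas):
            f_l = sitk.SmoothingRecursiveGaussian(F, sigma * F.GetSpacing()[0])
            f_l = sitk.Shrink(f_l, [shrink, shrink])
            m_l = sitk.SmoothingRecursiveGaussian(M, sigma * M.GetSpacing()[0])
            m_l = sitk.Shrink(m_l, [shrink, shrink])
            if field_img is None:
                field_img = demons.Execute(f_l, m_l)
            else:
                field_img = demons.Execute(
                    f_l, m_l, sitk.Resample(field_img, f_l, sitk.Transform(),
                                            sitk.sitkLinear))
        field_img = sitk.Resample(field_img, F, sitk.Transform(), sitk.sitkLinear)
    else:
        raise ValueError(f"unknown demons variant {variant!r}")
    field = sitk.GetArrayFromImage(field_img)     # (H, W, [dx, dy]) in index space
    field = field[..., ::-1].astype(np.float32)   # -> (dy, dx)
    if not np.isfinite(field).all():
        raise ValueError("non-finite displacement field")
    return field


def apply_deformation(img: np.ndarray, field: np.ndarray,
                      order: int = 1) -> np.ndarray:
    """Resample ``img`` through the displacement field: out(p) = img(p + field(p)).

    Bilinear for intensity images (order 1), nearest for masks (order 0).
    Out-of-bounds samples replicate the edge — they live inside the
    sacrificial registration margin.
    """
    h, w = img.shape[:2]
    rr, cc = np.meshgrid(np.arange(h, dtype=np.float32),
                         np.arange(w, dtype=np.float32), indexing="ij")
    src_r = rr + field[..., 0]
    src_c = cc + field[..., 1]
    if img.ndim == 2:
        return map_coordinates(img.astype(np.float32), [src_r, src_c],
                               order=order, mode="nearest")
    out = np.stack([map_coordinates(img[..., k].astype(np.float32),
                                    [src_r, src_c], order=order, mode="nearest")
                    for k in range(img.shape[2])], axis=-1)
    return out


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def _extract_window(img: np.ndarray, origin: tuple[int, int],
                    size: int) -> np.ndarray:
    """Half-open window with edge replication when it overruns the image."""
    h, w = img.shape[:2]
    r0, c0 = int(origin[0]), int(origin[1])
    pad_top = max(-r0, 0)
    pad_left = max(-c0, 0)
    pad_bottom = max(r0 + size - h, 0)
    pad_right = max(c0 + size - w, 0)
    rs, cs = max(r0, 0), max(c0, 0)
    win = img[rs:min(r0 + size, h), cs:min(c0 + size, w)]
    if pad_top or pad_left or pad_bottom or pad_right:
        pads = [(pad_top, pad_bottom), (pad_left, pad_right)]
        if img.ndim == 3:
            pads.append((0, 0))
        win = np.pad(win, pads, mode="edge")
    return win


def register_slide(hne_wsi: np.ndarray, if_wsi: np.ndarray,
                   patches: list[PatchRecord],
                   coarse_level: int = 6, patch_level: int = 1,
                   margin: int = 20, run_demons: bool = True,
                   demons_kwargs: dict | None = None) -> list[RegisteredPair]:
    """Full registration cascade on one slide pair.

    ``hne_wsi`` (RGB) and ``if_wsi`` (2-channel, DAPI first) are
    full-resolution arrays; pyramid levels are derived by block
    averaging.  Patches fully outside the IF extent after the consensus
    shift are dropped.
    """
    hne_pyr = ImagePyramid(hne_wsi)
    if_pyr = ImagePyramid(if_wsi)

    # (1) coarse whole-slide rigid alignment
    hema_c, dapi_c = alignment_channels(hne_pyr.level(coarse_level),
                                        if_pyr.level(coarse_level))
    coarse = estimate_rigid_shift(hema_c, dapi_c, level=coarse_level)
    scale_c = 2 ** coarse_level
    slide_shift = np.array([coarse.dy * scale_c, coarse.dx * scale_c])

    # (2) per-patch rigid at the intermediate level + KDE consensus
    scale_p = 2 ** patch_level
    hne_p = hne_pyr.level(patch_level)
    if_p = if_pyr.level(patch_level)
    size_p = max(patches[0].size_px // scale_p, 32) if patches else 0
    per_patch = []
    for patch in patches:
        origin_p = (patch.origin_level0[0] // scale_p,
                    patch.origin_level0[1] // scale_p)
        hne_tile = _extract_window(hne_p, origin_p, size_p)
        if_origin = (origin_p[0] - slide_shift[0] / scale_p,
                     origin_p[1] - slide_shift[1] / scale_p)
        if_tile = _extract_window(if_p, (round(if_origin[0]), round(if_origin[1])),
                                  size_p)
        hema, dapi = alignment_channels(hne_tile, if_tile)
        per_patch.append(estimate_rigid_shift(hema, dapi, level=patch_level))
    if per_patch:
        cons = consensus_shift(per_patch)
        slide_shift = slide_shift + np.array([cons.dy * scale_p, cons.dx * scale_p])

    demons_kwargs = demons_kwargs or {}
    h_if, w_if = if_wsi.shape[:2]
    pairs = []
    for patch in patches:
        size = patch.size_px
        r0, c0 = patch.origin_level0
        hne_tile = _extract_window(hne_wsi, (r0, c0), size)
        shift = slide_shift.copy()

        if_origin = (r0 - shift[0], c0 - shift[1])
        if (if_origin[0] + size <= 0 or if_origin[0] >= h_if or
                if_origin[1] + size <= 0 or if_origin[1] >= w_if):
            patch.flag("outside_if_extent")
            continue

        # (3)+(4) two per-patch rigid rounds: intermediate level, then full
        for lvl in (patch_level, 0):
            s = 2 ** lvl
            if_tile = _extract_window(if_wsi, (round(r0 - shift[0]),
                                               round(c0 - shift[1])), size)
            if lvl > 0:
                hne_l = downscale_local_mean(hne_tile.astype(np.float32),
                                             (s, s, 1))
                if_l = downscale_local_mean(if_tile.astype(np.float32), (s, s, 1))
            else:
                hne_l, if_l = hne_tile, if_tile
            hema, dapi = alignment_channels(hne_l, if_l)
            est = estimate_rigid_shift(hema, dapi, level=lvl)
            # estimates are correcting translations and compose additively
            shift = shift + np.array([est.dy * s, est.dx * s])

        if_tile = _extract_window(if_wsi, (round(r0 - shift[0]),
                                           round(c0 - shift[1])), size)

        # (5) non-rigid refinement on the nuclear channels
        hema, dapi = alignment_channels(hne_tile, if_tile)
        if run_demons:
            field = demons_refine(hema * 255.0, dapi * 255.0, **demons_kwargs)
            if_aligned = apply_deformation(if_tile.astype(np.float32), field)
        else:
            field = np.zeros((size, size, 2), dtype=np.float32)
            if_aligned = if_tile.astype(np.float32)

        # (6) margin crop
        m = margin
        pairs.append(RegisteredPair(
            hne_patch=np.asarray(hne_tile)[m:size - m, m:size - m],
            if_patch=np.clip(if_aligned, 0, 255).astype(np.uint8)[m:size - m,
                                                                  m:size - m],
            translation=TranslationEstimate(float(shift[0]), float(shift[1]), 0,
                                            est.peak_response),
            deformation=field,
            provenance=patch))
    return pairs
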