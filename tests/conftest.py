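"""Shared synthetic-slide fixtures.

Everything is generated programmatically; the expensive slide pairs and
registration runs are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from restainseg import fixtures as fx
from restainseg.preprocess import PatchRecord
from restainseg.refine import PatchSample
from restainseg.registration import alignment_channels, register_slide


@pytest.fixture(scope="session")
def plain_slide():
    """Aligned (zero-shift) single-spot slide: nuclei + RBCs, no deformation."""
    spec = fx.FixtureSpec(image_height_px=768, image_width_px=768,
                          n_spots=1, nuclei_per_spot=30, positive_fraction=0.5,
                          global_shift_px=(0.0, 0.0), rbc_count=5,
                          if_gradient=(80.0, 0.0), seed=11)
    return spec, *fx.generate_slide_pair(spec)


@pytest.fixture(scope="session")
def shifted_slide():
    """Slide pair offset by a pure (12, -9) px translation."""
    spec = fx.FixtureSpec(image_height_px=1300, image_width_px=1300,
                          global_shift_px=(12.0, -9.0), seed=3)
    return spec, *fx.generate_slide_pair(spec)


@pytest.fixture(scope="session")
def warped_slide():
    """Translation (12, -9) plus a smooth 3-px-amplitude deformation."""
    spec = fx.FixtureSpec(image_height_px=1300, image_width_px=1300,
                          global_shift_px=(12.0, -9.0),
                          deformation_amplitude_px=3.0,
                          deformation_smoothness_px=60.0, seed=4)
    return spec, *fx.generate_slide_pair(spec)


@pytest.fixture(scope="session")
def gradient_slide():
    """Aligned 4-spot slide whose true IF cutoff rises linearly across columns."""
    spec = fx.FixtureSpec(image_height_px=1024, image_width_px=1024,
                          n_spots=4, nuclei_per_spot=40, positive_fraction=0.6,
                          global_shift_px=(0.0, 0.0), rbc_count=4,
                          if_gradient=(40.0, 0.04), seed=7)
    return spec, *fx.generate_slide_pair(spec)


def gradient_patch_samples(hne, if_img, truth, size=256):
    """Cut a slide into a regular grid of refinement patch samples."""
    samples, gts, true_cutoffs = [], [], []
    h, w = hne.shape[:2]
    for r in range(0, h - size + 1, size):
        for c in range(0, w - size + 1, size):
            samples.append(PatchSample(
                if_target=if_img[r:r + size, c:c + size, 1].astype(float),
                hne=hne[r:r + size, c:c + size],
                rbc_mask=truth.rbc_mask[r:r + size, c:c + size],
                center_level0=(r + size / 2, c + size / 2),
                patch_id=f"p_{r}_{c}"))
            gts.append(truth.true_mask[r:r + size, c:c + size])
            true_cutoffs.append(float(
                truth.per_region_cutoff[r + size // 2, c + size // 2]))
    return samples, gts, np.asarray(true_cutoffs)


def truth_oracle_predictor(truth, size=256):
    """Predictor contract filled by ground truth: P(positive) = true mask."""
    def predict(sample: PatchSample) -> np.ndarray:
        r = int(sample.center_level0[0] - size / 2)
        c = int(sample.center_level0[1] - size / 2)
        return truth.true_mask[r:r + size, c:c + size].astype(float)
    return predict


def mean_nucleus_residual(pair, truth, patch_origin, margin=20, window=36):
    """Mean offset between true nucleus centroids and aligned DAPI centroids."""
    _, dapi = alignment_channels(pair.hne_patch, pair.if_patch)
    size = dapi.shape[0]
    off = patch_origin[0] + margin, patch_origin[1] + margin
    errs = []
    half = window // 2
    for k in range(1, truth.nucleus_labels.max() + 1):
        region = truth.nucleus_labels == k
        cy, cx = ndimage.center_of_mass(region)
        ry, rx = cy - off[0], cx - off[1]
        if not (half < ry < size - half and half < rx < size - half):
            continue
        r0, c0 = int(ry) - half, int(rx) - half
        win = dapi[r0:r0 + window, c0:c0 + window]
        if win.sum() == 0:
            continue
        wy, wx = ndimage.center_of_mass(win)
        errs.append(np.hypot(wy + r0 - ry, wx + c0 - rx))
    assert errs, "no nuclei inside the evaluated patch"
    return float(np.mean(errs))


@pytest.fixture(scope="session")
def registered_shifted(shifted_slide):
    """Registration cascade output on the purely translated slide."""
    _, hne, if_img, truth = shifted_slide
    patches = [PatchRecord("s", "s_100_100", (100, 100), 1024)]
    pairs = register_slide(hne, if_img, patches, coarse_level=3, patch_level=1)
    return pairs, truth


@pytest.fixture(scope="session")
def registered_warped(warped_slide):
    """Rigid-only and rigid+Demons outputs on the warped slide."""
    _, hne, if_img, truth = warped_slide
    patches = [PatchRecord("s", "s_100_100", (100, 100), 1024)]
    rigid = register_slide(hne, if_img, patches, coarse_level=3, patch_level=1,
                           run_demons=False)
    patches = [PatchRecord("s", "s_100_100", (100, 100), 1024)]
    full = register_slide(hne, if_img, patches, coarse_level=3, patch_level=1)
    return rigid, full, truth
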