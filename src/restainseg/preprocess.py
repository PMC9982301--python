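"""Slide-level preprocessing: tissue detection, blur QC and patch extraction.

Tissue candidates are found on a low-resolution pyramid level (level 4,
i.e. 1/16 of full resolution) by Otsu binarisation of the blurred
grayscale slide; connected regions are kept only when their area at full
resolution falls between 12.8e6 and 256e6 px^2.  Patches of
1024 x 1024 px (stride 1024) are laid out over each retained region and
a patch survives only when every one of its pixels is at least 200 px
(full-resolution) away from non-tissue — non-specific IF staining
concentrates at tissue edges.  Patches can further be flagged for blur
(variance of the 3x3 Laplacian of the unit-scaled grayscale patch below
5e-4) or for overlap with annotated artifact polygons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, box
from skimage.filters import threshold_otsu

# ITU-R 601 luminance weights; the blur threshold assumes unit-scaled gray
_LUMA = np.array([0.299, 0.587, 0.114])
_LAPLACIAN_3X3 = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)

LEVEL4_SCALE = 16            # level 4 = 1/16 of full resolution
LEVEL4_AREA_FACTOR = 256     # one level-4 pixel covers 16 x 16 full-res pixels


@dataclass
class TissueRegion:
    region_id: int
    mask_at_level4: np.ndarray
    area_level0_px2: float
    bounding_box: tuple[int, int, int, int]   # (row0, col0, row1, col1), level 0


@dataclass
class PatchRecord:
    slide_id: str
    patch_id: str
    origin_level0: tuple[int, int]
    size_px: int = 1024
    spot_id: int = -1
    qc_flags: set = field(default_factory=set)
    cutoff: float | None = None
    split: str = "unset"

    def flag(self, name: str) -> None:
        self.qc_flags.add(name)

    @property
    def center_level0(self) -> tuple[float, float]:
        r, c = self.origin_level0
        return (r + self.size_px / 2.0, c + self.size_px / 2.0)


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Luminance in [0, 1]."""
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim == 2:
        g = arr
    else:
        g = arr @ _LUMA
    if g.max() > 1.0:
        g = g / 255.0
    return g


def detect_tissue_regions(wsi_level4: np.ndarray,
                          blur_kernel: int = 81,
                          area_min_px2: float = 12.8e6,
                          area_max_px2: float = 256e6) -> list[TissueRegion]:
    """Tissue components of the level-4 slide, filtered by full-resolution area.

    Grayscale -> Gaussian blur (``blur_kernel`` square kernel) -> Otsu ->
    connected components; tissue is the darker phase.  Area bounds are in
    level-0 px^2 (level-4 pixel count x 256).
    """
    gray = to_grayscale(wsi_level4)
    if gray.size == 0:
        return []
    sigma = (blur_kernel - 1) / 6.0
    radius = (blur_kernel - 1) // 2
    blurred = ndimage.gaussian_filter(gray, sigma, truncate=radius / sigma)
    if blurred.max() == blurred.min():
        return []
    t = threshold_otsu(blurred)
    tissue = blurred < t          # tissue absorbs light: darker than background
    labels, n = ndimage.label(tissue)
    regions = []
    for k in range(1, n + 1):
        mask = labels == k
        area0 = float(mask.sum()) * LEVEL4_AREA_FACTOR
        if not area_min_px2 <= area0 <= area_max_px2:
            continue
        rows, cols = np.nonzero(mask)
        bbox = (int(rows.min()) * LEVEL4_SCALE, int(cols.min()) * LEVEL4_SCALE,
                int(rows.max() + 1) * LEVEL4_SCALE, int(cols.max() + 1) * LEVEL4_SCALE)
        regions.append(TissueRegion(len(regions), mask, area0, bbox))
    return regions


def blur_flag(patch: np.ndarray, threshold: float = 5e-4) -> tuple[float, bool]:
    """Variance of the 3x3 Laplacian of the unit-scaled grayscale patch."""
    gray = to_grayscale(patch)
    if gray.size == 0:
        raise ValueError("empty patch")
    lap = ndimage.convolve(gray, _LAPLACIAN_3X3, mode="reflect")
    score = float(lap.var())
    return score, score < threshold


def extract_patch_grid(tissue_mask_level0: np.ndarray, slide_id: str = "slide",
                       size: int = 1024, stride: int = 1024,
                       edge_margin: int = 200) -> list[PatchRecord]:
    """Non-overlapping patch windows fully inside the margin-eroded tissue.

    ``tissue_mask_level0`` is the binary tissue mask at full resolution
    (upsample ``TissueRegion.mask_at_level4`` by 16 for WSI input).  The
    edge rule is exact: a patch survives iff every pixel of its window is
    at least ``edge_margin`` px from the nearest non-tissue pixel,
    implemented with a Euclidean distance transform.  The grid is
    anchored at the top-left of the eroded mask's bounding box.
    """
    mask = np.asarray(tissue_mask_level0, dtype=bool)
    if edge_margin > 0:
        # the slide boundary counts as non-tissue, hence the zero border;
        # strictly-greater matches erosion by a disk of radius edge_margin
        padded = np.pad(mask, 1, constant_values=False)
        dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
        safe = dist > edge_margin
    else:
        safe = mask
    if not safe.any():
        return []
    rows, cols = np.nonzero(safe)
    r0, c0 = int(rows.min()), int(cols.min())
    r1, c1 = int(rows.max() + 1), int(cols.max() + 1)
    records = []
    for r in range(r0, r1 - size + 1, stride):
        for c in range(c0, c1 - size + 1, stride):
            if safe[r:r + size, c:c + size].all():
                records.append(PatchRecord(
                    slide_id=slide_id,
                    patch_id=f"{slide_id}_{r}_{c}",
                    origin_level0=(r, c),
                    size_px=size))
    return records


def upsample_mask(mask_level4: np.ndarray, factor: int = LEVEL4_SCALE) -> np.ndarray:
    return np.kron(mask_level4.astype(bool), np.ones((factor, factor), dtype=bool))


def flag_artifact_patches(patches: list[PatchRecord],
                          artifact_features: list[dict]) -> list[PatchRecord]:
    """Flag every patch whose window intersects any artifact polygon.

    ``artifact_features`` are GeoJSON Feature dicts with Polygon geometry
    in level-0 (x, y) = (col, row) coordinates.  Any overlap, including a
    single shared point, counts.  Invalid polygons are skipped with a
    warning.
    """
    polys = []
    for feat in artifact_features:
        geom = feat.get("geometry", feat)
        if geom.get("type") != "Polygon":
            continue
        try:
            p = Polygon(geom["coordinates"][0])
            if not p.is_valid:
                p = p.buffer(0)
            if p.is_empty:
                raise ValueError("empty after repair")
            polys.append(p)
        except Exception as exc:  # noqa: BLE001 - per-feature robustness
            warnings.warn(f"skipping invalid artifact polygon: {exc}")
    for patch in patches:
        r, c = patch.origin_level0
        window = box(c, r, c + patch.size_px, r + patch.size_px)
        if any(window.intersects(p) for p in polys):
            patch.flag("artifact_overlap")
    return patches


def patch_table(patches: list[PatchRecord]):
    """Patch records as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame([{
        "slide_id": p.slide_id, "patch_id": p.patch_id,
        "row": p.origin_level0[0], "col": p.origin_level0[1],
        "size_px": p.size_px, "spot_id": p.spot_id,
        "flags": "|".join(sorted(p.qc_flags)), "cutoff": p.cutoff,
        "split": p.split,
    } for p in patches])
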