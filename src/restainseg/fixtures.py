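"""Synthetic paired H&E / restained-IF slides with exhaustive ground truth.

The generator emulates the phenomena the pipeline must survive on real
restained sections, at desk scale:

* elliptical nuclei visible both as hematoxylin in the H&E image and as
  DAPI in the IF image;
* a per-cell target signal rendered in a nuclear, cytoplasmic or
  membranous pattern, modulated by a smooth intensity gradient across
  the slide (restained sections stain unevenly);
* red blood cells: red in H&E and autofluorescent in the target channel,
  with no DAPI;
* a global translation plus a smooth local deformation between the H&E
  and IF acquisitions (the section moves between scans);
* optional locally blurred regions and TMA-spot clustered layouts.

All intensities are 8-bit.  Coordinates are (row, col), 0-based, with
half-open windows throughout.  Identical (spec, seed) gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import find_contours

from .evaluate import AnnotationSet

# default render palette (uint8)
_BACKGROUND = np.array([245, 243, 244], dtype=float)
_EOSIN = np.array([231, 178, 203], dtype=float)
_HEMATOXYLIN = np.array([76, 52, 138], dtype=float)
_RBC_HNE = np.array([178, 92, 104], dtype=float)   # satisfies R>100, G<130, R>B
_RBC_AUTOFLUOR = 70.0
_DAPI_PEAK = 210.0


class FixtureSizingError(ValueError):
    """Image too small to place the requested objects."""


@dataclass
class FixtureSpec:
    image_height_px: int = 1408
    image_width_px: int = 1408
    mpp: float = 0.220818
    n_spots: int = 1
    nuclei_per_spot: int = 80
    positive_fraction: float = 0.5
    stain_pattern: str = "cytoplasmic"    # cytoplasmic | nuclear | membranous
    rbc_count: int = 6
    global_shift_px: tuple[float, float] = (8.0, -5.0)
    deformation_amplitude_px: float = 0.0
    deformation_smoothness_px: float = 40.0
    if_gradient: tuple[float, float] = (60.0, 0.02)   # base intensity, slope per px
    blur_region_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_height_px, self.image_width_px) < 64:
            raise FixtureSizingError("image must be at least 64 px on each side")
        for name in ("n_spots", "nuclei_per_spot", "rbc_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.deformation_smoothness_px <= 0:
            raise ValueError("deformation_smoothness_px must be positive")
        if self.stain_pattern not in ("cytoplasmic", "nuclear", "membranous"):
            raise ValueError(f"unknown stain_pattern {self.stain_pattern!r}")


@dataclass
class GroundTruth:
    true_mask: np.ndarray                     # binary, H&E frame
    nucleus_centers: np.ndarray               # (n, 2) float, (row, col)
    nucleus_labels: np.ndarray                # instance map, H&E frame
    per_region_cutoff: np.ndarray             # float image of local true cutoffs
    applied_shift: tuple[float, float]
    applied_deformation: np.ndarray           # (H, W, 2) of (dy, dx)
    rbc_mask: np.ndarray
    blur_mask: np.ndarray
    spot_ids: np.ndarray                      # per-nucleus spot membership
    positive: np.ndarray = field(default=None)  # per-nucleus bool
    cell_labels: np.ndarray = field(default=None)  # whole-cell instance map


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _spot_centers(spec: FixtureSpec) -> tuple[np.ndarray, float]:
    """Spot centres on a square grid plus the per-spot radius."""
    n = max(spec.n_spots, 1)
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    ch = spec.image_height_px / rows
    cw = spec.image_width_px / cols
    radius = 0.42 * min(ch, cw)
    centers = []
    for k in range(spec.n_spots):
        r, c = divmod(k, cols)
        centers.append(((r + 0.5) * ch, (c + 0.5) * cw))
    return np.asarray(centers, dtype=float), radius


def _place_nuclei(rng, center, spot_radius, n, nucleus_radius=(9.0, 13.0),
                  min_sep_factor=2.5, max_tries=4000):
    """Rejection-sample non-overlapping nucleus centres inside a spot."""
    placed, radii = [], []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise FixtureSizingError(
                f"could not place {n} nuclei in a spot of radius {spot_radius:.0f} px")
        rn = rng.uniform(*nucleus_radius)
        rho = spot_radius * 0.88 * np.sqrt(rng.random())
        theta = rng.uniform(0, 2 * np.pi)
        p = (center[0] + rho * np.sin(theta), center[1] + rho * np.cos(theta))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= (min_sep_factor * max(rn, rq)) ** 2
               for q, rq in zip(placed, radii)):
            placed.append(p)
            radii.append(rn)
    return np.asarray(placed), np.asarray(radii)


def _smooth_deformation(rng, shape, amplitude, smoothness) -> np.ndarray:
    field_ = np.zeros((*shape, 2), dtype=np.float32)
    if amplitude <= 0:
        return field_
    for k in range(2):
        noise = rng.standard_normal(shape)
        field_[..., k] = gaussian_filter(noise, smoothness)
    mag = np.linalg.norm(field_, axis=-1)
    peak = mag.max()
    if peak > 0:
        field_ *= amplitude / peak
    return field_


def _warp_channels(img: np.ndarray, shift, deformation) -> np.ndarray:
    """Render the observed (moved) image: content is displaced by +shift+field."""
    h, w = img.shape[:2]
    rr, cc = np.meshgrid(np.arange(h, dtype=np.float32),
                         np.arange(w, dtype=np.float32), indexing="ij")
    src_r = rr - shift[0] - deformation[..., 0]
    src_c = cc - shift[1] - deformation[..., 1]
    out = np.empty_like(img, dtype=np.float32)
    chans = img.shape[2] if img.ndim == 3 else 1
    img3 = img.reshape(h, w, chans)
    out3 = out.reshape(h, w, chans)
    for k in range(chans):
        out3[..., k] = map_coordinates(img3[..., k].astype(np.float32),
                                       [src_r, src_c], order=1, mode="constant")
    return out


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_slide_pair(spec: FixtureSpec):
    """Render a paired H&E (RGB) and IF (DAPI + target) slide plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    centers, spot_radius = _spot_centers(spec)
    if spec.nuclei_per_spot > 0 and spot_radius < 40:
        raise FixtureSizingError(
            f"spot radius {spot_radius:.0f} px too small for nuclei placement")

    tissue = np.zeros((h, w), dtype=bool)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    for cy, cx in centers:
        tissue |= (yy - cy) ** 2 + (xx - cx) ** 2 <= spot_radius ** 2

    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    membrane = np.zeros((h, w), dtype=bool)
    all_centers, all_radii, spot_ids = [], [], []
    for sid, (cy, cx) in enumerate(centers):
        if spec.nuclei_per_spot == 0:
            continue
        pts, radii = _place_nuclei(rng, (cy, cx), spot_radius, spec.nuclei_per_spot)
        for p, rn in zip(pts, radii):
            k = len(all_centers) + 1
            ecc = rng.uniform(0.85, 1.18)
            rot = rng.uniform(0, np.pi)
            rr, cc = draw_ellipse(p[0], p[1], rn * ecc, rn / ecc,
                                  shape=(h, w), rotation=rot)
            nucleus_labels[rr, cc] = k
            rc = rn + 8.0
            rr2, cc2 = draw_ellipse(p[0], p[1], rc * ecc, rc / ecc,
                                    shape=(h, w), rotation=rot)
            cell_labels[rr2, cc2] = k
            rr3, cc3 = draw_ellipse(p[0], p[1], (rc - 2.5) * ecc, (rc - 2.5) / ecc,
                                    shape=(h, w), rotation=rot)
            ring = np.zeros((h, w), dtype=bool)
            ring[rr2, cc2] = True
            ring[rr3, cc3] = False
            membrane |= ring
            all_centers.append(p)
            all_radii.append(rn)
            spot_ids.append(sid)
    nucleus_centers = (np.asarray(all_centers, dtype=float)
                       if all_centers else np.empty((0, 2)))
    spot_ids = np.asarray(spot_ids, dtype=int)
    n_cells = len(nucleus_centers)

    positive = rng.random(n_cells) < spec.positive_fraction if n_cells else \
        np.zeros(0, dtype=bool)

    # red blood cells: small ellipses inside tissue, away from nuclei
    rbc_mask = np.zeros((h, w), dtype=bool)
    placed_rbc = 0
    for _ in range(200 * max(spec.rbc_count, 1)):
        if placed_rbc >= spec.rbc_count:
            break
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        rr, cc = draw_ellipse(cy, cx, rng.uniform(5, 8), rng.uniform(4, 6),
                              shape=(h, w), rotation=rng.uniform(0, np.pi))
        if len(rr) and tissue[rr, cc].all() and not cell_labels[rr, cc].any():
            rbc_mask[rr, cc] = True
            placed_rbc += 1
    if placed_rbc < spec.rbc_count:
        raise FixtureSizingError(
            f"placed only {placed_rbc}/{spec.rbc_count} RBCs; enlarge the image")

    # ----- H&E rendering -------------------------------------------------
    hne = np.empty((h, w, 3), dtype=np.float32)
    hne[:] = _BACKGROUND
    hne[tissue] = _EOSIN
    hne[nucleus_labels > 0] = _HEMATOXYLIN
    hne[rbc_mask] = _RBC_HNE
    hne += rng.normal(0.0, 2.0, size=hne.shape)
    # keep the RBC colour rule airtight under noise
    hne[rbc_mask] = np.clip(hne[rbc_mask], [150, 60, 80], [200, 120, 120])

    blur_mask = np.zeros((h, w), dtype=bool)
    if spec.blur_region_fraction > 0:
        area = spec.blur_region_fraction * h * w
        side = int(np.sqrt(area))
        r0 = int(rng.uniform(0, max(h - side, 1)))
        c0 = int(rng.uniform(0, max(w - side, 1)))
        blur_mask[r0:r0 + side, c0:c0 + side] = True
        blurred = np.stack([gaussian_filter(hne[..., k], 8.0) for k in range(3)], axis=-1)
        hne[blur_mask] = blurred[blur_mask]
    hne = np.clip(hne, 0, 255).astype(np.uint8)

    # ----- IF rendering in the H&E frame ---------------------------------
    amplitude = np.clip(spec.if_gradient[0] + spec.if_gradient[1] * xx, 0, 255)
    dapi = np.zeros((h, w), dtype=np.float32)
    target = np.zeros((h, w), dtype=np.float32)
    if n_cells:
        brightness = rng.uniform(0.85, 1.0, size=n_cells)
        nuc = nucleus_labels > 0
        dapi[nuc] = _DAPI_PEAK * brightness[nucleus_labels[nuc] - 1]
        pos_ids = np.flatnonzero(positive) + 1
        pos_lut = np.zeros(n_cells + 1, dtype=bool)
        pos_lut[pos_ids] = True
        if spec.stain_pattern == "nuclear":
            region = pos_lut[nucleus_labels]
        elif spec.stain_pattern == "cytoplasmic":
            region = pos_lut[cell_labels] & ~(nucleus_labels > 0)
        else:  # membranous
            region = pos_lut[cell_labels] & membrane
        target[region] = amplitude[region]
        true_mask = region
    else:
        true_mask = np.zeros((h, w), dtype=bool)
    target[rbc_mask] = _RBC_AUTOFLUOR
    dapi += np.abs(rng.normal(0.0, 1.2, size=dapi.shape))
    target += np.abs(rng.normal(0.0, 1.2, size=target.shape))

    deformation = _smooth_deformation(rng, (h, w), spec.deformation_amplitude_px,
                                      spec.deformation_smoothness_px)
    if_aligned = np.stack([dapi, target], axis=-1)
    if_observed = _warp_channels(if_aligned, spec.global_shift_px, deformation)
    if_observed = np.clip(if_observed, 0, 255).astype(np.uint8)

    truth = GroundTruth(
        true_mask=true_mask,
        nucleus_centers=nucleus_centers,
        nucleus_labels=nucleus_labels,
        per_region_cutoff=(amplitude / 2.0).astype(np.float32),
        applied_shift=tuple(float(s) for s in spec.global_shift_px),
        applied_deformation=deformation,
        rbc_mask=rbc_mask,
        blur_mask=blur_mask,
        spot_ids=spot_ids,
        positive=positive,
        cell_labels=cell_labels,
    )
    return hne, if_observed, truth


def unwarp_if(if_observed: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """Map the observed IF image back into the H&E frame using the true transform."""
    h, w = if_observed.shape[:2]
    rr, cc = np.meshgrid(np.arange(h, dtype=np.float32),
                         np.arange(w, dtype=np.float32), indexing="ij")
    src_r = rr + truth.applied_shift[0] + truth.applied_deformation[..., 0]
    src_c = cc + truth.applied_shift[1] + truth.applied_deformation[..., 1]
    out = np.empty_like(if_observed, dtype=np.float32)
    for k in range(if_observed.shape[2]):
        out[..., k] = map_coordinates(if_observed[..., k].astype(np.float32),
                                      [src_r, src_c], order=1, mode="nearest")
    return out


# ---------------------------------------------------------------------------
# TMA layout + annotations
# ---------------------------------------------------------------------------

def generate_tma_layout(n_spots: int, spot_spacing_px: float,
                        patches_per_spot: int, seed: int = 0):
    """Clustered patch centres mimicking a TMA slide.

    Spot centres sit on a square grid with pitch 2 * ``spot_spacing_px``
    and patches scatter within ``spot_spacing_px / 4`` of their spot, so
    centres of different spots are at least ``spot_spacing_px`` apart.
    Returns a list of ((row, col), spot_id).
    """
    if spot_spacing_px <= 0:
        raise ValueError("spot_spacing_px must be positive")
    rng = np.random.default_rng(seed)
    cols = int(np.ceil(np.sqrt(max(n_spots, 1))))
    pitch = 2.0 * spot_spacing_px
    records = []
    for k in range(n_spots):
        gr, gc = divmod(k, cols)
        center = np.array([(gr + 0.5) * pitch, (gc + 0.5) * pitch])
        for _ in range(patches_per_spot):
            rho = (spot_spacing_px / 4.0) * np.sqrt(rng.random())
            theta = rng.uniform(0, 2 * np.pi)
            p = center + rho * np.array([np.sin(theta), np.cos(theta)])
            records.append(((float(p[0]), float(p[1])), k))
    return records


def generate_annotation_set(truth: GroundTruth, n_annotators: int,
                            miss_rate: float, jitter_px: float,
                            seed: int = 0) -> AnnotationSet:
    """Per-annotator point (and region) annotations derived from ground truth.

    Each annotator marks every true nucleus centre independently with
    probability ``1 - miss_rate`` and with isotropic Gaussian positional
    jitter of scale ``jitter_px``; region annotators trace the contours
    of the true positive mask with the same jitter.
    """
    if n_annotators < 1:
        raise ValueError("need at least one annotator")
    rng = np.random.default_rng(seed)
    out = AnnotationSet()
    centers = truth.nucleus_centers
    contours = [c[::6] for c in find_contours(truth.true_mask.astype(float), 0.5)
                if len(c) >= 12]
    for a in range(n_annotators):
        name = f"annotator_{a}"
        keep = rng.random(len(centers)) >= miss_rate if len(centers) else \
            np.zeros(0, dtype=bool)
        pts = centers[keep] + rng.normal(0, jitter_px, size=(int(keep.sum()), 2)) \
            if keep.any() else np.empty((0, 2))
        out.points[name] = pts
        polys = []
        for cont in contours:
            if rng.random() < miss_rate:
                continue
            polys.append(cont + rng.normal(0, jitter_px, size=cont.shape))
        out.polygons[name] = polys
    return out
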