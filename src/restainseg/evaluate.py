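"""Evaluation of masks, predictions and multi-annotator annotations.

Region targets are compared pixelwise and cell targets per cell.  The Dice
coefficient is always 2*TP / (2*TP + FP + FN); for cell-level scoring a
ground-truth point counts as detected when it falls on a predicted
connected component (or, for point predictions, when it matches a
predicted point within a fixed pixel radius).  Consensus over several
annotators requires agreement of at least ``min_votes`` of them, with
point annotations linked across annotators by single-linkage clustering
at the matching radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage.color import rgb2hed
from skimage.draw import polygon2mask
from skimage.measure import label as cc_label

from . import io as rio

POINT_MATCH_RADIUS_PX = 8.0     # = 1.77 um at 0.220818 um/px
DEFAULT_MIN_VOTES = 2


@dataclass
class AnnotationSet:
    """Per-annotator polygon and point annotations, coordinates in (row, col) px."""

    polygons: dict[str, list[np.ndarray]] = field(default_factory=dict)
    points: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def annotators(self) -> list[str]:
        return sorted(set(self.polygons) | set(self.points))

    def to_geojson(self, path) -> None:
        feats = []
        for ann, polys in self.polygons.items():
            feats += [rio.polygon_feature(p, annotator=ann) for p in polys]
        for ann, pts in self.points.items():
            feats += [rio.point_feature(r, c, annotator=ann) for r, c in np.atleast_2d(pts)]
        rio.write_geojson(path, feats)

    @classmethod
    def from_geojson(cls, path) -> "AnnotationSet":
        out = cls()
        for feat in rio.read_geojson(path):
            ann = str(feat.get("properties", {}).get("annotator", "0"))
            geom = feat["geometry"]
            if geom["type"] == "Point":
                x, y = geom["coordinates"]
                pts = out.points.setdefault(ann, np.empty((0, 2)))
                out.points[ann] = np.vstack([pts, [[y, x]]])
            elif geom["type"] == "Polygon":
                ring = np.asarray(geom["coordinates"][0])
                out.polygons.setdefault(ann, []).append(ring[:, ::-1])  # (x,y)->(row,col)
        return out


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    level: str = "pixel"
    flagged: bool = False

    @property
    def dice(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 1.0 if denom == 0 else 2 * self.tp / denom

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return 1.0 if denom == 0 else self.tp / denom

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return 1.0 if denom == 0 else self.tp / denom

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "dice": self.dice,
                "precision": self.precision, "recall": self.recall,
                "level": self.level, "flagged": self.flagged}


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _rasterize_annotator(polys: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for ring in polys:
        ring = np.asarray(ring, dtype=float)
        if len(ring) >= 3:
            shp = Polygon(ring)
            if not shp.is_valid:
                repaired = shp.buffer(0)
                if repaired.is_empty or not repaired.is_valid:
                    warnings.warn("skipping unrepairable self-intersecting polygon")
                    continue
                warnings.warn("repaired self-intersecting polygon")
                geoms = getattr(repaired, "geoms", [repaired])
                for g in geoms:
                    mask |= polygon2mask(shape, np.asarray(g.exterior.coords))
                continue
        mask |= polygon2mask(shape, ring)
    return mask


def consensus_regions(annotations: AnnotationSet, shape: tuple[int, int],
                      min_votes: int = DEFAULT_MIN_VOTES) -> np.ndarray:
    """Pixels covered by the polygons of at least ``min_votes`` annotators."""
    votes = np.zeros(shape, dtype=np.int32)
    for ann in annotations.annotators:
        polys = annotations.polygons.get(ann, [])
        if polys:
            votes += _rasterize_annotator(polys, shape)
    return votes >= min_votes


def consensus_points(annotations: AnnotationSet,
                     radius_px: float = POINT_MATCH_RADIUS_PX,
                     min_votes: int = DEFAULT_MIN_VOTES) -> np.ndarray:
    """Consensus cell locations from per-annotator point sets.

    Points from different annotators within ``radius_px`` (inclusive) are
    linked; each single-linkage component backed by >= ``min_votes``
    distinct annotators yields one consensus point at the component
    centroid.  Returns an (n, 2) array of (row, col).
    """
    pts, owner = [], []
    for i, ann in enumerate(annotations.annotators):
        p = np.atleast_2d(annotations.points.get(ann, np.empty((0, 2))))
        for q in p:
            pts.append(q)
            owner.append(i)
    if not pts:
        return np.empty((0, 2))
    pts = np.asarray(pts, dtype=float)
    owner = np.asarray(owner)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=radius_px, output_type="ndarray")
    n = len(pts)
    if len(pairs):
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    _, comp = connected_components(adj, directed=False)
    out = []
    for c in np.unique(comp):
        members = comp == c
        if len(np.unique(owner[members])) >= min_votes:
            out.append(pts[members].mean(axis=0))
    return np.asarray(out) if out else np.empty((0, 2))


# ---------------------------------------------------------------------------
# Dice machinery
# ---------------------------------------------------------------------------

def pixel_dice(a: np.ndarray, b: np.ndarray) -> EvalReport:
    """Pixelwise overlap of mask ``b`` against reference ``a``."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(~a & b))
    fn = int(np.count_nonzero(a & ~b))
    return EvalReport(tp, fp, fn, level="pixel",
                      flagged=not (a.any() or b.any()))


def _greedy_point_match(gt: np.ndarray, pred: np.ndarray, radius: float) -> int:
    """One-to-one nearest-first matching; returns the number of matches."""
    if len(gt) == 0 or len(pred) == 0:
        return 0
    d = np.linalg.norm(gt[:, None, :] - pred[None, :, :], axis=2)
    cand = [(d[i, j], i, j) for i in range(len(gt)) for j in range(len(pred))
            if d[i, j] <= radius]
    cand.sort()  # distance, then (gt index, pred index) for deterministic ties
    used_g, used_p, n = set(), set(), 0
    for _, i, j in cand:
        if i not in used_g and j not in used_p:
            used_g.add(i)
            used_p.add(j)
            n += 1
    return n


def cell_dice(gt_points: np.ndarray, prediction: np.ndarray,
              radius_px: float = POINT_MATCH_RADIUS_PX) -> EvalReport:
    """Cell-level Dice of a prediction against ground-truth cell points.

    ``prediction`` is either a binary mask (2-D bool/int image) or an
    (n, 2) array of predicted points.  Against a mask, a ground-truth
    point is a true positive when it lies on a predicted connected
    component; components containing no point count as false positives.
    Against points, matching is one-to-one within ``radius_px``.
    """
    gt_points = np.atleast_2d(np.asarray(gt_points, dtype=float)) \
        if np.size(gt_points) else np.empty((0, 2))
    pred = np.asarray(prediction)
    if pred.ndim == 2 and pred.shape[1] == 2 and pred.dtype.kind == "f":
        tp = _greedy_point_match(gt_points, pred, radius_px)
        fp = len(pred) - tp
        fn = len(gt_points) - tp
        return EvalReport(tp, fp, fn, level="cell")
    comps, n_comp = cc_label(pred.astype(bool), return_num=True)
    tp = fn = 0
    hit = np.zeros(n_comp + 1, dtype=bool)
    for r, c in gt_points:
        ri, ci = int(round(r)), int(round(c))
        inside = 0 <= ri < comps.shape[0] and 0 <= ci < comps.shape[1]
        lab = comps[ri, ci] if inside else 0
        if lab > 0:
            tp += 1
            hit[lab] = True
        else:
            fn += 1
    fp = int(n_comp - np.count_nonzero(hit[1:]))
    return EvalReport(tp, fp, fn, level="cell")


def pooled_dice(per_image_counts: list[EvalReport | tuple[int, int, int]]) -> float:
    """One Dice over summed TP/FP/FN (not the mean of per-image Dice)."""
    if not per_image_counts:
        raise ValueError("need at least one image")
    tp = fp = fn = 0
    for item in per_image_counts:
        t, p, n = (item.tp, item.fp, item.fn) if isinstance(item, EvalReport) else item
        tp += t
        fp += p
        fn += n
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


# ---------------------------------------------------------------------------
# morphometrics
# ---------------------------------------------------------------------------

def hematoxylin_intensity(hne_patch: np.ndarray, region: np.ndarray) -> float:
    """Mean colour-deconvolved hematoxylin absorbance over ``region``."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    hed = rgb2hed(np.asarray(hne_patch, dtype=np.uint8))
    return float(hed[..., 0][region].mean())


def nearest_rbc_distance(cell: tuple[float, float], rbc_mask: np.ndarray,
                         mpp: float = 0.220818) -> tuple[float, float]:
    """Euclidean distance (px, um) from a cell centre to the nearest RBC pixel."""
    rbc_mask = np.asarray(rbc_mask, dtype=bool)
    if not rbc_mask.any():
        warnings.warn("empty RBC mask: distance is infinite")
        return float("inf"), float("inf")
    dist = ndimage.distance_transform_edt(~rbc_mask)
    r, c = int(round(cell[0])), int(round(cell[1]))
    px = float(dist[r, c])
    return px, px * mpp
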