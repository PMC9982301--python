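"""Hierarchical multi-class label merging.

Per-target binary segmenters are combined into one 10-class label map by
walking a fixed lineage hierarchy from coarse to fine:

    layer 0: 0 background, 1 stroma        (from grayscale vs Otsu's threshold)
    layer 1: 2 epithelial, 3 smooth muscle
    layer 2: 4 leukocytes, 5 endothelial, 6 red blood cells
    layer 3: 7 lymphocytes, 8 plasma, 9 myeloid

At layer k a pixel takes argmax_m of the class logits in that layer when
the maximum logit is strictly positive, otherwise it keeps its previous
label — so a label is only ever overwritten by a strictly deeper layer.
Multiple models per class are ensembled by the pixelwise mean of their
logits.  Whole-slide inference tiles the image (7680 px tiles, padded at
the edges) with a single slide-level Otsu threshold, which makes the
tiled and untiled results identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .preprocess import to_grayscale

LABEL_NAMES = {
    0: "background", 1: "stroma",
    2: "epithelial", 3: "smooth_muscle",
    4: "leukocytes", 5: "endothelial", 6: "red_blood_cells",
    7: "lymphocytes", 8: "plasma", 9: "myeloid",
}

# fixed 10-colour palette for indexed-PNG export
LABEL_PALETTE = [
    (255, 255, 255), (220, 220, 220), (228, 26, 28), (255, 127, 0),
    (55, 126, 184), (77, 175, 74), (166, 86, 40), (152, 78, 163),
    (247, 129, 191), (255, 255, 51),
]


@dataclass
class HierarchySpec:
    """Ordered label layers; deeper layers overwrite shallower ones."""

    layers: tuple[tuple[int, ...], ...] = ((0, 1), (2, 3), (4, 5, 6), (7, 8, 9))

    def __post_init__(self) -> None:
        flat = [m for layer in self.layers for m in layer]
        if sorted(flat) != list(range(len(flat))):
            raise ValueError("labels must be unique consecutive integers from 0")

    @property
    def foreground_labels(self) -> list[int]:
        """All labels above background (the distinguishable tissue/cell types)."""
        return [m for layer in self.layers for m in layer if m != 0]

    @property
    def predicted_classes(self) -> list[int]:
        """Classes that need a logit map (layers 1 and deeper)."""
        return [m for layer in self.layers[1:] for m in layer]


def base_layer(x: np.ndarray, t: float, invert: bool = False) -> np.ndarray:
    """Layer-0 labels: stroma (1) where grayscale strictly exceeds t, else 0.

    ``invert`` flips the comparison for slides where tissue is darker
    than background in the chosen grayscale convention.
    """
    x = np.asarray(x, dtype=float)
    c0 = (x < t) if invert else (x > t)
    return c0.astype(np.int32)


def merge_layers(c0: np.ndarray, logits: dict[int, np.ndarray],
                 hierarchy: HierarchySpec = HierarchySpec()) -> np.ndarray:
    """Recursive coarse-to-fine label update.

    At each layer the pixel label becomes the argmax class of that layer
    iff the layer's maximum logit is strictly positive; ties break
    toward the lowest label id.  Missing class maps raise.
    """
    missing = [m for m in hierarchy.predicted_classes if m not in logits]
    if missing:
        names = ", ".join(f"{m} ({LABEL_NAMES.get(m, '?')})" for m in missing)
        raise ValueError(f"missing logit map for class(es): {names}")
    c = np.asarray(c0, dtype=np.int32)
    shape = c.shape
    for layer in hierarchy.layers[1:]:
        stack = np.stack([np.asarray(logits[m], dtype=float) for m in layer])
        if stack.shape[1:] != shape:
            raise ValueError("logit map shape does not match the label map")
        best = np.argmax(stack, axis=0)            # first occurrence wins ties
        best_val = np.take_along_axis(stack, best[None], axis=0)[0]
        labels = np.asarray(layer, dtype=np.int32)[best]
        c = np.where(best_val > 0, labels, c)
    return c


def ensemble_logits(model_logit_maps: list[np.ndarray]) -> np.ndarray:
    """Pixelwise mean logit over an ensemble of models."""
    if not model_logit_maps:
        raise ValueError("need at least one logit map")
    maps = [np.asarray(m, dtype=float) for m in model_logit_maps]
    if any(m.shape != maps[0].shape for m in maps):
        raise ValueError("logit maps must share shape")
    return np.mean(maps, axis=0)


def probabilities_to_logits(prob: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Log-odds conversion for predictors that only expose probabilities."""
    p = np.clip(np.asarray(prob, dtype=float), eps, 1 - eps)
    return np.log(p / (1 - p))


def tiled_inference(wsi: np.ndarray, predictors: dict[int, "callable"],
                    tile_px: int = 7680,
                    hierarchy: HierarchySpec = HierarchySpec(),
                    invert: bool = False) -> np.ndarray:
    """Whole-slide hierarchical labels assembled from non-overlapping tiles.

    ``predictors[m](rgb_tile) -> logit map`` per class m.  The grayscale
    Otsu threshold is computed once over the whole slide; edge tiles are
    padded to full size for inference and cropped back, so the assembly
    is seamless and equals the untiled result for deterministic
    predictors.
    """
    wsi = np.asarray(wsi)
    h, w = wsi.shape[:2]
    gray = to_grayscale(wsi)
    if gray.max() == gray.min():
        t = float("inf")        # constant slide: all background, by convention
    else:
        t = float(threshold_otsu(gray))
    out = np.zeros((h, w), dtype=np.int32)
    for r0 in range(0, h, tile_px):
        for c0 in range(0, w, tile_px):
            r1, c1 = min(r0 + tile_px, h), min(c0 + tile_px, w)
            tile = wsi[r0:r1, c0:c1]
            th, tw = tile.shape[:2]
            if (th, tw) != (tile_px, tile_px):
                pads = [(0, tile_px - th), (0, tile_px - tw)]
                if tile.ndim == 3:
                    pads.append((0, 0))
                tile = np.pad(tile, pads, mode="edge")
            logits = {m: np.asarray(pred(tile), dtype=float)[:th, :tw]
                      for m, pred in predictors.items()}
            c0_map = base_layer(gray[r0:r1, c0:c1], t, invert=invert)
            out[r0:r1, c0:c1] = merge_layers(c0_map, logits, hierarchy)
    return out


def label_map_metadata() -> dict:
    """Sidecar JSON payload mapping label ids to names and palette colours."""
    return {str(k): {"name": v, "color": list(LABEL_PALETTE[k])}
            for k, v in LABEL_NAMES.items()}
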