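"""Initial binary mask generation from registered IF signal.

Three mask modes cover the antigen panel:

* ``area`` — epithelium (pan-CK) and smooth muscle (aSMA): the
  thresholded IF-positive area is the mask, minus RBC autofluorescence.
* ``rbc`` — glycophorin-A (CD235a): IF-positive AND red in the H&E image
  (R > 100, G < 130, R > B).
* ``nucleus_transfer`` — hematopoietic and endothelial targets (CD45,
  MNDA, CD3/CD20, MIST1, ERG): the IF signal is transferred onto DAPI
  nuclei; a nucleus is masked when more than 40% of its pixels are
  IF-positive, then each masked nucleus is eroded once with a 3x3
  structuring element so touching cells stay separable.

Patches whose hematoxylin/DAPI Pearson correlation falls below 0.5 are
rejected as misregistered or artifactual.  The nucleus segmenter and the
RBC predictor are injected callables; a watershed fallback segmenter is
built in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

INITIAL_CUTOFF_STRONG = 50.0   # epithelium, smooth muscle, RBC
INITIAL_CUTOFF_DEFAULT = 25.0
NUCLEUS_OVERLAP_CUTOFF = 0.40

TARGET_PANEL = {
    # antigen -> (mask_mode, initial_cutoff, epithelium_flag)
    "panCK": ("area", INITIAL_CUTOFF_STRONG, True),
    "aSMA": ("area", INITIAL_CUTOFF_STRONG, False),
    "CD235a": ("rbc", INITIAL_CUTOFF_STRONG, False),
    "CD45": ("nucleus_transfer", INITIAL_CUTOFF_DEFAULT, False),
    "ERG": ("nucleus_transfer", INITIAL_CUTOFF_DEFAULT, False),
    "MNDA": ("nucleus_transfer", INITIAL_CUTOFF_DEFAULT, False),
    "MIST1": ("nucleus_transfer", INITIAL_CUTOFF_DEFAULT, False),
    "CD3_CD20": ("nucleus_transfer", INITIAL_CUTOFF_DEFAULT, False),
}


@dataclass
class TargetProfile:
    name: str
    mask_mode: str
    initial_cutoff: float
    epithelium_flag: bool = False

    def __post_init__(self) -> None:
        if self.mask_mode not in ("area", "nucleus_transfer", "rbc"):
            raise ValueError(f"unknown mask_mode {self.mask_mode!r}")
        if not 0 < self.initial_cutoff <= 255:
            raise ValueError("initial_cutoff must lie in (0, 255]")

    @classmethod
    def for_target(cls, name: str) -> "TargetProfile":
        mode, cutoff, epi = TARGET_PANEL[name]
        return cls(name, mode, cutoff, epi)


@dataclass
class NucleusInstanceMap:
    labels: np.ndarray                 # 0 background, k = nucleus k
    positive_fraction: np.ndarray      # per nucleus, index k-1
    pixel_count: np.ndarray
    centroids: np.ndarray              # (n, 2) float

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())

    @classmethod
    def from_labels(cls, labels: np.ndarray,
                    signal_mask: np.ndarray | None = None) -> "NucleusInstanceMap":
        labels = np.asarray(labels)
        n = int(labels.max())
        idx = np.arange(1, n + 1)
        if n == 0:
            return cls(labels, np.zeros(0), np.zeros(0, dtype=int), np.empty((0, 2)))
        count = ndimage.sum_labels(np.ones_like(labels), labels, idx).astype(int)
        if signal_mask is not None:
            pos = ndimage.sum_labels(np.asarray(signal_mask, dtype=float),
                                     labels, idx)
            frac = pos / count
        else:
            frac = np.zeros(n)
        cent = np.asarray(ndimage.center_of_mass(np.ones_like(labels), labels, idx))
        return cls(labels, frac, count, cent)


# ---------------------------------------------------------------------------
# QC and colour rules
# ---------------------------------------------------------------------------

def qc_nuclear_correlation(hematoxylin_map: np.ndarray, dapi_map: np.ndarray,
                           min_r: float = 0.5) -> tuple[float, bool]:
    """Pearson correlation of the two nuclear channels; keep iff r >= 0.5."""
    h = np.asarray(hematoxylin_map, dtype=float).ravel()
    d = np.asarray(dapi_map, dtype=float).ravel()
    if h.shape != d.shape:
        raise ValueError("maps must share shape")
    if h.std() == 0 or d.std() == 0:
        return float("nan"), False
    r = float(np.corrcoef(h, d)[0, 1])
    return r, r >= min_r


def rbc_color_mask(hne_patch: np.ndarray) -> np.ndarray:
    """Pixels red in H&E: R > 100 and G < 130 and R > B."""
    rgb = np.asarray(hne_patch).astype(np.int16)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    return (r > 100) & (g < 130) & (r > b)


def build_rbc_mask(if_target: np.ndarray, hne_patch: np.ndarray,
                   cutoff: float = INITIAL_CUTOFF_STRONG) -> np.ndarray:
    """RBC mask: IF-positive AND red in H&E."""
    return (np.asarray(if_target, dtype=float) > cutoff) & rbc_color_mask(hne_patch)


def suppress_rbc_false_positives(mask: np.ndarray,
                                 rbc_prediction: np.ndarray) -> np.ndarray:
    """Remove predicted-RBC pixels (autofluorescence) from a signal mask."""
    mask = np.asarray(mask, dtype=bool)
    rbc = np.asarray(rbc_prediction, dtype=bool)
    if mask.shape != rbc.shape:
        raise ValueError("mask and RBC prediction must share shape")
    return mask & ~rbc


# ---------------------------------------------------------------------------
# nucleus segmentation + transfer
# ---------------------------------------------------------------------------

def segment_nuclei(dapi_map: np.ndarray, min_distance: int = 12,
                   min_size: int = 30) -> NucleusInstanceMap:
    """Fallback DAPI nucleus segmenter: Otsu + distance-transform watershed.

    Any callable returning a :class:`NucleusInstanceMap` (e.g. a Cellpose
    adapter) may replace it in the pipeline.
    """
    dapi = np.asarray(dapi_map, dtype=float)
    if dapi.max() <= dapi.min():
        return NucleusInstanceMap.from_labels(np.zeros(dapi.shape, dtype=np.int32))
    t = threshold_otsu(dapi)
    fg = dapi > t
    fg = ndimage.binary_opening(fg, structure=np.ones((3, 3)))
    if not fg.any():
        return NucleusInstanceMap.from_labels(np.zeros(dapi.shape, dtype=np.int32))
    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=fg,
                           exclude_border=False)
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=fg)
    # drop specks and relabel contiguously
    idx = np.arange(1, labels.max() + 1)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, idx) if len(idx) else []
    keep = {k for k, n in zip(idx, counts) if n >= min_size}
    out = np.zeros_like(labels)
    for new, k in enumerate(sorted(keep), start=1):
        out[labels == k] = new
    return NucleusInstanceMap.from_labels(out)


def transfer_to_nuclei(nuclei: NucleusInstanceMap, signal_mask: np.ndarray,
                       overlap_cutoff: float = NUCLEUS_OVERLAP_CUTOFF) -> np.ndarray:
    """Mask nuclei whose positive fraction strictly exceeds ``overlap_cutoff``.

    Each included nucleus is then eroded once with a 3x3 element,
    independently per nucleus, so adjacent cells do not fuse.
    """
    if not 0 < overlap_cutoff < 1:
        raise ValueError("overlap_cutoff must lie in (0, 1)")
    inst = NucleusInstanceMap.from_labels(nuclei.labels, signal_mask)
    out = np.zeros(inst.labels.shape, dtype=bool)
    selem = np.ones((3, 3), dtype=bool)
    objects = ndimage.find_objects(inst.labels)
    for k in range(1, inst.n_nuclei + 1):
        if inst.positive_fraction[k - 1] > overlap_cutoff:
            sl = objects[k - 1]
            if sl is None:
                continue
            # pad so pixels beyond the nucleus count as background
            region = np.pad(inst.labels[sl] == k, 1)
            eroded = ndimage.binary_erosion(region, selem)[1:-1, 1:-1]
            out[sl] |= eroded
    return out


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def make_initial_mask(if_target: np.ndarray, hne_patch: np.ndarray,
                      profile: TargetProfile,
                      nuclei: NucleusInstanceMap | None = None,
                      rbc_prediction: np.ndarray | None = None,
                      cutoff: float | None = None,
                      overlap_cutoff: float = NUCLEUS_OVERLAP_CUTOFF) -> np.ndarray:
    """Initial mask for one registered patch, dispatching on the mask mode."""
    if_target = np.asarray(if_target, dtype=float)
    c = profile.initial_cutoff if cutoff is None else cutoff
    if profile.mask_mode == "rbc":
        return build_rbc_mask(if_target, hne_patch, c)
    signal = if_target > c
    if rbc_prediction is not None:
        signal = suppress_rbc_false_positives(signal, rbc_prediction)
    if profile.mask_mode == "area":
        return signal
    if profile.mask_mode == "nucleus_transfer":
        if nuclei is None:
            raise ValueError("nucleus_transfer mode needs a nucleus instance map")
        return transfer_to_nuclei(nuclei, signal, overlap_cutoff)
    raise ValueError(f"unknown mask_mode {profile.mask_mode!r}")
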