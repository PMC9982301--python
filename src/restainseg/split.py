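"""Train/validation/test partitioning by TMA spot, with patient-leakage repair.

Patches are grouped into TMA spots by DBSCAN on their centre coordinates
(eps 3000 px, min_samples 5; noise points are excluded from the splits).
Per slide, two spots go to validation, two to test and the rest to
training, so patches of one spot never span splits.  Because both spots
of a patient can land in different splits, a repair pass then moves all
patches of any patient touching the test set to test, and of any
remaining patient touching validation to validation; the pass is
idempotent and leaves every patient in exactly one split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

SPOT_EPS_PX = 3000.0
SPOT_MIN_SAMPLES = 5


@dataclass
class SplitAssignment:
    patch_split: dict[str, str] = field(default_factory=dict)
    spot_split: dict[tuple[str, int], str] = field(default_factory=dict)

    def patient_splits(self, patch_patient: dict[str, str]) -> dict[str, set]:
        out: dict[str, set] = {}
        for pid, split in self.patch_split.items():
            out.setdefault(patch_patient[pid], set()).add(split)
        return out


def detect_spots(patch_centers: np.ndarray, eps: float = SPOT_EPS_PX,
                 min_samples: int = SPOT_MIN_SAMPLES) -> np.ndarray:
    """DBSCAN spot labels for patch centres; -1 marks noise (excluded later)."""
    centers = np.atleast_2d(np.asarray(patch_centers, dtype=float))
    if len(centers) == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(centers)


def assign_splits(spot_ids_per_slide: dict[str, dict[str, int]],
                  n_val_spots: int = 2, n_test_spots: int = 2,
                  seed: int = 0) -> SplitAssignment:
    """Per slide: seeded-random choice of val/test spots, rest to train.

    ``spot_ids_per_slide`` maps slide_id -> {patch_id: spot_id}; patches
    with spot_id < 0 (DBSCAN noise) are left out of the assignment.
    """
    rng = np.random.default_rng(seed)
    out = SplitAssignment()
    for slide_id in sorted(spot_ids_per_slide):
        patch_spots = spot_ids_per_slide[slide_id]
        spots = sorted({s for s in patch_spots.values() if s >= 0})
        want = n_val_spots + n_test_spots
        if len(spots) < want + 1:
            warnings.warn(f"slide {slide_id}: only {len(spots)} spots for a "
                          f"{n_val_spots}+{n_test_spots} val/test draw; "
                          "degraded assignment")
        picked = list(rng.choice(spots, size=min(want, len(spots)),
                                 replace=False)) if spots else []
        val_spots = set(picked[:n_val_spots])
        test_spots = set(picked[n_val_spots:n_val_spots + n_test_spots])
        for s in spots:
            split = "val" if s in val_spots else \
                "test" if s in test_spots else "train"
            out.spot_split[(slide_id, s)] = split
        for pid, s in patch_spots.items():
            if s >= 0:
                out.patch_split[pid] = out.spot_split[(slide_id, s)]
    return out


def repair_patient_leakage(assignment: SplitAssignment,
                           patch_patient: dict[str, str]) -> SplitAssignment:
    """Force each patient into a single split (test wins over val over train)."""
    touches_test = {patch_patient[pid]
                    for pid, s in assignment.patch_split.items() if s == "test"}
    touches_val = {patch_patient[pid]
                   for pid, s in assignment.patch_split.items() if s == "val"}
    repaired = SplitAssignment(spot_split=dict(assignment.spot_split))
    for pid, split in assignment.patch_split.items():
        patient = patch_patient[pid]
        if patient in touches_test:
            repaired.patch_split[pid] = "test"
        elif patient in touches_val:
            repaired.patch_split[pid] = "val"
        else:
            repaired.patch_split[pid] = split
    return repaired
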