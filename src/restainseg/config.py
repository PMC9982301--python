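"""Pipeline configuration.

All numeric defaults are the pipeline's published operating constants
(patch geometry, intensity cutoffs, neighbourhood sizes, clustering
parameters) collected in one auditable place.  The config round-trips
losslessly through YAML and carries a stable content hash so every
artifact can be traced to the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    # -- geometry ---------------------------------------------------------
    mpp: float = 0.220818                  # microns per pixel at full resolution
    patch_size: int = 1024                 # patch side at extraction, px
    patch_stride: int = 1024
    edge_margin_px: int = 200              # tissue-edge exclusion zone
    registration_margin_px: int = 20       # cropped after non-rigid alignment

    # -- tissue detection -------------------------------------------------
    tissue_level: int = 4                  # pyramid level: 1/2**level of full res
    tissue_blur_kernel: int = 81           # Gaussian kernel side at tissue_level
    tissue_area_min_px2: float = 12.8e6    # connected-region bounds at full res
    tissue_area_max_px2: float = 256e6
    blur_threshold: float = 5e-4           # variance-of-Laplacian cutoff

    # -- registration -----------------------------------------------------
    coarse_level: int = 6                  # WSI-level rigid alignment
    patch_level: int = 1                   # patch-level rigid alignment
    demons_shrink_factors: tuple[int, ...] = (8, 4, 2)
    demons_smoothing_sigmas: tuple[float, ...] = (12.0, 8.0, 4.0)
    demons_learning_rate: float = 1.0
    demons_iterations: int = 20
    demons_variant: str = "metric"         # "metric" or "filter"
    min_peak_response: float = 0.1         # rigid-shift confidence floor

    # -- initial masks ----------------------------------------------------
    qc_correlation_min: float = 0.5        # hematoxylin-vs-DAPI Pearson r
    cutoff_strong: float = 50.0            # epithelium / smooth muscle / RBC
    cutoff_default: float = 25.0           # all other targets
    nucleus_overlap_cutoff: float = 0.40   # fraction of nucleus that must be positive

    # -- cutoff refinement ------------------------------------------------
    refine_blur_kernel: int = 11
    ridge_alpha: float = 1e-3
    positive_coeff_min: float = 1.0
    positive_intensity_min: float = 10.0
    otsu_neighbors: int = 8
    propagate_neighbors: int = 16
    propagate_sigma_px: float = 3000.0
    cutoff_clip: tuple[float, float] = (10.0, 50.0)
    epithelium_reduction: float = 0.8
    mcc_range: tuple[float, float] = (0.10, 0.80)
    mcc_step: float = 0.05
    refine_iterations: int = 2

    # -- dataset splitting ------------------------------------------------
    spot_eps_px: float = 3000.0            # DBSCAN neighbourhood for spot detection
    spot_min_samples: int = 5
    n_val_spots: int = 2
    n_test_spots: int = 2

    # -- multi-class merge ------------------------------------------------
    tile_px: int = 7680
    invert_base_layer: bool = False        # flip the stroma intensity convention

    # -- evaluation -------------------------------------------------------
    point_match_radius_px: float = 8.0
    consensus_min_votes: int = 2

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.nucleus_overlap_cutoff <= 1.0:
            raise ValueError("nucleus_overlap_cutoff must lie in [0, 1]")
        if self.cutoff_clip[0] > self.cutoff_clip[1]:
            raise ValueError("cutoff_clip bounds out of order")
        if self.patch_size <= 2 * self.registration_margin_px:
            raise ValueError("patch_size must exceed twice the registration margin")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the full configuration (for provenance manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
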