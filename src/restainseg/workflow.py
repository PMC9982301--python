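"""End-to-end orchestration over an on-disk workspace.

Each stage reads the previous stage's artifacts from the workspace
directory, writes its own, and records a manifest (inputs, outputs,
config hash, seed) so every artifact is traceable.  Reruns with the same
config and inputs are bit-identical.  The synthetic generator provides
the demonstration inputs; real slide pairs drop into the same layout.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import fixtures as fx
from . import io as rio
from . import maskgen, merge, refine, split
from .config import PipelineConfig
from .preprocess import (PatchRecord, blur_flag, detect_tissue_regions,
                         extract_patch_grid, patch_table, upsample_mask)
from .registration import ImagePyramid, alignment_channels, register_slide

STAGES = ["fixtures", "preprocess", "register", "maskgen", "refine",
          "split", "merge", "evaluate"]


def _manifest(workspace: Path, stage: str, config: PipelineConfig,
              inputs: list[str], outputs: list[str]) -> None:
    path = workspace / "manifests" / f"{stage}.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({
        "stage": stage, "config_hash": config.content_hash(),
        "seed": config.seed, "inputs": sorted(inputs),
        "outputs": sorted(outputs), "written_at": time.strftime("%Y-%m-%d"),
    }, indent=2))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def toy_fixture_spec(seed: int = 0) -> fx.FixtureSpec:
    """Desk-scale two-spot slide used by the demonstration pipeline."""
    return fx.FixtureSpec(image_height_px=1536, image_width_px=1536,
                          n_spots=4, nuclei_per_spot=35,
                          positive_fraction=0.5, stain_pattern="cytoplasmic",
                          rbc_count=4, global_shift_px=(6.0, -4.0),
                          deformation_amplitude_px=0.0,
                          if_gradient=(70.0, 0.02), seed=seed)


def toy_config(seed: int = 0) -> PipelineConfig:
    """Config with geometry scaled to the toy fixture (defaults fit real WSIs)."""
    return PipelineConfig(
        patch_size=128, patch_stride=128, edge_margin_px=24,
        tissue_area_min_px2=5e4, tissue_area_max_px2=1e9,
        coarse_level=3, patch_level=1,
        spot_eps_px=150.0, spot_min_samples=3,
        n_val_spots=1, n_test_spots=1,
        propagate_sigma_px=600.0, seed=seed)


def stage_fixtures(workspace: Path, config: PipelineConfig,
                   spec: fx.FixtureSpec | None = None) -> None:
    spec = spec or toy_fixture_spec(config.seed)
    hne, if_img, truth = fx.generate_slide_pair(spec)
    rio.write_image_pair(workspace, hne, if_img)
    rio.write_mask(workspace / "true_mask.png", truth.true_mask)
    rio.write_mask(workspace / "rbc_mask.png", truth.rbc_mask)
    rio.write_label_map(workspace / "nucleus_labels.png", truth.nucleus_labels)
    pd.DataFrame({
        "row": truth.nucleus_centers[:, 0] if len(truth.nucleus_centers) else [],
        "col": truth.nucleus_centers[:, 1] if len(truth.nucleus_centers) else [],
        "spot_id": truth.spot_ids,
        "positive": truth.positive,
    }).to_csv(workspace / "nucleus_centers.csv", index=False)
    np.save(workspace / "applied_deformation.npy", truth.applied_deformation)
    (workspace / "applied_shift.json").write_text(json.dumps(
        {"dy": truth.applied_shift[0], "dx": truth.applied_shift[1]}))
    ann = fx.generate_annotation_set(truth, n_annotators=3, miss_rate=0.1,
                                     jitter_px=2.0, seed=spec.seed)
    ann.to_geojson(workspace / "annotations.geojson")
    _manifest(workspace, "fixtures", config, [],
              ["slide_HE.tiff", "slide_IF.tiff", "true_mask.png",
               "nucleus_centers.csv", "annotations.geojson"])


def stage_preprocess(workspace: Path, config: PipelineConfig) -> None:
    hne = rio.read_tiff(workspace / "slide_HE.tiff")
    pyr = ImagePyramid(hne)
    level4 = pyr.level(config.tissue_level)
    regions = detect_tissue_regions(level4, config.tissue_blur_kernel,
                                    config.tissue_area_min_px2,
                                    config.tissue_area_max_px2)
    patches: list[PatchRecord] = []
    for region in regions:
        mask0 = upsample_mask(region.mask_at_level4,
                              2 ** config.tissue_level)[:hne.shape[0], :hne.shape[1]]
        patches += extract_patch_grid(mask0, slide_id="slide",
                                      size=config.patch_size,
                                      stride=config.patch_stride,
                                      edge_margin=config.edge_margin_px)
    for p in patches:
        r, c = p.origin_level0
        _, flagged = blur_flag(hne[r:r + p.size_px, c:c + p.size_px],
                               config.blur_threshold)
        if flagged:
            p.flag("blurred")
    patch_table(patches).to_csv(workspace / "patches.csv", index=False)
    _manifest(workspace, "preprocess", config, ["slide_HE.tiff"], ["patches.csv"])


def _load_patches(workspace: Path) -> list[PatchRecord]:
    df = pd.read_csv(workspace / "patches.csv")
    out = []
    for _, row in df.iterrows():
        p = PatchRecord(slide_id=row.slide_id, patch_id=row.patch_id,
                        origin_level0=(int(row.row), int(row.col)),
                        size_px=int(row.size_px), spot_id=int(row.spot_id))
        if isinstance(row.flags, str) and row.flags:
            p.qc_flags = set(row.flags.split("|"))
        out.append(p)
    return out


def stage_register(workspace: Path, config: PipelineConfig) -> None:
    hne = rio.read_tiff(workspace / "slide_HE.tiff")
    if_img = rio.read_tiff(workspace / "slide_IF.tiff")
    patches = [p for p in _load_patches(workspace) if not p.qc_flags]
    pairs = register_slide(hne, if_img, patches,
                           coarse_level=config.coarse_level,
                           patch_level=config.patch_level,
                           margin=config.registration_margin_px,
                           demons_kwargs={
                               "shrink_factors": config.demons_shrink_factors,
                               "smoothing_sigmas": config.demons_smoothing_sigmas,
                               "learning_rate": config.demons_learning_rate,
                               "iterations": config.demons_iterations,
                               "variant": config.demons_variant})
    reg_dir = workspace / "registered"
    rows = []
    for pair in pairs:
        stem = pair.provenance.patch_id
        rio.write_image_pair(reg_dir, pair.hne_patch, pair.if_patch, stem=stem)
        rows.append({"patch_id": stem, "dy": pair.translation.dy,
                     "dx": pair.translation.dx,
                     "peak_response": pair.translation.peak_response,
                     "demons_mean_px": float(np.linalg.norm(
                         pair.deformation, axis=-1).mean())})
    pd.DataFrame(rows).to_csv(workspace / "registration.csv", index=False)
    _manifest(workspace, "register", config,
              ["slide_HE.tiff", "slide_IF.tiff", "patches.csv"],
              ["registration.csv"])


def stage_maskgen(workspace: Path, config: PipelineConfig,
                  target: str = "aSMA") -> None:
    profile = maskgen.TargetProfile.for_target(target)
    reg = pd.read_csv(workspace / "registration.csv")
    mask_dir = workspace / "masks"
    rows = []
    for patch_id in reg.patch_id:
        hne = rio.read_tiff(workspace / "registered" / f"{patch_id}_HE.tiff")
        if_img = rio.read_tiff(workspace / "registered" / f"{patch_id}_IF.tiff")
        hema, dapi = alignment_channels(hne, if_img)
        r, keep = maskgen.qc_nuclear_correlation(hema, dapi,
                                                 config.qc_correlation_min)
        nuclei = maskgen.segment_nuclei(if_img[..., 0]) \
            if profile.mask_mode == "nucleus_transfer" else None
        rbc_pred = maskgen.rbc_color_mask(hne)
        mask = maskgen.make_initial_mask(
            if_img[..., 1], hne, profile, nuclei=nuclei, rbc_prediction=rbc_pred,
            overlap_cutoff=config.nucleus_overlap_cutoff)
        if keep:
            rio.write_mask(mask_dir / f"{patch_id}.png", mask)
        rows.append({"patch_id": patch_id, "nuclear_correlation": r,
                     "qc_pass": keep, "positive_px": int(mask.sum())})
    pd.DataFrame(rows).to_csv(workspace / "maskgen.csv", index=False)
    _manifest(workspace, "maskgen", config, ["registration.csv"],
              ["maskgen.csv"])


PREDICTOR_PLUGINS = {}


def predictor_plugin(name):
    def deco(fn):
        PREDICTOR_PLUGINS[name] = fn
        return fn
    return deco


@predictor_plugin("initial_mask")
def _initial_mask_predictor(workspace: Path, config: PipelineConfig,
                            profile: maskgen.TargetProfile):
    """Self-training surrogate: the initial mask acts as the probability map."""
    def predict(sample: refine.PatchSample) -> np.ndarray:
        return maskgen.make_initial_mask(
            sample.if_target, sample.hne, profile, nuclei=sample.nuclei,
            rbc_prediction=sample.rbc_mask).astype(float)
    return predict


def stage_refine(workspace: Path, config: PipelineConfig,
                 target: str = "aSMA", predictor: str = "initial_mask") -> None:
    profile = maskgen.TargetProfile.for_target(target)
    qc = pd.read_csv(workspace / "maskgen.csv")
    patches = {p.patch_id: p for p in _load_patches(workspace)}
    samples = []
    for patch_id in qc[qc.qc_pass].patch_id:
        hne = rio.read_tiff(workspace / "registered" / f"{patch_id}_HE.tiff")
        if_img = rio.read_tiff(workspace / "registered" / f"{patch_id}_IF.tiff")
        nuclei = maskgen.segment_nuclei(if_img[..., 0]) \
            if profile.mask_mode == "nucleus_transfer" else None
        samples.append(refine.PatchSample(
            if_target=if_img[..., 1], hne=hne,
            rbc_mask=maskgen.rbc_color_mask(hne), nuclei=nuclei,
            center_level0=patches[patch_id].center_level0, patch_id=patch_id))
    pred = PREDICTOR_PLUGINS[predictor](workspace, config, profile)
    result = refine.run_refinement(
        samples, pred, profile, n_iterations=config.refine_iterations,
        k_otsu=config.otsu_neighbors, k_propagate=config.propagate_neighbors,
        sigma_px=config.propagate_sigma_px, clip=config.cutoff_clip,
        mcc_range=config.mcc_range, mcc_step=config.mcc_step,
        overlap_cutoff=config.nucleus_overlap_cutoff)
    for sample, mask in zip(samples, result.masks):
        rio.write_mask(workspace / "refined_masks" / f"{sample.patch_id}.png", mask)
    pd.DataFrame([{
        "patch_id": pid, "cutoff": e.cutoff,
        "regression_coefficient": e.regression_coefficient,
        "max_if_intensity": e.max_if_intensity, "is_positive": e.is_positive,
    } for pid, e in result.thresholds.entries.items()]).to_csv(
        workspace / "thresholds.csv", index=False)
    pd.DataFrame({"iteration": range(1, len(result.flip_fractions) + 1),
                  "flip_fraction": result.flip_fractions}).to_csv(
        workspace / "flip_fractions.csv", index=False)
    _manifest(workspace, "refine", config, ["maskgen.csv"],
              ["thresholds.csv", "flip_fractions.csv"])


def stage_split(workspace: Path, config: PipelineConfig) -> None:
    df = pd.read_csv(workspace / "patches.csv")
    centers = np.stack([df.row + df.size_px / 2, df.col + df.size_px / 2], axis=1)
    spots = split.detect_spots(centers, eps=config.spot_eps_px,
                               min_samples=config.spot_min_samples)
    df["spot_id"] = spots
    per_slide = {}
    for _, row in df.iterrows():
        per_slide.setdefault(row.slide_id, {})[row.patch_id] = int(row.spot_id)
    assignment = split.assign_splits(per_slide, config.n_val_spots,
                                     config.n_test_spots, seed=config.seed)
    # two TMA spots per patient, as on a real array
    patient = {row.patch_id: f"P{int(row.spot_id) // 2}"
               for _, row in df.iterrows() if row.spot_id >= 0}
    assignment = split.repair_patient_leakage(assignment, patient)
    df["patient_id"] = [patient.get(pid, "") for pid in df.patch_id]
    df["split"] = [assignment.patch_split.get(pid, "excluded")
                   for pid in df.patch_id]
    df.to_csv(workspace / "patches.csv", index=False)
    _manifest(workspace, "split", config, ["patches.csv"], ["patches.csv"])


def stage_merge(workspace: Path, config: PipelineConfig,
                target: str = "aSMA") -> None:
    """Toy multi-class merge: the refined target masks drive one class' logits."""
    hne = rio.read_tiff(workspace / "slide_HE.tiff")
    target_class = {"panCK": 2, "aSMA": 3, "CD45": 4, "ERG": 5, "CD235a": 6,
                    "CD3_CD20": 7, "MIST1": 8, "MNDA": 9}[target]
    mask_dir = workspace / "refined_masks"
    patches = {p.patch_id: p for p in _load_patches(workspace)}
    full = np.zeros(hne.shape[:2], dtype=bool)
    m = config.registration_margin_px
    for path in sorted(mask_dir.glob("*.png")):
        patch = patches[path.stem]
        r, c = patch.origin_level0
        mask = rio.read_mask(path)
        full[r + m:r + m + mask.shape[0], c + m:c + m + mask.shape[1]] = mask
    hierarchy = merge.HierarchySpec()

    def absent(tile):
        return np.full(tile.shape[:2], -1.0)

    predictors = {cls: absent for cls in hierarchy.predicted_classes}
    predictors[target_class] = lambda tile, fm=full: _tile_logit(fm, tile)
    labels = merge.tiled_inference(hne, predictors, tile_px=config.tile_px,
                                   hierarchy=hierarchy,
                                   invert=config.invert_base_layer)
    rio.write_label_map(workspace / "label_map.png", labels)
    (workspace / "label_map.json").write_text(
        json.dumps(merge.label_map_metadata(), indent=2))
    _manifest(workspace, "merge", config, ["refined_masks"],
              ["label_map.png", "label_map.json"])


def _tile_logit(full_mask: np.ndarray, tile: np.ndarray) -> np.ndarray:
    # the toy slide fits in one tile: crop/pad the slide-level mask to the tile
    h, w = tile.shape[:2]
    out = np.full((h, w), -1.0)
    mh, mw = full_mask.shape
    out[:min(h, mh), :min(w, mw)] = np.where(full_mask[:h, :w], 1.0, -1.0)
    return out


def stage_evaluate(workspace: Path, config: PipelineConfig) -> None:
    truth_mask = rio.read_mask(workspace / "true_mask.png")
    m = config.registration_margin_px
    reports = []
    for path in sorted((workspace / "refined_masks").glob("*.png")):
        parts = path.stem.split("_")
        r, c = int(parts[-2]), int(parts[-1])
        mask = rio.read_mask(path)
        gt = truth_mask[r + m:r + m + mask.shape[0], c + m:c + m + mask.shape[1]]
        reports.append(ev.pixel_dice(gt, mask))
    pooled = ev.pooled_dice(reports) if reports else float("nan")
    ann = ev.AnnotationSet.from_geojson(workspace / "annotations.geojson")
    centers = pd.read_csv(workspace / "nucleus_centers.csv")
    gt_points = centers[["row", "col"]].to_numpy()
    cons = ev.consensus_points(ann, config.point_match_radius_px,
                               config.consensus_min_votes)
    cell = ev.cell_dice(gt_points, cons.astype(float),
                        config.point_match_radius_px)
    payload = {
        "pooled_pixel_dice": pooled,
        "n_eval_patches": len(reports),
        "consensus_cell_dice": cell.dice,
        "n_consensus_cells": int(len(cons)),
        "n_true_cells": int(len(gt_points)),
    }
    (workspace / "evaluation.json").write_text(json.dumps(payload, indent=2))
    pd.DataFrame([r.as_dict() for r in reports]).to_csv(
        workspace / "evaluation.csv", index=False)
    _manifest(workspace, "evaluate", config,
              ["refined_masks", "annotations.geojson"],
              ["evaluation.json", "evaluation.csv"])


STAGE_FUNCS = {
    "fixtures": stage_fixtures, "preprocess": stage_preprocess,
    "register": stage_register, "maskgen": stage_maskgen,
    "refine": stage_refine, "split": stage_split,
    "merge": stage_merge, "evaluate": stage_evaluate,
}


def run_pipeline(workspace: str | Path, config: PipelineConfig | None = None,
                 stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all) over one workspace."""
    workspace = Path(workspace)
    workspace.mkdir(parents=True, exist_ok=True)
    config = config or toy_config()
    for stage in stages or STAGES:
        if stage not in STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        STAGE_FUNCS[stage](workspace, config)
    return workspace
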