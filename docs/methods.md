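# Methods

## The problem and the model of the data

A destained-and-restained section yields two scans of the *same* tissue: an
RGB H&E image and a 2-channel IF image (DAPI + one target antibody). Because
the section is physically remounted between scans, the IF image is displaced
by a global translation plus a small, smooth, spatially varying deformation;
because staining chemistry is uneven, the IF signal amplitude drifts smoothly
across the slide. The pipeline's job is to undo the geometry (registration),
binarise the IF signal robustly (masking + cutoff refinement), and package
the result as a training dataset (splits, merged labels, metrics).

Both nuclear channels — the colour-deconvolved hematoxylin component
(`skimage.color.rgb2hed`) and DAPI — are the only structures reliably shared
between the modalities, so every alignment decision is driven by them.

## Registration cascade

Rigid estimates use phase correlation at integer precision; sub-pixel
residuals are deliberately left to the non-rigid stage. The per-patch
translations of one slide are pooled by a 2-D Gaussian KDE (Scott bandwidth)
and the input translation of maximal density becomes the slide consensus,
which suppresses per-patch failures on low-texture patches. When the KDE
covariance is singular (all translations identical or collinear) the modal
point is used instead — `scipy.stats.gaussian_kde` cannot represent that
case.

The non-rigid stage is a three-level Demons registration (shrink factors
8/4/2, smoothing sigmas 12/8/4) after histogram-matching DAPI onto the
hematoxylin map. The default variant optimises the Demons metric over a
displacement-field transform by gradient descent (learning rate 1.0, 20
iterations) via `SimpleITK.ImageRegistrationMethod`; the classic filter-based
Demons is available as `variant="filter"`. Demons is cross-modal here: even
for perfectly aligned pairs it produces a small nonzero field in non-nuclear
areas (cytoplasm and RBCs have no DAPI counterpart). The tests therefore
check the property that matters — nuclei stay aligned, the spurious field
stays below 1 px mean — rather than pixel identity of the warped image.

Interpolation is bilinear for images and nearest for masks (masks must stay
binary). Out-of-bounds samples replicate the edge; they can only live inside
the 20-px sacrificial margin, which is cropped, so no unregistered border
survives into the 984-px output.

## Tissue and patch rules

The tissue-edge rule ("discard patches within 200 px of the tissue edge") is
implemented exactly, as a Euclidean distance transform of the tissue mask
(slide boundary counted as non-tissue) with a strictly-greater test, which is
identical to erosion by a disk of radius 200 but cheaper and free of
upsampling artefacts. The patch grid is anchored at the top-left of the
*eroded* mask's bounding box, so the first retained row/column starts exactly
at the margin. The blur score is the variance of the 3×3 Laplacian of the
ITU-R 601 luminance scaled to [0, 1]; the 5e-4 threshold is only meaningful
on unit-scaled intensities. The 81×81 and 11×11 Gaussian kernels use
sigma = (k−1)/6 so the stated kernel size covers ±3 sigma.

## Cutoff refinement

The positive-patch regression fits probability = beta × intensity with zero
intercept and ridge penalty 1e-3, both maps smoothed with the 11×11 kernel
and the intensity normalised to [0, 1] — against a [0, 1] probability a
coefficient threshold of 1 is only attainable on normalised units. RBC
pixels are excluded from both the fit and the maximum-intensity condition.

The pooled Otsu threshold is computed on the 256-bin histogram of the patch
plus its 8 nearest positive patches, maximising the between-class variance
exhaustively. When the pooled histogram has an empty gap between its modes,
every threshold inside the gap scores identically; the centre of the tied
plateau is returned (as OpenCV does), so a background/signal histogram at
5 and 60 thresholds near 32 instead of hugging the background mode. This
tie rule is what lets the refined cutoffs track a smooth staining gradient.

Propagation weights are w = exp(−d²/(2·3000²)) over the 16 nearest positive
patches; the result is a convex combination of positive cutoffs, so the clip
bounds [10, 50] can never be escaped by propagation. "Over 40%" nucleus
overlap is a strict inequality, read literally. The 20% epithelium reduction
is applied after clipping. The Matthews-correlation grid (0.10–0.80, step
0.05) pools pixel counts over all evaluation patches before computing one
MCC per grid point; undefined MCCs score 0 and ties break toward the lower
rate. RBC suppression is applied at the signal level, before nucleus
transfer.

## Hierarchical merge

The label update is applied exactly as specified: layer 0 assigns stroma
where the grayscale intensity strictly exceeds the slide-level Otsu
threshold (an `invert` flag is provided because the natural intensity
convention — tissue darker than background — is the opposite; the default
follows the stated rule), and layers 1–3 overwrite a pixel iff the layer's
maximum logit is strictly positive, argmax ties breaking toward the lowest
label id. Ensembles average logits pixelwise; probability-only predictors
are converted through log-odds. Tiling uses one slide-level Otsu threshold
and edge-padded tiles, so tiled and untiled outputs are bit-identical for
deterministic predictors.

## Splits and evaluation

DBSCAN (eps 3,000 px, min_samples 5) on patch centres recovers TMA spots;
noise points are excluded from the splits. Validation/test spots are drawn
with a seeded RNG (the selection rule itself is otherwise unspecified).
Leakage repair gives test precedence over validation, mirroring the stated
move order, and is idempotent.

Point consensus links annotator points by single-linkage at an inclusive
8-px radius ("within 8 px" read as ≤ 8); a component counts when ≥ 2
distinct annotators back it. Point-set scoring uses greedy nearest-first
one-to-one matching with ties broken by index, deterministic. Cell-level
false positives against a mask prediction are counted per connected
component. Dice with both sides empty is defined as 1.0 and flagged, which
keeps pooled reports NaN-free.

## Synthetic slides

The generator renders elliptical nuclei (radius 9–13 px at 0.220818 µm/px,
i.e. 4–6 µm — the scale the watershed fallback expects) dark in H&E and
bright in DAPI; target signal in a nuclear, cytoplasmic or membranous
pattern around each positive cell; RBCs red in H&E (the colour rule holds
for every RBC pixel by construction) and autofluorescent in the target
channel; a linear IF amplitude gradient whose half-amplitude is recorded as
the true per-pixel cutoff; and a global shift plus an amplitude-capped,
Gaussian-smoothed random deformation applied to the IF frame. All channels
are 8-bit; coordinates are (row, col), 0-based, half-open. Identical
(spec, seed) is bit-identical output.

What the generator does *not* emulate: realistic stain texture and colour
variation, nucleus clumping and overlap, tissue folds, out-of-focus bands
with structured blur, autofluorescence outside RBCs, or scanner artefacts.
Passing tests therefore demonstrate the correctness of the pipeline's
geometry, rules and numerics under the stated noise model — not segmentation
performance on real tissue.

## Problem sizes and defaults

Synthetic checks run at desk scale by choice: 1,300-px slides with one
1,024-px patch for registration recovery, a 1,024-px slide cut into sixteen
256-px patches for cutoff refinement (propagation scale reduced to 600 px to
match the shrunken geometry), and a 1,536-px four-spot / two-patient slide
with 128-px patches for the end-to-end demonstration pipeline
(`restainseg.workflow.toy_config`). All production defaults
(`PipelineConfig`) keep the published operating constants: 1,024/1,024/200
patch geometry, 20-px registration margin, cutoffs 50/25, clip [10, 50],
neighbourhoods 8 and 16, propagation scale 3,000 px, DBSCAN 3,000 px / 5,
7,680-px tiles.

## Known limitations

Rotation and scale changes between scans are not modelled (translation +
Demons only). The fallback watershed segmenter under-performs any learned
instance segmenter on crowded nuclei; it exists to keep the pipeline
self-contained and to validate the transfer logic. The demonstration
pipeline's "initial-mask" predictor is a self-training surrogate, not a
trained network; on real data the predictor contract should be filled by a
segmentation model's probability output.
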