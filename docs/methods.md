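# Methods

This note records what each stage computes, the defaults that matter, the
choices made where the procedure was genuinely open, and what the synthetic
phantom does and does not establish about real data.

## Data model and conventions

Stacks are 8-bit grayscale arrays indexed `(slice, row, col)` with voxel size
(z, y, x) = (50, 10, 10) nm by default. Labels use a fixed 4-code alphabet:
0 background, 1 cell (cytoplasm), 2 nuclear envelope, 3 nucleus. Slice ranges
are written in the 1-based inclusive `start:step:stop` dialect (`"101:2:180"`
= 40 alternate central slices); all internal indexing is 0-based, converted
once at the parse boundary. Pixel coordinates are 0-based `(row, col)`;
window extents are half-open.

## Traditional image-processing segmentation

Per slice: Gaussian low-pass (σ = 2 px) → Canny edges → connected components
of the edge complement ("superpixels", 4-connectivity so 8-connected edge
curves partition the plane) → region selection → closing with a disk of
radius 5 px. The volume is segmented from the central slice outward, each
slice's nucleus mask serving as the prior for its outward neighbor.

Choices the procedure leaves open, and what this implementation does:

* **Canny thresholds** are data-driven: high = Otsu threshold of the Sobel
  gradient magnitude of the smoothed slice, low = 0.4·high. A constant slice
  returns an empty edge map.
* **Region filters.** Regions smaller than `min_area` (500 px at the
  2000-px reference scale, scaled by `(side/2000)²`) or touching the image
  border are discarded. Regions whose filled area exceeds 1.5× their own
  area are also discarded: such regions are membrane-like rings (the
  edge-free interior of the envelope band, or the cytoplasm annulus between
  envelope and plasma membrane), not nuclear regions, and without this test
  the propagation latches onto the annulus that surrounds the nucleus.
* **"Central region".** On the starting slice the region containing the
  image center pixel is selected (an annulus can have its *centroid* at the
  center too); if no candidate contains it, the nearest-centroid candidate
  is used.
* **Prior rule.** A region qualifies when its overlap with the prior dilated
  by a 20-px disk exceeds 50% of the region's own area — this is what picks
  up disjoint nucleus fragments. Two continuity guards apply: the region's
  mean (smoothed) intensity must match the propagated nuclear brightness
  within 20 gray levels (the nuclear interior looks the same on adjacent
  50-nm slices; cytoplasm is darker), and a mask larger than 2.5× the prior
  reports the nucleus as lost rather than accepting a cytoplasm-sized jump.
  An empty slice keeps the last non-empty mask as prior, so the chain never
  restarts unconditioned.
* **Background segmentation** thresholds the σ = 8 smoothed slice with Otsu
  and keeps the bright side, subject to two guards: background must be
  near-saturation bright (≥ 170 on the 8-bit scale — embedding resin images
  much brighter than any organelle) and background components must touch the
  frame border. Holes smaller than 10⁴ px (reference scale, scaled by area)
  are filled. Without the guards, the bright nucleus of a frame fully
  covered by one cell would be classed as background.
* **Cell detection** ranks local maxima of the distance transform of the
  background complement and greedily suppresses seeds closer than half the
  crop side; salience ties break by (row, col). Fewer maxima than requested
  yields a shorter list with a logged warning.
* **Automatic 4-class labels** for a cell-centered crop: nucleus from the
  pipeline above; envelope as the geometric band immediately *outside* the
  nucleus (width = `envelope_thickness`, default 5 px) — placing the band
  outside rather than centered on the boundary keeps the nucleus class
  un-eroded and matches the ring geometry; cell as the
  foreground component containing the nucleus (or crop center); everything
  else background. During automatic mining, cells whose crop cannot be
  centered inside the frame are skipped — the labeling assumes a centered
  cell, which fails at frame edges.

The module is deterministic end to end.

## Patch factory

Pairs are 128×128 aligned image/label windows on a 50%-overlap grid
(stride 64); trailing margins that do not fit a whole window are dropped, so
one 2000×2000 slice yields 30×30 = 900 pairs. The five strategies: s1/s2 use
40 alternate central slices (36,000 pairs, single-nucleus vs multi-nuclei
manual ground truth), s3 every other slice of the whole stack (135,000),
s4 mines 15 spread-out full frames automatically (10 cells per frame,
2000-px crops, 135,000), and s5 is the concatenation of s3 and s4 (270,000).
Every recipe scales down (patch, crop, cell count, slice range) for
desk-size runs; label patches are copied verbatim, never relabeled. Pairs
are stored as paired PNGs plus a CSV manifest.

## U-Net

Depth-4 encoder/decoder: per level two 3×3 "same" convolutions + ReLU and a
2×2 max-pool; a two-conv bridge; per decoder level a 2×2 stride-2 transposed
convolution, skip concatenation and two conv+ReLU blocks; a final 1×1
convolution to 4 classes and a softmax. Counting every Conv, ReLU, MaxPool,
TransposedConv, the final 1×1 Conv and the Softmax as one layer each — skip
concatenations are wiring, not layers — the model has 4·5 + 4 + 4·5 + 1 + 1
= 46 layers. Channels run 64→128→256→512 with 1024 at the bridge at full
scale. Defaults: 128-px patches, 15 epochs, Adam at 10⁻³, batch 64,
unweighted per-pixel cross-entropy, no validation split or early stopping.
"Same" padding keeps outputs at input size, so any input whose sides divide
2⁴ passes through.

The implementation is pure numpy: im2col convolutions over BLAS matrix
products, explicit backward passes (verified against finite differences),
and Adam written out. This makes training CPU-bound: tests and the demo use
reduced settings (base 4–8 channels, 32/64-px patches, tens to hundreds of
pairs), which train in seconds to minutes on one CPU, while the full-scale
defaults remain available. Initialization is He-normal from the config seed;
identical data + config + seed reproduce the loss trace exactly on one
device. Inference over large slices is tiled: tiles at stride tile/2,
keeping each tile's central tile/2 block for the mosaic, reflective padding
at borders (iterated when a pad exceeds the image size, so slices smaller
than one tile work). Argmax ties break toward the lowest class code.

## Post-processing

Per class: fill holes, close with a 3-px disk (then fill again — closing can
create new enclosed holes), and remove connected components strictly smaller
than `min_area` (a component of exactly `min_area` survives). The default
threshold is 0.08% of the slice area — 3200 px at 2000×2000 — and scales
with slice size. The envelope gets the repair step instead of hole-filling:
dilate the cleaned nucleus and cell by the closing radius and add their
overlap to the envelope, which closes small ring discontinuities. Cleaned
masks are re-aggregated with precedence nucleus > envelope > cell >
background; pixels claimed by no cleaned mask keep their input class, so the
output is total. Background is not hole-filled (holes in background are
cells). The operation is idempotent and strictly 2D (applied per slice).

## Evaluation

Accuracy `(TP+TN)/(TP+TN+FP+FN)` and Jaccard `TP/(TP+FP+FN)` per slice on a
binary mask — by default nucleus vs everything else, with the envelope
excluded from the positive set (an option includes it, and per-class
evaluation is available). A slice with empty ground truth and empty
prediction has undefined Jaccard (flagged, excluded from range means,
accuracy 1); non-empty ground truth with an empty prediction scores 0 —
the regime at stack ends where a nucleus is present but missed. Range
summaries are unweighted per-slice means over 1-based ranges.

## Synthetic phantom

Each cell is a star-convex cytoplasm blob containing a star-convex nucleus
(low-order radial Fourier perturbation; `invagination_amplitude` sets the
peak relative boundary deflection, so 0.4 produces clearly non-convex
nuclei). The envelope is the `envelope_thickness_px`-wide band immediately
outside the nucleus. Nucleus radius follows a spherical-cap profile along z
with 6% per-slice jitter, so nuclei shrink and grow irregular toward the
stack ends; the cytoplasm cap is 25% taller, so extreme slices show cells
without nuclei. Cells are placed without overlap (rejection sampling; an
impossible request raises); the first cell sits at the frame center and is
the ROI target.

Rendering starts from the configured class means — default (200, 110, 45,
140) for (background, cytoplasm, envelope, nucleus); background must be
brightest — and adds a structured perturbation: slowly varying background
shading, band-passed cytoplasm texture (amplitude 6, 0.3× inside the
nucleus), per-cell brightness offsets (±8, emulating cell-to-cell appearance
variability), and a few dark mitochondria-like ellipses per cell. The
perturbation is quantized to integers and exactly de-meaned within each
class, so ground-truth-masked class means recover the configured means
exactly at any noise level; `noise_sigma` adds white Gaussian noise on top.
All randomness flows from the single spec seed.

What the phantom does **not** emulate: organelle-rich cytoplasm beyond
simple ellipses, charging/curtaining and other acquisition artifacts,
anisotropic texture, touching cells, and the full morphological diversity of
real cells. Passing tests therefore establish that the pipeline's logic and
numerics behave as designed on EM-like geometry and contrast; they do not
certify accuracy figures on real microscope volumes, whose reproduction
requires the public data and full-scale training and is out of scope here.

## Scaled experiments

The acceptance script and test suite run everything at desk scale, sizes
chosen as the package's own study conditions: the noise-free recovery run
uses a 512²×40 single-cell ROI (nucleus radius 100 px — the full-scale
nucleus-to-crop ratio); the training smoke run uses 200 pairs of 64-px
patches for 3 epochs at 8 base channels; the single-cell vs multi-cell
comparison trains two 8-channel models per seed (160 pairs of 64-px patches,
25 epochs — enough to train past the point where the nucleus class emerges
at this scale, so the comparison measures the training data rather than
optimization luck) on one frame and evaluates volume-level nucleus Jaccard
on a held-out frame generated from an independent seed, repeated over three
seeds with a majority decision. Both the one-cell and the many-cell pair
sources are labeled by the same automatic pipeline, so the comparison
isolates the number of source cells rather than confounding it with label
quality. The demo uses a 320²×20 phantom
and a 12-epoch, 32-px-patch network so the whole chain finishes in about a
minute.

## Known limitations

* The IP pipeline assumes one roughly centered cell per ROI and segments
  only that nucleus; it does not track instances across slices or handle
  frames where the cell is clipped.
* The numpy U-Net trains at practical speed only at reduced scale; there is
  no GPU path, no augmentation, no class weighting.
* The noise-monotonicity of IP recovery holds up to tie-level wiggle
  (≲ 0.005 Jaccard) at small phantom sizes, where pixel discretization
  dominates between low noise levels.
* Post-processing precedence (nucleus > envelope > cell > background) is a
  convention; conflicts between cleaned masks are rare but resolved, not
  reported.
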