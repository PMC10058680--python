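"""Build training patch-pair sets from image/label volumes.

A training unit is a :class:`PatchPair`: a square intensity patch and the
aligned class patch cut from the same window.  Patches tile each selected
slice on a regular grid with 50% overlap (stride = patch/2); trailing margins
that do not fit a full window are dropped, so a 2000-px side yields
30 windows of 128 px and one 2000x2000 slice yields 900 pairs.

Five named strategies mirror the study design:

====================  =============================================================
``s1_single36k``      40 alternate central slices (101:2:180), manual ground truth
                      with only the central nucleus labeled
``s2_multi36k``       same slices, manual ground truth with all nuclei labeled
``s3_multi135k``      every other slice of the whole stack (1:2:300), multi-nuclei
                      ground truth
``s4_auto135k``       15 spread-out full frames (230:10:370); per frame the 10 most
                      salient cells are detected, cropped and auto-labeled by the
                      image-processing pipeline; 900 pairs per crop
``s5_union270k``      concatenation of s3 and s4
====================  =============================================================

Slice ranges and sizes above are the full-study defaults; every recipe scales
down (smaller crops, fewer cells, shorter ranges) for desk-size runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio

from . import ip_segmentation as ipseg
from .volume_io import LabelVolume, VolumeStack, slice_indices

logger = logging.getLogger(__name__)

PATCH_SIZE = 128
OVERLAP = 0.5


class PatchError(Exception):
    pass


@dataclass
class PatchPair:
    """An aligned (image, label) window and where it came from."""

    image: np.ndarray
    label: np.ndarray
    origin: tuple[int, int, int, str]   # (slice index 0-based, row, col, source id)


@dataclass
class TrainingStrategy:
    """A named recipe producing a patch-pair set."""

    name: str
    slice_range: str
    gt_source: str       # manual | automatic | union
    gt_variant: str      # single-nucleus | multi-nuclei | n/a
    n_cells: int = 10
    crop: int = 2000
    patch: int = PATCH_SIZE
    overlap: float = OVERLAP


#: The five study strategies at full scale.
STRATEGIES: dict[str, TrainingStrategy] = {
    "s1_single36k": TrainingStrategy("s1_single36k", "101:2:180", "manual", "single-nucleus"),
    "s2_multi36k": TrainingStrategy("s2_multi36k", "101:2:180", "manual", "multi-nuclei"),
    "s3_multi135k": TrainingStrategy("s3_multi135k", "1:2:300", "manual", "multi-nuclei"),
    "s4_auto135k": TrainingStrategy("s4_auto135k", "230:10:370", "automatic", "n/a"),
    "s5_union270k": TrainingStrategy("s5_union270k", "1:2:300", "union", "multi-nuclei"),
}


def grid_positions(length: int, patch: int = PATCH_SIZE, stride: int | None = None) -> list[int]:
    """Window offsets 0, stride, ... with offset+patch <= length.

    >>> len(grid_positions(2000, 128, 64))
    30
    """
    if stride is None:
        stride = patch // 2
    if patch > length:
        raise PatchError(f"patch {patch} larger than length {length}")
    if stride < 1:
        raise PatchError(f"stride must be >= 1, got {stride}")
    return list(range(0, length - patch + 1, stride))


def pairs_per_slice(side: int, patch: int = PATCH_SIZE, overlap: float = OVERLAP) -> int:
    """Number of pairs one square slice yields (grid per side, squared)."""
    stride = max(1, int(round(patch * (1.0 - overlap))))
    return len(grid_positions(side, patch, stride)) ** 2


def extract_pairs(volume: VolumeStack | np.ndarray, labels: LabelVolume | np.ndarray,
                  slice_range: str | list[int] | None = None,
                  patch: int = PATCH_SIZE, overlap: float = OVERLAP,
                  source: str = "roi") -> list[PatchPair]:
    """Cut the full 2D grid of patch pairs from the listed slices.

    *slice_range* is a 1-based ``"a:s:b"`` string, a list of 0-based indices,
    or None for all slices.  Label patches are copied verbatim from the label
    volume — no relabeling happens during extraction.
    """
    img = volume.data if isinstance(volume, VolumeStack) else np.asarray(volume)
    lab = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    if img.shape != lab.shape:
        raise PatchError(f"volume {img.shape} and labels {lab.shape} not congruent")
    nz, h, w = img.shape
    if slice_range is None:
        zs = list(range(nz))
    elif isinstance(slice_range, str):
        zs = slice_indices(slice_range, nz)
    else:
        zs = list(slice_range)
        if zs and (min(zs) < 0 or max(zs) >= nz):
            raise PatchError(f"slice index out of range for stack of {nz}")
    stride = max(1, int(round(patch * (1.0 - overlap))))
    rows = grid_positions(h, patch, stride)
    cols = grid_positions(w, patch, stride)
    pairs = []
    for z in zs:
        for r in rows:
            for c in cols:
                pairs.append(PatchPair(
                    image=img[z, r:r + patch, c:c + patch].copy(),
                    label=lab[z, r:r + patch, c:c + patch].copy(),
                    origin=(z, r, c, source)))
    return pairs


def _crop_centered(arr: np.ndarray, center: tuple[int, int], size: int) -> np.ndarray:
    """Clamped square crop around *center* (stays inside the frame)."""
    h, w = arr.shape
    r0 = int(np.clip(center[0] - size // 2, 0, h - size))
    c0 = int(np.clip(center[1] - size // 2, 0, w - size))
    return arr[r0:r0 + size, c0:c0 + size]


def auto_pairs_from_frames(frames: list[np.ndarray], strategy: TrainingStrategy,
                           envelope_thickness: int = ipseg.DEFAULT_ENVELOPE_THICKNESS,
                           ) -> list[PatchPair]:
    """Strategy-4 core: detect cells in each full frame, crop, auto-label with
    the image-processing pipeline and extract the patch grid per crop.

    Seeds are recomputed per frame independently.  Seeds whose crop cannot be
    centered inside the frame are skipped — the labeling assumes the cell sits
    at the crop center, which fails for cells at the frame edge.  A frame with
    fewer usable cells than requested contributes proportionally fewer pairs
    (logged as a shortfall).
    """
    pairs: list[PatchPair] = []
    for fi, frame in enumerate(frames):
        frame = np.asarray(frame)
        bg = ipseg.segment_background(frame)
        seeds = ipseg.detect_cells(frame, n=strategy.n_cells,
                                   min_separation=strategy.crop // 2, background=bg)
        half = strategy.crop // 2
        seeds = [s for s in seeds
                 if half <= s.centroid[0] <= frame.shape[0] - half
                 and half <= s.centroid[1] <= frame.shape[1] - half]
        if len(seeds) < strategy.n_cells:
            logger.warning("frame %d: only %d of %d usable cells",
                           fi, len(seeds), strategy.n_cells)
        for si, seed in enumerate(seeds):
            crop = _crop_centered(np.asarray(frame), seed.centroid, strategy.crop)
            auto = ipseg.segment_cell_roi(crop, envelope_thickness=envelope_thickness)
            pairs.extend(extract_pairs(
                crop[None], auto.data, patch=strategy.patch, overlap=strategy.overlap,
                source=f"auto_f{fi}_c{si}"))
    return pairs


def build_training_set(strategy: TrainingStrategy | str,
                       roi: VolumeStack | None = None,
                       gt_single: LabelVolume | None = None,
                       gt_multi: LabelVolume | None = None,
                       frames: list[np.ndarray] | None = None,
                       slice_range: str | None = None,
                       **overrides) -> list[PatchPair]:
    """Assemble the patch-pair set of one training strategy.

    Manual strategies need *roi* plus the ground-truth variant they declare;
    the automatic strategy needs *frames* (the full slices to mine); the
    union strategy needs all of these.  *slice_range* and keyword overrides
    (``n_cells``, ``crop``, ``patch``...) rescale a recipe for small runs.
    """
    if isinstance(strategy, str):
        if strategy not in STRATEGIES:
            raise PatchError(f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}")
        strategy = STRATEGIES[strategy]
    if slice_range is not None or overrides:
        strategy = replace(strategy, **({"slice_range": slice_range} if slice_range else {}),
                           **overrides)

    if strategy.gt_source == "manual":
        gt = gt_single if strategy.gt_variant == "single-nucleus" else gt_multi
        if roi is None or gt is None:
            raise PatchError(
                f"strategy {strategy.name} needs the ROI and its "
                f"{strategy.gt_variant} ground truth")
        return extract_pairs(roi, gt, strategy.slice_range,
                             patch=strategy.patch, overlap=strategy.overlap,
                             source=strategy.name)
    if strategy.gt_source == "automatic":
        if frames is None:
            raise PatchError(f"strategy {strategy.name} needs full frames to mine")
        return auto_pairs_from_frames(frames, strategy)
    if strategy.gt_source == "union":
        s3 = build_training_set(replace(STRATEGIES["s3_multi135k"],
                                        slice_range=strategy.slice_range,
                                        patch=strategy.patch, overlap=strategy.overlap),
                                roi=roi, gt_multi=gt_multi)
        s4 = build_training_set(replace(STRATEGIES["s4_auto135k"],
                                        n_cells=strategy.n_cells, crop=strategy.crop,
                                        patch=strategy.patch, overlap=strategy.overlap),
                                frames=frames)
        return s3 + s4
    raise PatchError(f"unknown gt_source {strategy.gt_source!r}")


def save_pairs(pairs: list[PatchPair], out_dir: str | Path,
               strategy: str = "") -> Path:
    """Write pairs as PNG files plus a CSV manifest; returns the manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(pairs):
        fi, fl = f"images/pair_{i:06d}.png", f"labels/pair_{i:06d}.png"
        iio.imwrite(str(out / fi), p.image)
        iio.imwrite(str(out / fl), p.label)
        z, r, c, src = p.origin
        rows.append(dict(file_image=fi, file_label=fl, slice=z, row=r, col=c,
                         source=src, strategy=strategy))
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_pairs(manifest: str | Path) -> list[PatchPair]:
    """Read a pair set back from its CSV manifest."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    base = manifest.parent
    return [
        PatchPair(image=iio.imread(str(base / row.file_image)),
                  label=iio.imread(str(base / row.file_label)),
                  origin=(int(row.slice), int(row.row), int(row.col), str(row.source)))
        for row in df.itertuples()
    ]
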