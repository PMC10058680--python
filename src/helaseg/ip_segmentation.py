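"""Traditional image-processing segmentation of a HeLa nucleus in EM stacks.

The pipeline runs per slice and propagates through the stack:

1. low-pass (Gaussian) filtering to suppress acquisition noise;
2. Canny edge detection with data-driven hysteresis thresholds;
3. "superpixels" = connected components of the edge-free complement;
4. morphological region selection: drop small regions and regions touching
   the image border, keep the region(s) matching the propagated prior (or,
   on the starting slice, the region closest to the image center), then
   smooth with morphological closing;
5. propagation: starting at the central slice, each slice's nucleus mask is
   the prior for its outward neighbor, which lets disjoint regions that
   belong to the same nucleus be picked up across slices.

On full frames the module also segments the bright smooth background and
detects cells as local maxima of the distance transform of the background
complement, which seeds automatic 4-class labeling of cropped cells.

The module is fully deterministic: no randomness anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology

from .volume_io import CELL, ENVELOPE, NUCLEUS, LabelVolume, VolumeStack

logger = logging.getLogger(__name__)

# Parameter defaults, stated at the 2000x2000 ROI scale where applicable.
DEFAULT_DENOISE_SIGMA = 2.0
DEFAULT_MIN_AREA_2000 = 500          # px at 2000^2; scaled by (side/2000)^2
DEFAULT_CLOSING_RADIUS = 5
DEFAULT_PRIOR_DILATION = 20
DEFAULT_PRIOR_OVERLAP = 0.5
DEFAULT_BG_SIGMA = 8.0
DEFAULT_BG_HOLE_AREA_2000 = 10_000   # px at 2000^2; scaled by (side/2000)^2
DEFAULT_BG_MIN_INTENSITY = 170.0     # resin is near-saturation on the 8-bit scale
DEFAULT_ENVELOPE_THICKNESS = 5


class SegmentationError(Exception):
    pass


@dataclass
class CellSeed:
    """A detected cell: centroid and its distance-transform salience."""

    centroid: tuple[int, int]   # (row, col)
    salience: float


def scaled_min_area(side: int, base: int = DEFAULT_MIN_AREA_2000) -> int:
    """Area thresholds anchored at the 2000-px reference scale."""
    return max(1, int(round(base * (side / 2000.0) ** 2)))


def denoise(slice_: np.ndarray, sigma: float = DEFAULT_DENOISE_SIGMA) -> np.ndarray:
    """Gaussian low-pass filter; ``sigma=0`` returns the input unchanged."""
    if sigma < 0:
        raise SegmentationError(f"sigma must be >= 0, got {sigma}")
    img = np.asarray(slice_, dtype=np.float64)
    if sigma == 0:
        return img
    return ndi.gaussian_filter(img, sigma=sigma)


def detect_edges(slice_: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Canny edge map with hysteresis thresholds derived from the data:
    high = Otsu threshold of the smoothed gradient magnitude, low = 0.4*high."""
    img = np.asarray(slice_, dtype=np.float64)
    grad = filters.sobel(ndi.gaussian_filter(img, sigma))
    if grad.max() <= 1e-12:
        return np.zeros(img.shape, dtype=bool)
    high = filters.threshold_otsu(grad)
    low = 0.4 * high
    return feature.canny(img, sigma=sigma, low_threshold=low, high_threshold=high)


def superpixels_from_edges(edges: np.ndarray) -> np.ndarray:
    """Label connected components of the edge complement; edge pixels get 0.

    4-connectivity is used so that 8-connected Canny curves actually
    partition the plane.
    """
    edges = np.asarray(edges, dtype=bool)
    return measure.label(~edges, connectivity=1)


def select_nucleus_region(spx: np.ndarray, prior: np.ndarray | None = None,
                          min_area: int | None = None,
                          closing_radius: int = DEFAULT_CLOSING_RADIUS,
                          prior_dilation: int = DEFAULT_PRIOR_DILATION,
                          prior_overlap: float = DEFAULT_PRIOR_OVERLAP,
                          intensity: np.ndarray | None = None,
                          prior_mean: float | None = None,
                          intensity_tol: float = 20.0) -> np.ndarray:
    """Pick the nucleus from a superpixel map of an ROI slice.

    Regions smaller than *min_area* or touching the image border are
    discarded.  With a *prior* (the neighboring slice's nucleus), every
    surviving region whose overlap with the dilated prior exceeds
    *prior_overlap* of its own area is kept — this is what lets disjoint
    nucleus fragments be collected.  When *intensity* and *prior_mean* are
    given, a region must also match the propagated nuclear brightness within
    *intensity_tol* gray levels (the nuclear interior looks the same on
    adjacent 50-nm slices; cytoplasm is darker).  Without a prior the region
    whose centroid lies closest to the image center is kept.  The result is
    smoothed by morphological closing.  Returns an all-false mask when no
    region survives (nucleus absent at this slice).
    """
    spx = np.asarray(spx)
    h, w = spx.shape
    if min_area is None:
        min_area = scaled_min_area(max(h, w))

    props = measure.regionprops(spx)
    candidates = []
    for p in props:
        if p.area < min_area:
            continue
        r0, c0, r1, c1 = p.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            continue
        # membrane-like regions (the edge-free interior of the envelope band,
        # or the cytoplasm annulus) enclose large holes; nuclear regions are
        # filled blobs.  Discard regions whose filled area dwarfs their area.
        if p.area_filled > 1.5 * p.area:
            continue
        candidates.append(p)
    if not candidates:
        return np.zeros((h, w), dtype=bool)

    mask = np.zeros((h, w), dtype=bool)
    if prior is not None and np.asarray(prior).any():
        prior_arr = np.asarray(prior, bool)
        prior_d = ndi.binary_dilation(prior_arr,
                                      structure=morphology.disk(prior_dilation))
        for p in candidates:
            region = spx == p.label
            if (region & prior_d).sum() <= prior_overlap * p.area:
                continue
            if intensity is not None and prior_mean is not None and \
                    abs(float(intensity[region].mean()) - prior_mean) > intensity_tol:
                continue
            mask |= region
        # continuity guard: the nucleus area varies smoothly between adjacent
        # slices; a mask several times the prior means the selection latched
        # onto surrounding cytoplasm, so report the nucleus as lost instead
        if mask.sum() > 2.5 * prior_arr.sum():
            return np.zeros((h, w), dtype=bool)
        if not mask.any():
            return mask
    else:
        # "central region": the one containing the image center if any
        # (an annular region can have its centroid at the center too),
        # otherwise the candidate with the nearest centroid
        center_label = spx[h // 2, w // 2]
        hit = [p for p in candidates if p.label == center_label]
        if hit:
            best = hit[0]
        else:
            center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
            best = min(candidates,
                       key=lambda p: float(np.hypot(*(np.asarray(p.centroid) - center))))
        mask = spx == best.label

    if closing_radius > 0:
        mask = ndi.binary_closing(mask, structure=morphology.disk(closing_radius))
    return mask


def _segment_slice(slice_: np.ndarray, prior: np.ndarray | None,
                   sigma: float, min_area: int | None, closing_radius: int,
                   prior_mean: float | None = None) -> np.ndarray:
    den = denoise(slice_, sigma)
    edges = detect_edges(den)
    spx = superpixels_from_edges(edges)
    return select_nucleus_region(spx, prior=prior, min_area=min_area,
                                 closing_radius=closing_radius,
                                 intensity=den, prior_mean=prior_mean)


def segment_nucleus_volume(roi: VolumeStack | np.ndarray,
                           sigma: float = DEFAULT_DENOISE_SIGMA,
                           min_area: int | None = None,
                           closing_radius: int = DEFAULT_CLOSING_RADIUS) -> np.ndarray:
    """Segment the nucleus of the (roughly centered) cell in an ROI stack.

    The central slice is segmented without a prior; the result then
    propagates outward, each slice's mask acting as the prior for the next
    slice up/down the stack.  Returns a boolean (slice, row, col) volume.
    """
    data = roi.data if isinstance(roi, VolumeStack) else np.asarray(roi)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.size == 0:
        raise SegmentationError("expected a non-empty 3D stack")
    nz = data.shape[0]
    out = np.zeros(data.shape, dtype=bool)
    mid = nz // 2
    out[mid] = _segment_slice(data[mid], None, sigma, min_area, closing_radius)

    def _mean_under(z: int, mask: np.ndarray) -> float:
        return float(denoise(data[z], sigma)[mask].mean())

    # outward propagation; an empty slice keeps the last non-empty mask (and
    # its nuclear brightness) as prior so the chain never restarts
    # unconditioned on cytoplasm
    for direction in (range(mid + 1, nz), range(mid - 1, -1, -1)):
        prior = out[mid] if out[mid].any() else None
        prior_mean = _mean_under(mid, out[mid]) if prior is not None else None
        for z in direction:
            out[z] = _segment_slice(data[z], prior, sigma, min_area,
                                    closing_radius, prior_mean=prior_mean)
            if out[z].any():
                prior = out[z]
                prior_mean = _mean_under(z, out[z])
    return out


def segment_background(frame: np.ndarray, sigma: float = DEFAULT_BG_SIGMA,
                       hole_area: int | None = None,
                       bg_min_intensity: float = DEFAULT_BG_MIN_INTENSITY) -> np.ndarray:
    """Mask of the bright, smooth background of a full frame.

    Otsu threshold on the heavily smoothed slice, keeping the bright side.
    Two guards keep bright intracellular regions out: the background must be
    near-saturation bright (>= *bg_min_intensity*; embedding resin images
    much brighter than any organelle), and background components must touch
    the frame border.  Small holes are filled so textured background stays in
    one piece.  The complement approximates the union of the cells.
    """
    img = np.asarray(frame, dtype=np.float64)
    h, w = img.shape
    if hole_area is None:
        hole_area = scaled_min_area(max(h, w), DEFAULT_BG_HOLE_AREA_2000)
    sm = ndi.gaussian_filter(img, sigma)
    if sm.max() - sm.min() <= 1e-9:
        # featureless frame: all background iff bright enough to be resin
        return np.full(img.shape, bool(sm.flat[0] >= bg_min_intensity))
    thr = filters.threshold_otsu(sm)
    bright = (sm > thr) & (sm >= bg_min_intensity)
    if not bright.any():
        return bright
    # background must reach the frame border
    lab = measure.label(bright, connectivity=1)
    border_labels = np.unique(np.concatenate([
        lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))
    border_labels = border_labels[border_labels > 0]
    mask = np.isin(lab, border_labels)
    if mask.any():
        # fill small enclosed holes (texture pockets), keep large ones (cells)
        holes, _ = ndi.label(~mask, structure=np.ones((3, 3), dtype=int))
        border = np.unique(np.concatenate([
            holes[0, :], holes[-1, :], holes[:, 0], holes[:, -1]]))
        sizes = np.bincount(holes.ravel())
        small = np.flatnonzero(sizes < hole_area)
        small = np.setdiff1d(small[small > 0], border)
        mask |= np.isin(holes, small)
    return mask


def detect_cells(frame: np.ndarray, n: int = 10,
                 min_separation: int | None = None,
                 background: np.ndarray | None = None) -> list[CellSeed]:
    """Detect up to *n* cells as the most salient maxima of the distance
    transform of the background complement.

    Seeds are ranked by distance-transform value and greedily suppressed so
    no two seeds lie closer than *min_separation* (default: a quarter of the
    frame side, i.e. half the crop side at the usual crop = side/2).  Ties in
    salience break by (row, col) order.  Fewer than *n* maxima yields a
    shorter list with a logged warning.
    """
    img = np.asarray(frame)
    if background is None:
        background = segment_background(img)
    fg = ~background
    if not fg.any():
        return []
    if min_separation is None:
        min_separation = max(img.shape) // 4
    dist = ndi.distance_transform_edt(fg)
    # local maxima of the distance map, coarse grid suppression via max filter
    mx = ndi.maximum_filter(dist, size=5)
    peaks = np.argwhere((dist == mx) & (dist > 0))
    saliences = dist[tuple(peaks.T)]
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -saliences))
    seeds: list[CellSeed] = []
    for i in order:
        r, c = int(peaks[i, 0]), int(peaks[i, 1])
        if all(np.hypot(r - s.centroid[0], c - s.centroid[1]) >= min_separation
               for s in seeds):
            seeds.append(CellSeed(centroid=(r, c), salience=float(saliences[i])))
            if len(seeds) == n:
                break
    if len(seeds) < n:
        logger.warning("detect_cells: found %d of %d requested seeds", len(seeds), n)
    return seeds


def envelope_band(nucleus: np.ndarray,
                  thickness: int = DEFAULT_ENVELOPE_THICKNESS) -> np.ndarray:
    """Geometric nuclear-envelope band: the *thickness*-wide ring immediately
    outside the nucleus mask."""
    nucleus = np.asarray(nucleus, bool)
    if not nucleus.any():
        return np.zeros_like(nucleus)
    return ndi.binary_dilation(nucleus, structure=morphology.disk(thickness)) & ~nucleus


def segment_cell_roi(roi: VolumeStack | np.ndarray,
                     envelope_thickness: int = DEFAULT_ENVELOPE_THICKNESS,
                     sigma: float = DEFAULT_DENOISE_SIGMA,
                     min_area: int | None = None) -> LabelVolume:
    """Automatic 4-class labeling of an ROI centered on one cell.

    Nucleus from the per-slice pipeline with 3D propagation; envelope as the
    geometric band just outside the nucleus; cell as the foreground
    (background complement) component containing the nucleus (or the ROI
    center when the nucleus is absent); everything else background.  An ROI
    with neither nucleus nor foreground yields an all-background label.
    """
    data = roi.data if isinstance(roi, VolumeStack) else np.asarray(roi)
    if data.ndim == 2:
        data = data[None]
    nz, h, w = data.shape
    nucleus = segment_nucleus_volume(data, sigma=sigma, min_area=min_area)
    labels = np.zeros(data.shape, dtype=np.uint8)
    for z in range(nz):
        bg = segment_background(data[z])
        fg = ~bg
        sl = labels[z]
        if fg.any():
            comp = measure.label(fg, connectivity=1)
            if nucleus[z].any():
                ids = np.unique(comp[nucleus[z]])
            else:
                ids = np.atleast_1d(comp[h // 2, w // 2])
            ids = ids[ids > 0]
            if ids.size:
                sl[np.isin(comp, ids)] = CELL
        if nucleus[z].any():
            env = envelope_band(nucleus[z], envelope_thickness)
            sl[env] = ENVELOPE
            sl[nucleus[z]] = NUCLEUS
    return LabelVolume(labels)
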