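"""I/O and coordinate conventions for EM image stacks and 4-class label volumes.

The whole package works on 8-bit grayscale stacks indexed ``(slice, row, col)``
and on label volumes over four semantic classes::

    0  background   (bright, smooth resin outside the cells)
    1  cell         (cytoplasm, everything inside the plasma membrane that is
                     neither nucleus nor nuclear envelope)
    2  nuclear envelope  (thin dark ring separating nucleus from cytoplasm)
    3  nucleus

Slice ranges are written in the 1-based inclusive ``start:step:stop`` dialect
common in the EM literature (e.g. ``"101:2:180"`` = every other slice of the
central region); conversion to 0-based indices happens once, at the parse
boundary.  Pixel coordinates are 0-based ``(row, col)`` and window extents are
half-open.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

# Class codes, ordered: background < cell < envelope < nucleus.
BACKGROUND = 0
CELL = 1
ENVELOPE = 2
NUCLEUS = 3
CLASS_NAMES = ("background", "cell", "nuclear_envelope", "nucleus")
N_CLASSES = 4

#: Acquisition voxel size (z, y, x) in nanometres.
DEFAULT_VOXEL_SIZE_NM = (50.0, 10.0, 10.0)

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


class VolumeIOError(Exception):
    """Raised for malformed stacks, label alphabets or slice-range strings."""


@dataclass
class VolumeStack:
    """A 3D grayscale intensity volume, ``data[slice, row, col]`` in [0, 255]."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeIOError(f"expected 3D (slice,row,col) data, got ndim={self.data.ndim}")
        if self.data.size == 0:
            raise VolumeIOError("empty volume (0 slices)")
        lo, hi = self.data.min(), self.data.max()
        if lo < 0 or hi > 255:
            raise VolumeIOError(f"intensities outside [0,255]: min={lo}, max={hi}")
        self.data = self.data.astype(np.uint8, copy=False)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Per-voxel class codes over the fixed 4-class alphabet, same layout as
    its :class:`VolumeStack`."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM
    classes: tuple[str, ...] = field(default=CLASS_NAMES)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeIOError(f"expected 3D (slice,row,col) labels, got ndim={self.data.ndim}")
        if self.data.size == 0:
            raise VolumeIOError("empty label volume (0 slices)")
        bad = np.setdiff1d(np.unique(self.data), np.arange(N_CLASSES))
        if bad.size:
            raise VolumeIOError(f"label codes outside {{0..3}}: {bad.tolist()}")
        self.data = self.data.astype(np.uint8, copy=False)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _read_pages(path: Path) -> np.ndarray:
    """Read a multi-page TIFF / single image file into (n, rows, cols)."""
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise VolumeIOError(f"{path}: expected 2D pages, got shape {arr.shape}")
    return arr


def read_stack(path: str | os.PathLike, kind: str = "image") -> VolumeStack | LabelVolume:
    """Read an image or label stack.

    Parameters
    ----------
    path
        Either a multi-page TIFF file, or a directory of single-slice
        TIFF/PNG files ordered lexicographically by filename.
    kind
        ``"image"`` for intensities, ``"label"`` for 4-class label maps
        (codes outside {0..3} raise).
    """
    if kind not in ("image", "label"):
        raise ValueError(f"kind must be 'image' or 'label', got {kind!r}")
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise VolumeIOError(f"{p}: no TIFF/PNG slices found")
        slices = []
        for f in files:
            pages = _read_pages(f)
            slices.extend(pages)
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise VolumeIOError(f"{p}: mixed slice shapes {sorted(shapes)}")
        data = np.stack(slices)
    elif p.is_file():
        data = _read_pages(p)
    else:
        raise VolumeIOError(f"{p}: no such file or directory")
    if kind == "label":
        return LabelVolume(data)
    return VolumeStack(data)


def write_stack(volume: VolumeStack | LabelVolume, path: str | os.PathLike,
                format: str = "tiff") -> list[Path]:
    """Write a stack; round-trips bit-exactly through :func:`read_stack`.

    ``format="tiff"`` writes one multi-page TIFF at *path*; ``"dir-tiff"`` /
    ``"dir-png"`` write one file per slice (``slice_000.tif`` ...) into the
    directory *path*.  Returns the written file paths.
    """
    data = volume.data
    if data.size == 0:  # defensive; constructors already reject this
        raise VolumeIOError("refusing to write an empty volume")
    p = Path(path)
    if format == "tiff":
        p.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(str(p), data, photometric="minisblack")
        return [p]
    if format in ("dir-tiff", "dir-png"):
        ext = ".tif" if format == "dir-tiff" else ".png"
        p.mkdir(parents=True, exist_ok=True)
        out = []
        for i, sl in enumerate(data):
            f = p / f"slice_{i:04d}{ext}"
            if ext == ".tif":
                tifffile.imwrite(str(f), sl)
            else:
                iio.imwrite(str(f), sl)
            out.append(f)
        return out
    raise ValueError(f"unknown format {format!r}")


_RANGE_RE = re.compile(r"^\s*(\d+)\s*:\s*(\d+)\s*:\s*(\d+)\s*$")


def parse_slice_range(spec: str) -> list[int]:
    """Parse 1-based inclusive ``"start:step:stop"`` into a list of 1-based
    slice indices; *stop* is included only when it lies on the lattice.

    >>> parse_slice_range("101:2:180")[:3]
    [101, 103, 105]
    """
    m = _RANGE_RE.match(spec)
    if not m:
        raise VolumeIOError(f"malformed slice range {spec!r}; expected 'start:step:stop'")
    a, s, b = (int(g) for g in m.groups())
    if a < 1 or s < 1 or a > b:
        raise VolumeIOError(f"invalid slice range {spec!r}: need 1 <= start <= stop, step >= 1")
    return list(range(a, b + 1, s))


def slice_indices(spec: str, n_slices: int | None = None) -> list[int]:
    """1-based range string -> 0-based indices, bounds-checked against a stack."""
    idx = [i - 1 for i in parse_slice_range(spec)]
    if n_slices is not None and idx[-1] >= n_slices:
        raise VolumeIOError(f"slice range {spec!r} exceeds stack of {n_slices} slices")
    return idx


# Overlay colors: cell red, nuclear envelope blue, nucleus green.
_OVERLAY_RGB = {CELL: (255, 64, 64), ENVELOPE: (64, 64, 255), NUCLEUS: (64, 255, 64)}


def label_overlay(image_slice: np.ndarray, label_slice: np.ndarray,
                  alpha: float = 0.4) -> np.ndarray:
    """Blend class shading over a grayscale slice; returns an RGB uint8 array."""
    img = np.asarray(image_slice, dtype=np.float32)
    rgb = np.repeat(img[..., None], 3, axis=-1)
    for code, color in _OVERLAY_RGB.items():
        m = label_slice == code
        rgb[m] = (1 - alpha) * rgb[m] + alpha * np.array(color, dtype=np.float32)
    return np.clip(rgb, 0, 255).astype(np.uint8)


def write_overlay(image_slice: np.ndarray, label_slice: np.ndarray,
                  path: str | os.PathLike, alpha: float = 0.4) -> Path:
    """Export a label overlay as an RGB PNG."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(str(p), label_overlay(image_slice, label_slice, alpha))
    return p
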