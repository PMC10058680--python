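"""Synthetic serial block-face EM phantoms with exact 4-class ground truth.

Real SBF-SEM frames of HeLa cells show a bright, smooth resin background and
darker textured cells, each with a large nucleus wrapped in a thin dark
nuclear-envelope ring.  The phantom emulates exactly those features:

* each cell is a star-convex cytoplasm blob containing a star-convex nucleus
  (a low-order radial Fourier perturbation imitates envelope invaginations);
* the nuclear envelope is the ``envelope_thickness_px``-wide band immediately
  outside the nucleus;
* the nucleus radius follows a spherical-cap profile along z with per-slice
  jitter, so nuclei shrink and grow irregular toward the first and last
  slices — the regime where segmentation is hardest;
* the image always carries cytoplasm texture, a slowly varying background
  field and a few dark mitochondria-like ellipses (real cytoplasm is never
  flat); the structured perturbation is exactly de-meaned per class, so
  ground-truth-masked intensity means recover the configured class means
  exactly, and ``noise_sigma`` controls only the additional white noise.

All randomness flows from the single ``seed`` in the spec; identical specs
produce identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage as ndi

from .volume_io import (
    BACKGROUND, CELL, ENVELOPE, NUCLEUS,
    LabelVolume, VolumeStack,
)


class PhantomError(Exception):
    """Raised for invalid phantom specs or impossible cell placements."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic EM scene.

    ``intensity_means`` is ordered (background, cytoplasm, envelope, nucleus)
    on the 8-bit scale; the background must be the brightest class.
    """

    frame_size: int = 512
    n_slices: int = 60
    n_cells: int = 4
    nucleus_radius_px: tuple[float, float] = (60.0, 10.0)  # (mean, jitter)
    envelope_thickness_px: int = 5
    invagination_amplitude: float = 0.15
    intensity_means: tuple[float, float, float, float] = (200.0, 110.0, 45.0, 140.0)
    noise_sigma: float = 5.0
    texture_amplitude: float = 6.0
    cell_intensity_jitter: float = 8.0
    n_mitochondria_per_cell: int = 3
    cytoplasm_ratio: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        bg, cyt, env, nuc = self.intensity_means
        if not (bg > cyt and bg > env):
            raise PhantomError("background mean must exceed cytoplasm and envelope means")
        if self.envelope_thickness_px < 1:
            raise PhantomError("envelope_thickness_px must be >= 1")
        if not (0.0 <= self.invagination_amplitude < 1.0):
            raise PhantomError("invagination_amplitude must be in [0, 1)")
        if self.frame_size < 32 or self.n_slices < 1 or self.n_cells < 1:
            raise PhantomError("frame_size/n_slices/n_cells too small")
        if self.noise_sigma < 0:
            raise PhantomError("noise_sigma must be >= 0")


@dataclass
class _Cell:
    center: tuple[float, float]          # (row, col)
    r_nuc: float
    r_cyt: float
    z_center: float
    hz_nuc: float
    hz_cyt: float
    nuc_profile: np.ndarray              # radial perturbation coefficients
    cyt_profile: np.ndarray
    z_jitter: np.ndarray                 # per-slice multiplicative jitter
    intensity_offset: float


def _radial_profile(rng: np.random.Generator, amplitude: float,
                    harmonics=(2, 3, 4, 5)) -> np.ndarray:
    """Coefficients (a_k, phi_k) of a star-convex boundary perturbation with
    peak relative amplitude = *amplitude*."""
    a = rng.uniform(0.3, 1.0, size=len(harmonics))
    phi = rng.uniform(0, 2 * np.pi, size=len(harmonics))
    coeffs = np.stack([np.asarray(harmonics, float), a, phi], axis=1)
    # normalize so max |sum a_k cos(...)| over a dense grid equals amplitude
    theta = np.linspace(0, 2 * np.pi, 720)
    p = sum(ak * np.cos(k * theta + pk) for k, ak, pk in coeffs)
    peak = np.abs(p).max()
    if peak > 0:
        coeffs[:, 1] *= amplitude / peak
    return coeffs


def _eval_profile(coeffs: np.ndarray, theta: np.ndarray) -> np.ndarray:
    out = np.zeros_like(theta)
    for k, ak, pk in coeffs:
        out += ak * np.cos(k * theta + pk)
    return out


def _place_cells(spec: PhantomSpec, rng: np.random.Generator) -> list[_Cell]:
    size, mid = spec.frame_size, spec.frame_size / 2.0
    r_mean, r_jit = spec.nucleus_radius_px
    cells: list[_Cell] = []
    max_tries = 2000
    for i in range(spec.n_cells):
        r_nuc = max(5.0, r_mean + rng.uniform(-r_jit, r_jit))
        r_cyt = r_nuc * spec.cytoplasm_ratio
        placed = False
        for _ in range(max_tries):
            if i == 0:
                center = (mid, mid)  # designated ROI cell sits at the frame center
            else:
                margin = 0.35 * r_cyt
                center = tuple(rng.uniform(margin, size - margin, size=2))
            ok = all(
                np.hypot(center[0] - c.center[0], center[1] - c.center[1])
                >= 0.95 * (r_cyt + c.r_cyt) + 4
                for c in cells
            )
            if ok:
                placed = True
                break
            if i == 0:
                break
        if not placed:
            raise PhantomError(
                f"could not place {spec.n_cells} non-overlapping cells in a "
                f"{size}x{size} frame (failed at cell {i})")
        if i == 0:
            z_center = spec.n_slices / 2.0
        else:
            z_center = spec.n_slices * rng.uniform(0.3, 0.7)
        hz_nuc = spec.n_slices * rng.uniform(0.38, 0.48)
        cells.append(_Cell(
            center=center, r_nuc=r_nuc, r_cyt=r_cyt,
            z_center=z_center, hz_nuc=hz_nuc, hz_cyt=hz_nuc * 1.25,
            nuc_profile=_radial_profile(rng, spec.invagination_amplitude),
            cyt_profile=_radial_profile(rng, min(0.08, spec.invagination_amplitude)),
            z_jitter=1.0 + 0.06 * rng.standard_normal(spec.n_slices),
            intensity_offset=rng.uniform(-1, 1) * spec.cell_intensity_jitter,
        ))
    return cells


def _cap(z: np.ndarray | float, zc: float, hz: float) -> np.ndarray | float:
    """Spherical-cap radius scale in [0,1]; 0 outside the cap."""
    u = (z - zc) / hz
    return np.sqrt(np.clip(1.0 - u * u, 0.0, None))


def generate_phantom(spec: PhantomSpec, return_instances: bool = False):
    """Generate an EM-like image volume and its exact 4-class label volume.

    Returns ``(VolumeStack, LabelVolume)``; with ``return_instances=True`` a
    third int array is returned holding the owning cell index per voxel
    (-1 for background), which tests use to reason about individual cells.
    """
    rng = np.random.default_rng(spec.seed)
    cells = _place_cells(spec, rng)
    size, nz, t = spec.frame_size, spec.n_slices, spec.envelope_thickness_px

    labels = np.zeros((nz, size, size), dtype=np.uint8)
    instances = np.full((nz, size, size), -1, dtype=np.int16)
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    selem = _disk(t)

    for ci, cell in enumerate(cells):
        dr, dc = rr - cell.center[0], cc - cell.center[1]
        dist = np.hypot(dr, dc)
        theta = np.arctan2(dr, dc)
        pn = _eval_profile(cell.nuc_profile, theta)
        pc = _eval_profile(cell.cyt_profile, theta)
        for z in range(nz):
            sc_n = float(_cap(z, cell.z_center, cell.hz_nuc)) * cell.z_jitter[z]
            sc_c = float(_cap(z, cell.z_center, cell.hz_cyt))
            if sc_c <= 0:
                continue
            rn = cell.r_nuc * sc_n * (1.0 + pn)
            nucleus = dist < rn if cell.r_nuc * sc_n > 2.5 else np.zeros_like(dist, bool)
            # cytoplasm always leaves room for the envelope band + margin
            rc = np.maximum(cell.r_cyt * sc_c * (1.0 + pc),
                            (rn + t + 3) if nucleus.any() else 0.0)
            cyto = dist < rc
            if not cyto.any():
                continue
            sl_lab = labels[z]
            sl_lab[cyto] = CELL
            if nucleus.any():
                env = ndi.binary_dilation(nucleus, structure=selem) & ~nucleus
                sl_lab[env] = ENVELOPE
                sl_lab[nucleus] = NUCLEUS
            instances[z][cyto] = ci

    image = _render(spec, labels, instances, cells, rng)
    vol = VolumeStack(image)
    lab = LabelVolume(labels)
    if return_instances:
        return vol, lab, instances
    return vol, lab


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    return (x * x + y * y) <= r * r


def _render(spec: PhantomSpec, labels: np.ndarray, instances: np.ndarray,
            cells: list[_Cell], rng: np.random.Generator) -> np.ndarray:
    """Render intensities.

    The image is the class-mean lookup plus a structured perturbation field
    (background shading, cytoplasm/nucleus texture, per-cell brightness
    offsets, dark mitochondria-like ellipses).  The perturbation is quantised
    to integers and exactly de-meaned within each class, so GT-masked class
    means always recover the configured means exactly — even before the final
    additive Gaussian noise, which is only applied for ``noise_sigma > 0``.
    """
    means = np.rint(np.asarray(spec.intensity_means)).astype(np.int64)
    img = means[labels]
    nz, size = labels.shape[0], labels.shape[1]

    pert = np.zeros(labels.shape, dtype=np.float64)
    # slowly varying background shading
    low = ndi.gaussian_filter(rng.standard_normal((nz, size, size)),
                              sigma=(0, size / 10, size / 10))
    low *= 6.0 / max(low.std(), 1e-9)
    bgm = labels == BACKGROUND
    pert[bgm] += low[bgm]
    # fine texture in cytoplasm (strong) and nucleus (mild)
    tex = ndi.gaussian_filter(rng.standard_normal((nz, size, size)), sigma=(0, 1.5, 1.5))
    tex *= spec.texture_amplitude / max(tex.std(), 1e-9)
    pert[labels == CELL] += tex[labels == CELL]
    pert[labels == NUCLEUS] += 0.3 * tex[labels == NUCLEUS]
    # per-cell brightness offsets (cell-to-cell appearance variability)
    for ci, cell in enumerate(cells):
        m = (instances == ci) & ((labels == CELL) | (labels == NUCLEUS))
        pert[m] += cell.intensity_offset
    # dark mitochondria-like ellipses inside the cytoplasm
    for ci, cell in enumerate(cells):
        for _ in range(spec.n_mitochondria_per_cell):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(cell.r_nuc + spec.envelope_thickness_px + 6,
                              max(cell.r_cyt * 0.9, cell.r_nuc + 10))
            er, ec = (cell.center[0] + rad * np.sin(ang),
                      cell.center[1] + rad * np.cos(ang))
            a, b = rng.uniform(4, 9), rng.uniform(2, 5)
            z0 = int(rng.uniform(0, nz))
            zspan = range(max(0, z0 - 2), min(nz, z0 + 3))
            dr2 = ((np.arange(size) - er)[:, None] / a) ** 2 \
                + ((np.arange(size) - ec)[None, :] / b) ** 2
            ell = dr2 < 1.0
            for z in zspan:
                m = ell & (labels[z] == CELL) & (instances[z] == ci)
                pert[z][m] -= 35.0

    ipert = np.rint(np.clip(pert, -45, 45)).astype(np.int64)
    for c in range(4):
        m = labels == c
        npx = int(m.sum())
        if npx == 0:
            continue
        vals = ipert[m]
        q, r = divmod(int(vals.sum()), npx)
        vals -= q
        if r:
            vals[:r] -= 1      # distribute the remainder; class sum is now 0
        ipert[m] = vals
    img = img + ipert
    if spec.noise_sigma > 0:
        img = img + np.rint(rng.normal(0.0, spec.noise_sigma, img.shape)).astype(np.int64)
    return np.clip(img, 0, 255).astype(np.uint8)


@dataclass
class PhantomScene:
    """A full frame plus a centered ROI crop around the designated cell."""

    frame_image: VolumeStack
    frame_labels: LabelVolume
    roi_image: VolumeStack
    roi_labels: LabelVolume
    roi_offset: tuple[int, int]   # (row0, col0) of the crop in frame coordinates
    instances: np.ndarray | None = None


def phantom_roi_and_frame(spec: PhantomSpec, roi_size: int | None = None) -> PhantomScene:
    """Generate a frame and crop an ROI centered on the designated cell
    (cell 0, placed at the frame center), recording the crop offset so frame
    and ROI labels stay aligned."""
    if roi_size is None:
        roi_size = spec.frame_size // 2
    if roi_size > spec.frame_size:
        raise PhantomError(f"roi_size {roi_size} exceeds frame_size {spec.frame_size}")
    vol, lab, inst = generate_phantom(spec, return_instances=True)
    mid = spec.frame_size // 2
    r0 = mid - roi_size // 2
    c0 = mid - roi_size // 2
    if r0 < 0 or r0 + roi_size > spec.frame_size:
        raise PhantomError("ROI crop exceeds frame bounds")
    sl = np.s_[:, r0:r0 + roi_size, c0:c0 + roi_size]
    return PhantomScene(
        frame_image=vol, frame_labels=lab,
        roi_image=VolumeStack(vol.data[sl].copy()),
        roi_labels=LabelVolume(lab.data[sl].copy()),
        roi_offset=(r0, c0), instances=inst,
    )


def single_nucleus_variant(labels: LabelVolume, instances: np.ndarray,
                           keep_cell: int = 0) -> LabelVolume:
    """Ground-truth variant in which only the designated cell's nucleus and
    envelope keep their classes; other cells' nuclei/envelopes are relabeled
    as plain cell.  Mirrors the distinction between annotating a single
    central nucleus versus all nuclei visible in a crop."""
    data = labels.data.copy()
    other = (instances != keep_cell) & np.isin(data, (ENVELOPE, NUCLEUS))
    data[other] = CELL
    return LabelVolume(data)
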