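"""Semi-automated breast-volume segmentation and cross-dataset mask transfer.

The segmentation mimics an interactive workflow: intensity thresholding
of the in-phase image, morphological despeckling of background noise
(keeping the skin), a straight coronal cut at the most anterior position
of the pectoral muscle, and a midsagittal split into left and right
breasts. Masks can be carried to other datasets after a
mutual-information translation registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image import VolumeImage

__all__ = [
    "SegmentationMask",
    "RigidShift",
    "body_mask",
    "cut_index_on_grid",
    "pectoral_cut_and_split",
    "register_translation",
    "transfer_mask",
]


def cut_index_on_grid(plane_index: int, src_spacing_y: float,
                      dst_spacing_y: float) -> int:
    """Convert a coronal cut index between grids conservatively.

    The floor keeps only voxel centres strictly anterior to the physical
    cut plane, so that chest-wall signal interpolated onto a coarser
    grid can never survive the cut.
    """
    return int(np.floor(plane_index * src_spacing_y / dst_spacing_y + 1e-6))

# 6-connected structuring element: faces only
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegmentationMask:
    """Binary breast mask plus its provenance."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    laterality: str = "both"  # "L" | "R" | "both"
    posterior_cut_index: int | None = None
    threshold: float | None = None
    erosion_iters: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def as_volume(self) -> VolumeImage:
        return VolumeImage(self.data.astype(np.uint8), self.spacing)


@dataclass
class RigidShift:
    """Translation (mm) mapping a moving volume onto a fixed one."""

    shift_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.shift_mm = tuple(float(s) for s in self.shift_mm)
        if not all(np.isfinite(self.shift_mm)):
            raise ValueError("shift must be finite")


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_STRUCT6)
    if n <= 1:
        return mask
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == int(sizes.argmax())


def body_mask(
    in_phase: VolumeImage,
    threshold: float | str = "auto",
    erosion_iters: int = 1,
) -> SegmentationMask:
    """Threshold the in-phase image and clean up background speckle.

    Voxels at or above the threshold are kept; ``erosion_iters`` rounds
    of 6-connected binary erosion remove isolated noise voxels, a
    matched dilation restores the surviving component's boundary
    (including the skin), and only the largest connected component is
    retained. ``threshold="auto"`` uses Otsu's method on the magnitude
    histogram.
    """
    data = np.abs(in_phase.data)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"threshold must be a number or 'auto', got {threshold!r}")
        thr = float(threshold_otsu(data))
    else:
        thr = float(threshold)
    raw = data >= thr
    if not raw.any():
        raise ValueError(
            f"threshold {thr:g} leaves an empty mask (image max {data.max():g}); "
            "lower the threshold"
        )
    if erosion_iters < 0:
        raise ValueError("erosion_iters must be >= 0")

    cleaned = raw
    if erosion_iters > 0:
        eroded = ndimage.binary_erosion(raw, _STRUCT6, iterations=erosion_iters)
        if eroded.any():
            # reconstruct the surviving structures within the raw mask:
            # specks thinner than the erosion vanish, the body boundary
            # (incl. skin) is restored exactly
            cleaned = ndimage.binary_propagation(eroded, structure=_STRUCT6, mask=raw)
        # else: every structure is thinner than the erosion; keep raw mask
    cleaned = _largest_component(cleaned)
    return SegmentationMask(
        cleaned, in_phase.spacing, laterality="both",
        threshold=thr, erosion_iters=erosion_iters,
    )


def pectoral_cut_and_split(
    mask: SegmentationMask, cut_index: int
) -> tuple[SegmentationMask, SegmentationMask]:
    """Apply the straight coronal pectoral cut and split left/right.

    Voxels with coronal index ``>= cut_index`` (at or posterior to the
    most anterior pectoral position) are removed; the rest is split at
    the midsagittal plane. Returns ``(left, right)``; the right breast
    occupies the lower ``x`` indices.
    """
    ny = mask.data.shape[1]
    if not (0 <= cut_index <= ny):
        raise ValueError(f"cut index {cut_index} outside grid (ny={ny})")
    cut = mask.data.copy()
    cut[:, cut_index:, :] = False
    if not cut.any():
        raise ValueError("pectoral cut removed every voxel; check cut index")

    mid = mask.data.shape[0] // 2
    right = np.zeros_like(cut)
    left = np.zeros_like(cut)
    right[:mid] = cut[:mid]
    left[mid:] = cut[mid:]

    def _side(arr, lat):
        return SegmentationMask(
            arr, mask.spacing, laterality=lat, posterior_cut_index=cut_index,
            threshold=mask.threshold, erosion_iters=mask.erosion_iters,
        )

    return _side(left, "L"), _side(right, "R")


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _overlap_slices(shape, shift_vox):
    """Index slices of fixed and moving arrays overlapping under an
    integer voxel shift (moving displaced by +shift)."""
    fix, mov = [], []
    for n, d in zip(shape, shift_vox):
        if d >= 0:
            fix.append(slice(d, n))
            mov.append(slice(0, n - d))
        else:
            fix.append(slice(0, n + d))
            mov.append(slice(-d, n))
    return tuple(fix), tuple(mov)


def register_translation(
    fixed: VolumeImage,
    moving: VolumeImage,
    search_radius_mm: float = 10.0,
    bins: int = 32,
) -> RigidShift:
    """Find the translation that best aligns ``moving`` to ``fixed`` by
    maximizing mutual information.

    An exhaustive integer-voxel grid search within ``search_radius_mm``
    (32-bin joint histogram over the overlap region) is refined per axis
    by a quadratic fit through the three best-neighbouring MI values,
    giving sub-voxel precision. Mutual information is invariant to
    monotone intensity remapping, so datasets with different contrast
    register as well as identical ones.
    """
    if fixed.shape != moving.shape:
        raise ValueError("grid-search registration requires equal shapes")
    a = np.abs(np.asarray(fixed.data, dtype=np.float64))
    b = np.abs(np.asarray(moving.data, dtype=np.float64))
    if a.max() == a.min() or b.max() == b.min():
        raise ValueError("cannot register a constant image")

    radii = [max(1, int(round(search_radius_mm / s))) for s in fixed.spacing]
    mi = {}

    def score(dv):
        if dv not in mi:
            fs, ms = _overlap_slices(a.shape, dv)
            if any(s.stop - s.start < 2 for s in fs):
                mi[dv] = -np.inf
            else:
                mi[dv] = _mutual_information(a[fs], b[ms], bins=bins)
        return mi[dv]

    best = (0, 0, 0)
    for dx in range(-radii[0], radii[0] + 1):
        for dy in range(-radii[1], radii[1] + 1):
            for dz in range(-radii[2], radii[2] + 1):
                if score((dx, dy, dz)) > score(best):
                    best = (dx, dy, dz)

    # quadratic sub-voxel refinement, one axis at a time
    refined = []
    for ax in range(3):
        lo = list(best); lo[ax] -= 1
        hi = list(best); hi[ax] += 1
        y0, y1, y2 = score(tuple(lo)), score(best), score(tuple(hi))
        denom = y0 - 2 * y1 + y2
        if np.isfinite(y0) and np.isfinite(y2) and denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        refined.append((best[ax] + delta) * fixed.spacing[ax])
    return RigidShift(tuple(refined))


def transfer_mask(
    mask: SegmentationMask,
    shift: RigidShift,
    target: VolumeImage | SegmentationMask,
) -> SegmentationMask:
    """Resample a (shifted) mask onto the target grid by nearest neighbour.

    The shift maps the mask's dataset onto the target's; a target voxel
    at physical position ``p`` looks up the mask at ``p - shift``. The
    posterior cut index is carried over, rescaled to the target's
    coronal spacing.
    """
    src = mask.data.astype(np.float32)
    tgt_shape = target.data.shape if hasattr(target, "data") else target.shape
    tgt_spacing = target.spacing
    coords = np.meshgrid(
        *[
            (np.arange(n) * ts - s) / ms
            for n, ts, s, ms in zip(tgt_shape, tgt_spacing, shift.shift_mm, mask.spacing)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(src, np.stack(coords), order=0, mode="constant", cval=0.0)
    out = out > 0.5
    if not out.any():
        raise ValueError("mask transfer produced an empty mask")
    cut = mask.posterior_cut_index
    if cut is not None:
        cut = int(round((cut * mask.spacing[1] - shift.shift_mm[1]) / tgt_spacing[1]))
    return SegmentationMask(
        out, tgt_spacing, laterality=mask.laterality, posterior_cut_index=cut,
        threshold=mask.threshold, erosion_iters=mask.erosion_iters,
    )
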