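"""Signal-intensity calibration and %FGT quantification.

The water fraction of a voxel is computed from the water- and fat-only
images after calibrating the water image with a correction factor
``c = F_max / W_max``, the ratio of the maximum fat and water signal
intensities inside a standardized 30x30 mm^2 region of interest at the
centre of the breast:

    WF(i,j,k) = c * W(i,j,k) / (c * W(i,j,k) + F(i,j,k))

Summing WF over the segmentation mask times the voxel volume gives the
fibroglandular tissue (FGT) volume; expressed relative to the mask
volume it gives %FGT. The calibration normalizes pure-tissue voxels to
WF of 0 (fat) or 1 (water) so that mixed voxels contribute their
partial volume, which is what lets low-resolution acquisitions recover
the same %FGT as high-resolution ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image import VolumeImage
from .recon import DixonPair
from .segment import SegmentationMask

__all__ = [
    "ROIRecord",
    "CorrectionFactor",
    "WFVolume",
    "FGTResult",
    "select_calibration_roi",
    "correction_factor",
    "water_fraction_map",
    "fgt_summary",
    "sensitivity",
]

log = logging.getLogger(__name__)


@dataclass
class ROIRecord:
    """Calibration ROI and the signal maxima measured inside it."""

    slice_index: int
    center_xy: tuple[int, int]
    extent_mm: tuple[float, float]
    size_vox: tuple[int, int]
    F_max: float
    W_max: float

    def __post_init__(self) -> None:
        if self.F_max <= 0 or self.W_max <= 0:
            raise ValueError("ROI signal maxima must be positive")


@dataclass
class CorrectionFactor:
    """Water-image scaling ``c = F_max / W_max`` (dimensionless)."""

    c: float
    source: ROIRecord | None = None

    def __post_init__(self) -> None:
        if not (self.c > 0 and np.isfinite(self.c)):
            raise ValueError(f"correction factor must be positive, got {self.c}")


@dataclass
class WFVolume:
    """Per-voxel water fraction in [0, 1] on the acquisition grid."""

    wf: np.ndarray
    spacing: tuple[float, float, float]
    n_degenerate: int = 0  # voxels where cW + F == 0, assigned WF = 0

    def as_volume(self) -> VolumeImage:
        return VolumeImage(self.wf.astype(np.float32), self.spacing)


@dataclass
class FGTResult:
    """Per-breast fibroglandular tissue summary."""

    fgt_volume_cm3: float
    total_volume_cm3: float
    pct_fgt: float
    laterality: str = "both"
    dataset: str = ""
    correction_factor: float | None = None


def roi_size_vox(extent_mm, spacing) -> tuple[int, int]:
    """In-plane ROI size in voxels: nearest integer of ``extent/spacing``
    per axis (30 mm at 1.3 mm spacing gives 23 voxels)."""
    return tuple(max(1, int(round(e / s))) for e, s in zip(extent_mm, spacing[:2]))


def _roi_slices(center_xy, size, shape):
    out = []
    for c, n, dim in zip(center_xy, size, shape):
        start = max(0, min(c - n // 2, dim - n))
        out.append(slice(start, min(dim, start + n)))
    return tuple(out)


def select_calibration_roi(
    pair: DixonPair,
    mask: SegmentationMask,
    extent_mm: tuple[float, float] = (30.0, 30.0),
    min_class_fraction: float = 0.05,
) -> ROIRecord:
    """Place the calibration ROI and measure the signal maxima.

    The ROI is a square of ``extent_mm`` centred on the mask's in-plane
    centroid, in the axial slice nearest the mask centroid that contains
    both tissue classes (at least ``min_class_fraction`` of in-mask ROI
    voxels above and below an uncorrected water fraction of 0.5).
    ``F_max`` and ``W_max`` are the plain maxima of the fat and water
    images over the in-mask ROI voxels.
    """
    m = mask.data
    if not m.any():
        raise ValueError("empty segmentation mask")
    idx = np.argwhere(m)
    centroid = idx.mean(axis=0)
    cx, cy = int(round(centroid[0])), int(round(centroid[1]))
    z0 = int(round(centroid[2]))

    size = roi_size_vox(extent_mm, pair.water.spacing)
    W = pair.water.data
    F = pair.fat.data
    with np.errstate(invalid="ignore", divide="ignore"):
        wf_raw = np.where(W + F > 0, W / np.where(W + F > 0, W + F, 1.0), 0.0)

    nz = m.shape[2]
    order = sorted(range(nz), key=lambda z: (abs(z - z0), z))
    sx, sy = _roi_slices((cx, cy), size, m.shape[:2])
    for z in order:
        roi_mask = m[sx, sy, z]
        n = int(roi_mask.sum())
        if n == 0:
            continue
        wf_roi = wf_raw[sx, sy, z][roi_mask]
        frac_water = float((wf_roi > 0.5).mean())
        frac_fat = float((wf_roi <= 0.5).mean())
        if frac_water >= min_class_fraction and frac_fat >= min_class_fraction:
            f_max = float(F[sx, sy, z][roi_mask].max())
            w_max = float(W[sx, sy, z][roi_mask].max())
            return ROIRecord(
                slice_index=z, center_xy=(cx, cy), extent_mm=tuple(extent_mm),
                size_vox=size, F_max=f_max, W_max=w_max,
            )
    raise ValueError("no slice containing both fat and water")


def correction_factor(roi: ROIRecord) -> CorrectionFactor:
    """``c = F_max / W_max`` from the calibration ROI."""
    if roi.W_max == 0:
        raise ZeroDivisionError("W_max is zero; cannot form F_max/W_max")
    return CorrectionFactor(c=roi.F_max / roi.W_max, source=roi)


def water_fraction_map(
    pair: DixonPair,
    c: CorrectionFactor | float,
    mask: SegmentationMask | None = None,
) -> WFVolume:
    """Corrected water-fraction map ``WF = cW / (cW + F)``.

    Only the water image is scaled by ``c``; the fat image enters the
    denominator unmodified. Voxels where ``cW + F = 0`` get WF = 0 and
    are counted. Outside the mask (if given) WF is 0.
    """
    cval = c.c if isinstance(c, CorrectionFactor) else float(c)
    if cval <= 0:
        raise ValueError("correction factor must be positive")
    W = np.asarray(pair.water.data, dtype=np.float64)
    F = np.asarray(pair.fat.data, dtype=np.float64)
    denom = cval * W + F
    wf = np.where(denom > 0, (cval * W) / np.where(denom > 0, denom, 1.0), 0.0)
    if mask is not None:
        if mask.data.shape != wf.shape:
            raise ValueError("mask grid does not match the Dixon pair")
        n_degen = int(((denom == 0) & mask.data).sum())
        wf = np.where(mask.data, wf, 0.0)
    else:
        n_degen = int((denom == 0).sum())
    if n_degen:
        log.info("%d voxels with zero combined signal assigned WF=0", n_degen)
    return WFVolume(wf, pair.water.spacing, n_degenerate=n_degen)


def fgt_summary(
    wf: WFVolume,
    mask: SegmentationMask,
    dataset: str = "",
    c: float | None = None,
) -> FGTResult:
    """FGT volume, mask volume and %FGT of one breast.

    ``fgt_volume = sum(WF over mask) * voxel_volume``;
    ``%FGT = 100 * fgt_volume / mask_volume``.
    """
    if wf.wf.shape != mask.data.shape:
        raise ValueError("water-fraction map and mask grids differ")
    n = mask.voxel_count
    if n == 0:
        raise ValueError("empty segmentation mask")
    voxel_cm3 = float(np.prod(wf.spacing)) / 1000.0
    fgt = float(wf.wf[mask.data].sum()) * voxel_cm3
    total = n * voxel_cm3
    return FGTResult(
        fgt_volume_cm3=fgt,
        total_volume_cm3=total,
        pct_fgt=100.0 * fgt / total,
        laterality=mask.laterality,
        dataset=dataset,
        correction_factor=c,
    )


def sensitivity(
    pair: DixonPair,
    mask: SegmentationMask,
    c: CorrectionFactor | float,
    delta_fraction: float = 0.15,
) -> dict:
    """%FGT change when the correction factor is mis-estimated by
    ``±delta_fraction`` (the water-fraction map and summary are fully
    recomputed at ``c (1 ± delta)``)."""
    if delta_fraction < 0:
        raise ValueError("delta_fraction must be >= 0")
    cval = c.c if isinstance(c, CorrectionFactor) else float(c)
    base = fgt_summary(water_fraction_map(pair, cval, mask), mask, c=cval)
    plus = fgt_summary(water_fraction_map(pair, cval * (1 + delta_fraction), mask), mask)
    minus = fgt_summary(water_fraction_map(pair, cval * (1 - delta_fraction), mask), mask)
    return {
        "pct_fgt": base.pct_fgt,
        "pct_fgt_plus": plus.pct_fgt,
        "pct_fgt_minus": minus.pct_fgt,
        "delta_plus": plus.pct_fgt - base.pct_fgt,
        "delta_minus": minus.pct_fgt - base.pct_fgt,
        "c": cval,
        "delta_fraction": delta_fraction,
    }
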