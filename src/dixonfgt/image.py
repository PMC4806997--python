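"""3D image container and NIfTI input/output.

The axis convention throughout the package is (x, y, z) =
(left-right, anterior-posterior, superior-inferior): axis 0 indexes
sagittal planes, axis 1 indexes coronal planes (the pectoral cut is a
plane of constant ``y``), axis 2 indexes axial planes. Voxel centres are
aligned to ``index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "load_volume", "save_volume"]


@dataclass
class VolumeImage:
    """A 3D scalar (or complex) grid with voxel spacing in mm.

    Parameters
    ----------
    data
        3D array; real volumes are stored as float, simulated echoes may
        be complex.
    spacing
        Voxel edge lengths in mm along (x, y, z).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"VolumeImage requires a 3D array, got {self.data.ndim}D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of a single voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent covered by the grid (edge to edge) in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.data.copy(), self.spacing)

    def like(self, data: np.ndarray) -> "VolumeImage":
        """New volume on this grid holding ``data``."""
        return VolumeImage(np.asarray(data), self.spacing)


def load_volume(path: str | Path) -> VolumeImage:
    """Read a 3D NIfTI volume, preserving data and voxel spacing.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the image is not 3-dimensional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D from {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(np.asarray(data, dtype=np.float32), spacing)


def save_volume(vol: VolumeImage, path: str | Path, dtype=np.float32) -> Path:
    """Write a volume as NIfTI with a diagonal affine built from its spacing.

    Complex data cannot be stored in NIfTI-1; save magnitude explicitly
    before calling.
    """
    path = Path(path)
    data = np.asarray(vol.data)
    if np.iscomplexobj(data):
        raise ValueError("cannot save complex data; take magnitude or real part first")
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_zooms(vol.spacing)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path
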