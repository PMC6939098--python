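"""Volume container and NIfTI I/O.

A :class:`VolumeGrid` is a 3D scalar array together with its per-axis voxel
spacing in millimetres.  Axis order is fixed as (x, y, z) with z the slice
axis.  An optional boolean region-of-interest mask travels with the volume;
voxels outside it are excluded from all downstream statistics and component
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "load_nifti", "save_nifti"]


@dataclass
class VolumeGrid:
    """3D intensity volume with voxel spacing in mm.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities; must be finite.
    voxel_spacing_mm : tuple of float
        Per-axis voxel spacing, all strictly positive.
    roi : ndarray of bool, optional
        Region-of-interest mask on the same grid.
    """

    data: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    roi: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")
        spacing = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be 3 positive reals, got {spacing}")
        self.voxel_spacing_mm = spacing
        if self.roi is not None:
            self.roi = np.asarray(self.roi, dtype=bool)
            if self.roi.shape != self.data.shape:
                raise ValueError(
                    f"ROI shape {self.roi.shape} does not match data shape {self.data.shape}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """Copy of this grid geometry carrying new intensity data."""
        return VolumeGrid(data, self.voxel_spacing_mm, roi=self.roi)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_spacing_mm
        return aff


def save_nifti(vol: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.voxel_spacing_mm)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(np.asarray(img.dataobj, dtype=np.float64), spacing)
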