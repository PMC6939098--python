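"""Reslicing of anisotropic volumes and ROI application.

The reslicing rule is deliberately narrow: a 2 mm slice spacing is converted
to 1 mm isotropic by inserting, between each pair of adjacent slices, a new
slice equal to their arithmetic mean.  Original slices are preserved
bit-exactly at even output indices; output depth is ``2*Z - 1`` (the rule
defines voxels only *between* existing slices, so no final slice is
invented; ``pad_last_slice=True`` duplicates the last slice for an even
count).  Anything other than a 1x1x2 mm input grid is refused rather than
silently resampled.
"""

from __future__ import annotations

import numpy as np

from .grid import VolumeGrid

__all__ = ["reslice_isotropic", "reslice_mask", "apply_roi"]

_TOL = 1e-6


def reslice_isotropic(vol: VolumeGrid, pad_last_slice: bool = False) -> VolumeGrid:
    """Insert-average reslicing from (1, 1, 2) mm to 1 mm isotropic.

    Even output z-planes reproduce the input slices exactly; each odd plane
    is the mean of its two neighbours.

    Raises
    ------
    ValueError
        If in-plane spacing is not 1 mm, slice spacing is not 2 mm (the rule
        is specific to doubling), or there are fewer than 2 slices.
    """
    sx, sy, sz = vol.voxel_spacing_mm
    if abs(sx - 1.0) > _TOL or abs(sy - 1.0) > _TOL:
        raise ValueError(f"in-plane spacing must be 1 mm, got ({sx}, {sy})")
    if abs(sz - 2.0) > _TOL:
        raise ValueError(
            f"slice spacing must be 2 mm (insert-average rule is specific to "
            f"doubling), got {sz} mm"
        )
    nz = vol.shape[2]
    if nz < 2:
        raise ValueError("need at least 2 slices to reslice")

    nz_out = 2 * nz - 1 + (1 if pad_last_slice else 0)
    out = np.empty(vol.shape[:2] + (nz_out,), dtype=vol.data.dtype)
    out[:, :, 0 : 2 * nz - 1 : 2] = vol.data
    out[:, :, 1 : 2 * nz - 1 : 2] = 0.5 * (vol.data[:, :, :-1] + vol.data[:, :, 1:])
    if pad_last_slice:
        out[:, :, -1] = vol.data[:, :, -1]
    return VolumeGrid(out, (1.0, 1.0, 1.0))


def reslice_mask(mask: VolumeGrid, pad_last_slice: bool = False) -> VolumeGrid:
    """Reslice a binary mask by nearest-neighbour (odd planes copy the slice below).

    Averaging a mask would create non-binary values, so inserted planes take
    the nearest original slice; ties (exact midpoints) resolve downward.
    """
    sx, sy, sz = mask.voxel_spacing_mm
    if abs(sx - 1.0) > _TOL or abs(sy - 1.0) > _TOL or abs(sz - 2.0) > _TOL:
        raise ValueError("mask reslicing expects a (1, 1, 2) mm grid")
    nz = mask.shape[2]
    if nz < 2:
        raise ValueError("need at least 2 slices to reslice")
    binary = mask.data > 0.5
    nz_out = 2 * nz - 1 + (1 if pad_last_slice else 0)
    out = np.zeros(mask.shape[:2] + (nz_out,), dtype=np.float64)
    out[:, :, 0 : 2 * nz - 1 : 2] = binary
    out[:, :, 1 : 2 * nz - 1 : 2] = binary[:, :, :-1]
    if pad_last_slice:
        out[:, :, -1] = binary[:, :, -1]
    return VolumeGrid(out, (1.0, 1.0, 1.0))


def apply_roi(vol: VolumeGrid, roi: VolumeGrid) -> VolumeGrid:
    """Attach a binary ROI to a volume; outside voxels are excluded downstream.

    Intensities are kept intact (the vesselness filter needs real context for
    its derivatives); every downstream statistic and component is restricted
    to the ROI.
    """
    if roi.shape != vol.shape:
        raise ValueError(f"ROI shape {roi.shape} does not match volume shape {vol.shape}")
    return VolumeGrid(vol.data, vol.voxel_spacing_mm, roi=roi.data > 0.5)
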