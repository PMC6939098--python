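"""Thresholding, connected-component extraction and morphological filtering.

Candidates are 26-connected components of the thresholded vesselness field.
Hard acceptance rules are length (major ellipsoid axis) between 3 and 50 mm
inclusive and size at most 1000 voxels — the volume bound being the rounded
volume of a cylinder of radius 2.5 and length 50 voxels.  Width is only
softly constrained by the filter scales and is deliberately not re-applied
as a hard rule.  QC flags are advisory and never drop subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .metrics import ellipsoid_axes_from_coords
from .vesselness import VesselnessField

__all__ = [
    "PVSComponent",
    "threshold_field",
    "extract_components",
    "filter_components",
    "qc_flags",
    "cylinder_volume_bound",
    "MIN_LENGTH_MM",
    "MAX_LENGTH_MM",
    "MAX_SIZE_VOXELS",
]

MIN_LENGTH_MM = 3.0
MAX_LENGTH_MM = 50.0
MAX_SIZE_VOXELS = 1000

#: 26-connectivity structuring element (face/edge/corner adjacency)
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def cylinder_volume_bound(radius_voxels: float = 2.5, length_voxels: float = 50.0) -> int:
    """Volume of a cylinder, rounded to the nearest hundred voxels.

    With the default radius 2.5 and length 50 this reproduces the 1000-voxel
    maximum-size constraint.
    """
    return int(round(np.pi * radius_voxels ** 2 * length_voxels, -2))


@dataclass
class PVSComponent:
    """One connected component in the resliced 1 mm space."""

    id: int
    voxels: np.ndarray  # (N, 3) int voxel coordinates
    size_voxels: int
    size_mm3: float
    axis_lengths_mm: tuple[float, float, float]  # descending
    centroid: tuple[float, float, float]
    slice_span: int


def threshold_field(field: VesselnessField, t: float) -> np.ndarray:
    """Binary mask where vesselness >= t, restricted to the ROI."""
    if not (0.0 < t <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {t}")
    mask = field.data >= t
    if field.roi is not None:
        mask &= field.roi
    return mask


def extract_components(mask: np.ndarray, voxel_volume_mm3: float = 1.0) -> list[PVSComponent]:
    """Label the mask with 26-connectivity and measure each component."""
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    comps: list[PVSComponent] = []
    objects = ndimage.find_objects(labels)
    for idx, sl in enumerate(objects, start=1):
        local = np.argwhere(labels[sl] == idx)
        offset = np.array([s.start for s in sl])
        vox = local + offset
        axes = ellipsoid_axes_from_coords(vox)
        centroid = vox.mean(axis=0)
        comps.append(PVSComponent(
            id=idx - 1,
            voxels=vox,
            size_voxels=int(vox.shape[0]),
            size_mm3=float(vox.shape[0] * voxel_volume_mm3),
            axis_lengths_mm=axes,
            centroid=(float(centroid[0]), float(centroid[1]), float(centroid[2])),
            slice_span=int(vox[:, 2].max() - vox[:, 2].min() + 1),
        ))
    return comps


def filter_components(
    components: list[PVSComponent],
    min_length_mm: float = MIN_LENGTH_MM,
    max_length_mm: float = MAX_LENGTH_MM,
    max_size_voxels: int = MAX_SIZE_VOXELS,
) -> tuple[list[PVSComponent], list[dict]]:
    """Apply the hard morphological rules; bounds inclusive.

    Returns the accepted components and a rejection log recording every rule
    that fired for each discarded component.
    """
    accepted: list[PVSComponent] = []
    rejections: list[dict] = []
    for comp in components:
        reasons = []
        length = comp.axis_lengths_mm[0]
        if length < min_length_mm:
            reasons.append("min-length")
        if length > max_length_mm:
            reasons.append("max-length")
        if comp.size_voxels > max_size_voxels:
            reasons.append("max-volume")
        if reasons:
            rejections.append({
                "id": comp.id,
                "reasons": reasons,
                "length_mm": length,
                "size_voxels": comp.size_voxels,
            })
        else:
            accepted.append(comp)
    return accepted, rejections


def qc_flags(
    mask: np.ndarray,
    roi: np.ndarray,
    components: list[PVSComponent],
    noise_fraction_limit: float = 0.05,
    min_roi_voxels: int = 200,
    blob_axis_ratio: float = 1.5,
) -> dict:
    """Advisory QC report: noise, empty-ROI and blob-leak proxies.

    ``noise_suspect``: segmented fraction of the ROI exceeds the limit.
    ``empty_roi``: ROI smaller than the floor.  ``blob_suspect``: an accepted
    component with length/width below ``blob_axis_ratio`` (WMH-like).  Flags
    never auto-drop a subject.
    """
    roi = np.asarray(roi, dtype=bool)
    roi_n = int(roi.sum())
    seg_n = int((mask & roi).sum()) if roi_n else int(mask.sum())
    flags: list[str] = []
    if roi_n < min_roi_voxels:
        flags.append("empty_roi")
    frac = seg_n / roi_n if roi_n else 0.0
    if frac > noise_fraction_limit:
        flags.append("noise_suspect")
    for comp in components:
        length, width = comp.axis_lengths_mm[0], comp.axis_lengths_mm[1]
        if width > 0 and length / width < blob_axis_ratio:
            flags.append("blob_suspect")
            break
    return {
        "flags": flags,
        "roi_voxels": roi_n,
        "segmented_voxels": seg_n,
        "segmented_fraction": frac,
        "n_components": len(components),
    }
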