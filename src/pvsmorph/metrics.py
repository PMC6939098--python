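"""Per-component ellipsoid morphometry and per-subject aggregates.

Axis lengths follow the ellipsoid-of-equal-moments convention: from the
second central moment matrix of the voxel coordinates, with a per-axis
``voxel_size^2 / 12`` correction for the extent of each voxel, an axis is
``4 * sqrt(eigenvalue)``.  A single voxel therefore has three equal axes of
``4*sqrt(1/12) ~ 1.1547`` voxel sizes, and an N-voxel straight line has
major axis ``4*sqrt(N^2/12)``.  "Length" is the major axis, "width" the
second axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ellipsoid_axes_from_coords",
    "ellipsoid_axes",
    "SubjectSummary",
    "summarize_subject",
    "emulate_visual_rating",
    "rating_from_count",
]

#: rating bands on the max per-slice/hemisphere count: 0; 1-10; 11-20; 21-40; >40
_RATING_BANDS = (0, 10, 20, 40)

PERCENTILES = (5, 25, 75, 95)


def ellipsoid_axes_from_coords(
    coords: np.ndarray, voxel_size_mm: float = 1.0
) -> tuple[float, float, float]:
    """Descending ellipsoid axis lengths (mm) of a voxel coordinate cloud.

    ``coords`` is an (N, 3) array of voxel indices; coordinates are scaled by
    ``voxel_size_mm`` before the moment matrix is formed, and the diagonal
    correction scales accordingly, so doubling the grid doubles every axis.
    """
    coords = np.asarray(coords, dtype=np.float64) * voxel_size_mm
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError("coords must be a non-empty (N, 3) array")
    centered = coords - coords.mean(axis=0)
    cov = (centered.T @ centered) / coords.shape[0]
    cov += (voxel_size_mm ** 2 / 12.0) * np.eye(3)
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    axes = 4.0 * np.sqrt(np.maximum(eigvals, 0.0))
    return (float(axes[0]), float(axes[1]), float(axes[2]))


def ellipsoid_axes(comp) -> tuple[float, float, float]:
    """Axis lengths of a component (duck-typed: needs ``.voxels``)."""
    return ellipsoid_axes_from_coords(comp.voxels)


@dataclass
class SubjectSummary:
    """Per-subject aggregate PVS measures.

    ``feature_stats`` maps each of "length", "width", "size" to mean, median,
    sd and the 5/25/75/95 percentiles; it is ``None`` (undefined, not zero)
    when there are no components.
    """

    count: int
    total_volume_mm3: float
    feature_stats: dict | None
    max_slice_count: int
    max_slice_index: int
    emulated_rating: int
    qc_flags: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "pvs_count": self.count,
            "pvs_volume": self.total_volume_mm3,
            "max_slice_count": self.max_slice_count,
            "max_slice_index": self.max_slice_index,
            "pvs_visual_emulated": self.emulated_rating,
        }
        for feat in ("length", "width", "size"):
            stats = (self.feature_stats or {}).get(feat)
            for key in ("mean", "median", "sd", *(f"p{p}" for p in PERCENTILES)):
                row[f"pvs_{key}_{feat}" if key.startswith("p") else f"pvs_{feat}_{key}"] = (
                    stats[key] if stats else np.nan
                )
        row["qc_flags"] = ";".join(self.qc_flags)
        return row


def _feature_stats(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=np.float64)
    out = {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "sd": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
    }
    for p in PERCENTILES:
        out[f"p{p}"] = float(np.percentile(values, p))  # linear interpolation
    return out


def rating_from_count(max_slice_count: int) -> int:
    """Map a max per-slice PVS count to the ordinal 0-4 visual-rating band."""
    if max_slice_count < 0:
        raise ValueError("count must be non-negative")
    return int(np.searchsorted(_RATING_BANDS, max_slice_count))


def emulate_visual_rating(
    components, split_x: float | None = None
) -> tuple[int, int, int]:
    """Emulate the ordinal visual rating from the busiest axial slice.

    Counts, per axial slice and hemisphere (x below vs. at/above
    ``split_x``), the components with at least one voxel there; the maximum
    over slices and hemispheres is banded into the 0-4 rating.

    Returns ``(max_slice_count, max_slice_index, rating)``.
    """
    counts: dict[tuple[int, int], int] = {}
    for comp in components:
        vox = np.asarray(comp.voxels)
        sx = split_x if split_x is not None else -np.inf  # single hemisphere
        hemis = (vox[:, 0] >= sx).astype(int)
        for key in {(int(z), int(h)) for z, h in zip(vox[:, 2], hemis)}:
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        return 0, -1, 0
    (z_best, _), n_best = max(counts.items(), key=lambda kv: (kv[1], -kv[0][0]))
    return n_best, z_best, rating_from_count(n_best)


def summarize_subject(
    components, split_x: float | None = None, qc_flags: list[str] | None = None
) -> SubjectSummary:
    """Aggregate accepted components into a per-subject summary."""
    count = len(components)
    total = float(sum(c.size_mm3 for c in components))
    if count == 0:
        stats = None
    else:
        stats = {
            "length": _feature_stats([c.axis_lengths_mm[0] for c in components]),
            "width": _feature_stats([c.axis_lengths_mm[1] for c in components]),
            "size": _feature_stats([c.size_mm3 for c in components]),
        }
    msc, msi, rating = emulate_visual_rating(components, split_x=split_x)
    return SubjectSummary(
        count=count,
        total_volume_mm3=total,
        feature_stats=stats,
        max_slice_count=msc,
        max_slice_index=msi,
        emulated_rating=rating,
        qc_flags=list(qc_flags or []),
    )


def components_table(components) -> pd.DataFrame:
    """One row per component: id, size, centroid, axis lengths."""
    rows = []
    for c in components:
        rows.append({
            "id": c.id,
            "size_voxels": c.size_voxels,
            "size_mm3": c.size_mm3,
            "length_mm": c.axis_lengths_mm[0],
            "width_mm": c.axis_lengths_mm[1],
            "third_axis_mm": c.axis_lengths_mm[2],
            "centroid_x": c.centroid[0],
            "centroid_y": c.centroid[1],
            "centroid_z": c.centroid[2],
            "slice_span": c.slice_span,
        })
    return pd.DataFrame(rows)
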