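"""Synthetic phantoms and simulated cohorts with known ground truth.

Two generators live here:

* :func:`generate_volume` draws an MRI-like volume containing bright tubular
  structures (PVS surrogates) and bright spherical blobs (WMH-like
  confounders) on a noisy background, together with an exact truth catalog
  and an ROI mask, so that every downstream stage of the pipeline can be
  tested without real data.
* :func:`simulate_cohort` draws a per-subject table (risk factors, ordinal
  ratings, skewed WMH proportion, PVS morphometry proxies) with configurable
  true effect sizes, for parameter-recovery testing of the statistics layer.

Both are fully deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .grid import VolumeGrid

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSimSpec",
    "generate_volume",
    "simulate_cohort",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when requested structures cannot be placed in the grid."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic volume.

    Tubes have a Gaussian cross-section of the stated radius around a
    straight centerline, with peak intensity ``background_mean +
    pvs_contrast``; blobs have a Gaussian radial profile.  Tube orientation
    is biased towards the slice (z) axis within ``tilt_max_deg`` degrees.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    n_pvs: int = 5
    pvs_length_range_mm: tuple[float, float] = (5.0, 30.0)
    pvs_radius_range_voxels: tuple[float, float] = (0.5, 1.25)
    n_wmh_blobs: int = 0
    wmh_radius_range_mm: tuple[float, float] = (3.0, 6.0)
    background_mean: float = 100.0
    pvs_contrast: float = 80.0
    noise_sigma: float = 2.0
    noise_model: str = "gaussian"
    artefact: str = "none"
    tilt_max_deg: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.grid_shape)
        if len(shape) != 3 or any(s < 8 for s in shape):
            raise ValueError(f"grid_shape entries must all be >= 8, got {shape}")
        self.grid_shape = shape
        spacing = tuple(float(s) for s in self.voxel_spacing_mm)
        if any(s <= 0 for s in spacing):
            raise ValueError("voxel spacing must be positive")
        self.voxel_spacing_mm = spacing
        if self.n_pvs < 0 or self.n_wmh_blobs < 0:
            raise ValueError("structure counts must be non-negative")
        lo, hi = self.pvs_length_range_mm
        if not (0 < lo <= hi):
            raise ValueError("pvs_length_range_mm must be a positive interval")
        if hi >= max(s * v for s, v in zip(shape, spacing)):
            raise ValueError("pvs_length_range_mm exceeds the grid extent")
        if self.pvs_radius_range_voxels[0] <= 0 or self.wmh_radius_range_mm[0] <= 0:
            raise ValueError("radii must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.artefact not in ("none", "parallel_streaks"):
            raise ValueError(f"unknown artefact mode {self.artefact!r}")


@dataclass
class PhantomTruth:
    """Ground-truth catalog of the structures drawn into a phantom.

    Each record holds ``id``, ``class`` ("PVS"/"WMH"), a centerline as an
    ordered list of points in mm, ``radius_mm`` and ``length_mm`` (arc length
    of the centerline; 0 for blobs).
    """

    structures: list[dict] = field(default_factory=list)
    roi_mask_ref: str = "roi"

    @property
    def pvs(self) -> list[dict]:
        return [s for s in self.structures if s["class"] == "PVS"]

    @property
    def wmh(self) -> list[dict]:
        return [s for s in self.structures if s["class"] == "WMH"]

    def to_json(self, path: str | Path) -> None:
        recs = []
        for s in self.structures:
            r = dict(s)
            r["centerline"] = [list(map(float, p)) for p in s["centerline"]]
            recs.append(r)
        Path(path).write_text(
            json.dumps({"roi_mask_ref": self.roi_mask_ref, "structures": recs}, indent=2)
        )


def _roi_box(shape: tuple[int, int, int], spacing: tuple[float, float, float]) -> np.ndarray:
    """Central box ROI, inset ~10% (at least 2 voxels) per axis."""
    roi = np.zeros(shape, dtype=bool)
    sl = []
    for n in shape:
        m = max(2, int(round(0.1 * n)))
        sl.append(slice(m, n - m))
    roi[tuple(sl)] = True
    return roi


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3D segments (sampled; adequate for spacing checks)."""
    t = np.linspace(0.0, 1.0, 24)
    a = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    b = q0[None, :] + t[:, None] * (q1 - q0)[None, :]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return float(d.min())


def _sample_direction(rng: np.random.Generator, tilt_max_deg: float) -> np.ndarray:
    """Unit vector within tilt_max_deg of the z axis (uniform in cos over the cap)."""
    cmin = np.cos(np.deg2rad(tilt_max_deg))
    c = rng.uniform(cmin, 1.0)
    s = np.sqrt(1.0 - c * c)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([s * np.cos(phi), s * np.sin(phi), c])


def _add_tube(data: np.ndarray, spacing, p0: np.ndarray, p1: np.ndarray,
              radius_mm: float, amplitude: float) -> None:
    """Add a tube with Gaussian cross-section exp(-d^2 / 2 r^2) around segment p0-p1."""
    spacing = np.asarray(spacing)
    pad = 4.0 * radius_mm
    lo = np.maximum(np.floor((np.minimum(p0, p1) - pad) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p0, p1) + pad) / spacing).astype(int) + 1,
                    np.asarray(data.shape))
    ix = np.arange(lo[0], hi[0])
    iy = np.arange(lo[1], hi[1])
    iz = np.arange(lo[2], hi[2])
    X, Y, Z = np.meshgrid(ix * spacing[0], iy * spacing[1], iz * spacing[2], indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    d = p1 - p0
    L2 = float(d @ d)
    t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
    closest = p0[None, None, None, :] + t[..., None] * d[None, None, None, :]
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(
        -dist2 / (2.0 * radius_mm ** 2)
    )


def _add_blob(data: np.ndarray, spacing, center: np.ndarray,
              radius_mm: float, amplitude: float) -> None:
    spacing = np.asarray(spacing)
    pad = 4.0 * radius_mm
    lo = np.maximum(np.floor((center - pad) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center + pad) / spacing).astype(int) + 1, np.asarray(data.shape))
    ix = np.arange(lo[0], hi[0])
    iy = np.arange(lo[1], hi[1])
    iz = np.arange(lo[2], hi[2])
    X, Y, Z = np.meshgrid(ix * spacing[0], iy * spacing[1], iz * spacing[2], indexing="ij")
    dist2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(
        -dist2 / (2.0 * radius_mm ** 2)
    )


def generate_volume(spec: PhantomSpec) -> tuple[VolumeGrid, PhantomTruth, VolumeGrid]:
    """Draw a synthetic volume, its truth catalog, and an ROI mask.

    Returns
    -------
    (volume, truth, roi_mask)
        ``volume`` is the noisy intensity volume; ``truth`` catalogs every
        structure drawn; ``roi_mask`` is a binary VolumeGrid covering the
        placement region.

    Raises
    ------
    PlacementError
        If a structure cannot be placed after bounded retries (grid too
        small for the requested lengths/counts).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    spacing = np.asarray(spec.voxel_spacing_mm)
    data = np.full(shape, float(spec.background_mean))
    roi = _roi_box(shape, spec.voxel_spacing_mm)

    # placement bounds in mm: inside the ROI box with a margin of 3 sigma
    idx = np.argwhere(roi)
    roi_lo_mm = idx.min(axis=0) * spacing
    roi_hi_mm = idx.max(axis=0) * spacing

    truth = PhantomTruth()
    placed: list[tuple[np.ndarray, np.ndarray, float]] = []
    max_retries = 400

    for i in range(spec.n_pvs):
        radius_vox = rng.uniform(*spec.pvs_radius_range_voxels)
        radius_mm = radius_vox * min(spec.voxel_spacing_mm[0], spec.voxel_spacing_mm[1])
        length = rng.uniform(*spec.pvs_length_range_mm)
        margin = 3.0 * radius_mm
        if np.any(roi_lo_mm + margin >= roi_hi_mm - margin):
            raise PlacementError(
                f"grid too small for tube of radius {radius_mm:.2f} mm"
            )
        ok = False
        for _ in range(max_retries):
            direction = _sample_direction(rng, spec.tilt_max_deg)
            center = rng.uniform(roi_lo_mm + margin, roi_hi_mm - margin)
            p0 = center - 0.5 * length * direction
            p1 = center + 0.5 * length * direction
            if np.any(p0 < roi_lo_mm + margin) or np.any(p0 > roi_hi_mm - margin):
                continue
            if np.any(p1 < roi_lo_mm + margin) or np.any(p1 > roi_hi_mm - margin):
                continue
            # keep tubes separated so components never merge
            min_sep = 6.0 * radius_mm + 3.0
            if any(_segment_distance(p0, p1, q0, q1) < max(min_sep, 6.0 * r + 3.0)
                   for q0, q1, r in placed):
                continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place tube {i} (length {length:.1f} mm) after "
                f"{max_retries} retries; grid too small or too crowded"
            )
        _add_tube(data, spacing, p0, p1, radius_mm, spec.pvs_contrast)
        placed.append((p0, p1, radius_mm))
        truth.structures.append({
            "id": len(truth.structures),
            "class": "PVS",
            "centerline": [p0.tolist(), p1.tolist()],
            "radius_mm": float(radius_mm),
            "length_mm": float(np.linalg.norm(p1 - p0)),
        })

    for i in range(spec.n_wmh_blobs):
        radius_mm = rng.uniform(*spec.wmh_radius_range_mm)
        margin = 1.5 * radius_mm
        if np.any(roi_lo_mm + margin >= roi_hi_mm - margin):
            raise PlacementError(f"grid too small for blob of radius {radius_mm:.2f} mm")
        ok = False
        for _ in range(max_retries):
            center = rng.uniform(roi_lo_mm + margin, roi_hi_mm - margin)
            if any(_segment_distance(center, center, q0, q1) < 2.0 * (radius_mm + r) + 3.0
                   for q0, q1, r in placed):
                continue
            ok = True
            break
        if not ok:
            raise PlacementError(f"could not place blob {i} after {max_retries} retries")
        _add_blob(data, spacing, center, radius_mm, spec.pvs_contrast)
        placed.append((center, center, radius_mm))
        truth.structures.append({
            "id": len(truth.structures),
            "class": "WMH",
            "centerline": [center.tolist()],
            "radius_mm": float(radius_mm),
            "length_mm": 0.0,
        })

    if spec.artefact == "parallel_streaks":
        # thin bright lines along the phase (y) axis, mimicking motion
        # artefacts; dense enough to dominate the segmented fraction
        nx, nz = shape[0] - 4, shape[2] - 4
        n_streaks = max(12, nx * nz // 8)
        cells = rng.choice(nx * nz, size=n_streaks, replace=False)
        for cell in cells:
            x, z = 2 + cell // nz, 2 + cell % nz
            data[x, :, z] += 0.9 * spec.pvs_contrast

    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            data = data + rng.normal(0.0, spec.noise_sigma, size=shape)
        else:  # rician: magnitude of signal + complex gaussian
            n_re = rng.normal(0.0, spec.noise_sigma, size=shape)
            n_im = rng.normal(0.0, spec.noise_sigma, size=shape)
            data = np.sqrt((data + n_re) ** 2 + n_im ** 2)

    vol = VolumeGrid(data, spec.voxel_spacing_mm)
    roi_vol = VolumeGrid(roi.astype(np.float64), spec.voxel_spacing_mm)
    return vol, truth, roi_vol


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: affine map latent proxy -> observed scale: (mean, sd, latent loading)
_METRIC_PARAMS = {
    "pvs_count": (258.0, 94.8, 0.70),
    "pvs_volume": (3274.8, 1464.4, 0.90),
    "pvs_mean_length": (3.94, 0.54, 0.85),
    "pvs_mean_width": (2.01, 0.36, 0.85),
    "pvs_mean_size": (13.76, 4.85, 0.95),
}

_DEFAULT_PREVALENCES = {
    "hypertension": 0.4765,
    "diabetes": 0.0957,
    "cholesterol": 0.3921,
    "cvd": 0.2833,
    "stroke": 0.1764,
}


@dataclass
class CohortSimSpec:
    """Parameters of a simulated cohort table.

    Each subject carries a standard-normal latent PVS-burden score.  The PVS
    morphometry columns are noisy affine proxies of that latent; binary
    outcomes follow logistic models with per-SD log-odds ``effect_log_odds``;
    WMH %ICV is Beta-distributed with logit-linear mean in the latent and
    precision ``beta_precision``; the ordinal rating is the latent cut at
    ``rating_cutpoints``.
    """

    n_subjects: int = 533
    prevalences: dict = field(default_factory=lambda: dict(_DEFAULT_PREVALENCES))
    effect_log_odds: dict = field(default_factory=dict)
    beta_reg_coefs: tuple[float, float] = (-4.6, 0.0)
    beta_precision: float = 50.0
    rating_cutpoints: tuple[float, float, float, float] = (-1.8, -0.25, 1.0, 2.2)
    age_mean: float = 72.5
    age_sd: float = 0.7
    sex_prop_male: float = 0.533
    rating_misclass_prob: float = 0.0
    metric_loadings: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for k, p in self.prevalences.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"prevalence for {k!r} must be in (0,1), got {p}")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be > 0")
        cps = tuple(float(c) for c in self.rating_cutpoints)
        if len(cps) != 4 or any(a >= b for a, b in zip(cps, cps[1:])):
            raise ValueError("rating_cutpoints must be 4 strictly ascending reals")
        self.rating_cutpoints = cps
        if not (0.0 < self.sex_prop_male < 1.0):
            raise ValueError("sex_prop_male must be in (0,1)")


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a per-subject cohort table with known effect structure.

    Returns a DataFrame with columns: age, sex (1=male), one 0/1 column per
    outcome in ``spec.prevalences``, fazekas_total (0-6), wmh_pct_icv,
    pvs_visual (0-4), and the five PVS morphometry columns.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    latent = rng.normal(0.0, 1.0, size=n)

    df = pd.DataFrame({"latent_burden": latent})
    df["age"] = rng.normal(spec.age_mean, spec.age_sd, size=n)
    df["sex"] = (rng.uniform(size=n) < spec.sex_prop_male).astype(int)

    for name, prev in spec.prevalences.items():
        eff = float(spec.effect_log_odds.get(name, 0.0))
        p = expit(logit(prev) + eff * latent)
        df[name] = (rng.uniform(size=n) < p).astype(int)

    b0, b1 = spec.beta_reg_coefs
    mu = expit(b0 + b1 * latent)
    phi = spec.beta_precision
    df["wmh_pct_icv"] = rng.beta(mu * phi, (1.0 - mu) * phi)

    # Fazekas total 0-6: latent WMH severity cut into 7 bands
    wmh_latent = 0.6 * latent + 0.8 * rng.normal(size=n)
    faz_cuts = np.quantile(rng.normal(size=10_000), [0.05, 0.2, 0.45, 0.7, 0.88, 0.97])
    df["fazekas_total"] = np.searchsorted(faz_cuts, wmh_latent).astype(int)

    rating = np.searchsorted(np.asarray(spec.rating_cutpoints), latent).astype(int)
    if spec.rating_misclass_prob > 0:
        flip = rng.uniform(size=n) < spec.rating_misclass_prob
        shift = rng.choice([-1, 1], size=n)
        rating = np.where(flip, np.clip(rating + shift, 0, 4), rating)
    df["pvs_visual"] = rating

    loadings = dict(spec.metric_loadings)
    for name, (mean, sd, rho) in _METRIC_PARAMS.items():
        rho = float(loadings.get(name, rho))
        proxy = rho * latent + np.sqrt(max(1.0 - rho * rho, 0.0)) * rng.normal(size=n)
        vals = mean + sd * proxy
        if name == "pvs_count":
            vals = np.maximum(np.round(vals), 1.0)
        else:
            vals = np.maximum(vals, 0.01 * mean)
        df[name] = vals

    return df
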