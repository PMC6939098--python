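"""Run configuration: YAML schema, validation, defaults.

Every default is traceable either to a printed constraint (length bounds
3-50 mm, 1000-voxel size cap) or to a documented design decision (filter
scales, threshold, QC limits).  Unknown keys are rejected so typos never
silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .phantom import CohortSimSpec, PhantomSpec
from .vesselness import FrangiParams

__all__ = ["RunConfig", "validate_config", "load_config", "default_config"]

_STAGES = ("phantom", "preprocess", "vesselness", "segmentation", "metrics", "stats")
#: stage -> stage it requires
_STAGE_DEPS = {
    "preprocess": "phantom",
    "vesselness": "preprocess",
    "segmentation": "vesselness",
    "metrics": "segmentation",
}


@dataclass
class FilterBounds:
    min_length_mm: float = 3.0
    max_length_mm: float = 50.0
    max_size_voxels: int = 1000


@dataclass
class QCThresholds:
    noise_fraction_limit: float = 0.05
    min_roi_voxels: int = 200
    blob_axis_ratio: float = 1.5


@dataclass
class RunConfig:
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    n_subjects: int = 3
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    frangi: FrangiParams = field(default_factory=FrangiParams)
    filters: FilterBounds = field(default_factory=FilterBounds)
    qc: QCThresholds = field(default_factory=QCThresholds)
    cohort_sim: CohortSimSpec | None = None
    pad_last_slice: bool = False
    seed: int = 0
    out_dir: str = "pvsmorph_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.cohort_sim is None:
            d.pop("cohort_sim")
        return d


def default_config() -> RunConfig:
    return RunConfig()


def validate_config(raw: dict) -> tuple[RunConfig | None, list[str]]:
    """Build a RunConfig from a raw mapping; returns (config, errors).

    On any error the config is None and ``errors`` lists every problem found
    (unknown keys, invalid bounds, unsatisfied stage dependencies).
    """
    errors: list[str] = []
    raw = dict(raw or {})

    known = set(RunConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key!r}")

    def build(cls, name):
        data = raw.get(name)
        if data is None:
            return cls()
        if not isinstance(data, dict):
            errors.append(f"section {name!r} must be a mapping")
            return cls()
        bad = set(data) - set(cls.__dataclass_fields__)
        if bad:
            errors.append(f"unknown keys in {name!r}: {sorted(bad)}")
            return cls()
        try:
            return cls(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in data.items()})
        except (ValueError, TypeError) as err:
            errors.append(f"invalid {name!r}: {err}")
            return cls()

    phantom = build(PhantomSpec, "phantom")
    frangi = build(FrangiParams, "frangi")
    filters = build(FilterBounds, "filters")
    qc = build(QCThresholds, "qc")
    cohort_sim = build(CohortSimSpec, "cohort_sim") if "cohort_sim" in raw else None

    if filters.min_length_mm <= 0 or filters.max_length_mm <= 0:
        errors.append("length bounds must be positive")
    if filters.min_length_mm > filters.max_length_mm:
        errors.append("min_length_mm must not exceed max_length_mm")
    if filters.max_size_voxels < 1:
        errors.append("max_size_voxels must be >= 1")
    if qc.noise_fraction_limit <= 0 or qc.blob_axis_ratio <= 0:
        errors.append("QC thresholds must be positive")

    stages = {s: True for s in _STAGES}
    if "stages" in raw:
        if not isinstance(raw["stages"], dict):
            errors.append("stages must be a mapping of stage -> bool")
        else:
            bad = set(raw["stages"]) - set(_STAGES)
            if bad:
                errors.append(f"unknown stages: {sorted(bad)}")
            stages.update({k: bool(v) for k, v in raw["stages"].items() if k in _STAGES})
    for stage, dep in _STAGE_DEPS.items():
        if stages.get(stage) and not stages.get(dep):
            errors.append(f"stage {stage!r} requires stage {dep!r} to be enabled")

    if errors:
        return None, errors

    cfg = RunConfig(
        stages=stages,
        n_subjects=int(raw.get("n_subjects", 3)),
        phantom=phantom,
        frangi=frangi,
        filters=filters,
        qc=qc,
        cohort_sim=cohort_sim,
        pad_last_slice=bool(raw.get("pad_last_slice", False)),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "pvsmorph_out")),
        log_level=str(raw.get("log_level", "INFO")),
    )
    if cfg.n_subjects < 1:
        return None, ["n_subjects must be >= 1"]
    return cfg, []


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg, errors = validate_config(raw)
    if cfg is None:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg
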