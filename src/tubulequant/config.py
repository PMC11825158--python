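"""Quantification configuration: thresholds, QC minima, pooling and alpha."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .model import ConfigError, TISSUE_TYPES

#: Minimum total tubular area (mm^2) below which the density estimate is
#: flagged as unreliable, by tissue type.
DEFAULT_MIN_TOTAL_AREA = {"fetal": 0.015, "prepubertal": 0.003}

POOLING_MODES = ("per_section_mean", "pooled_counts")


@dataclass
class QuantConfig:
    """Tunable parameters of the quantification pipeline.

    roundness_threshold
        Longest/shortest diameter ratio strictly below which a tubule
        cross-section counts as round (cut near-perpendicular to its axis).
    edge_tolerance_mm
        A tubule whose outline comes within this distance of the ROI
        boundary (or leaves the ROI) is treated as edge-clipped, i.e. its
        basement membrane is taken to be incomplete, unless the annotator
        supplied an explicit intact flag.
    min_round_tubules
        QC floor on the number of round cross-sections per sample.
    min_total_area_mm2
        QC floor on total tubular area; ``None`` selects the tissue-type
        default (0.015 fetal, 0.003 prepubertal).
    pooling_mode
        How sections are aggregated to sample level: unweighted mean of
        per-section metric values, or pooling of raw counts/areas before
        re-applying the formulas.
    alpha
        Significance level for all tests.
    """

    roundness_threshold: float = 1.5
    edge_tolerance_mm: float = 0.002
    min_round_tubules: int = 25
    min_total_area_mm2: float | None = None
    pooling_mode: str = "per_section_mean"
    alpha: float = 0.05
    scale_mm_per_unit: float = 1.0
    classification_property: str = "classification.name"

    def __post_init__(self) -> None:
        if self.roundness_threshold <= 1:
            raise ConfigError("roundness_threshold must be > 1")
        if self.edge_tolerance_mm < 0:
            raise ConfigError("edge_tolerance_mm must be >= 0")
        if self.min_round_tubules < 0:
            raise ConfigError("min_round_tubules must be >= 0")
        if self.min_total_area_mm2 is not None and self.min_total_area_mm2 <= 0:
            raise ConfigError("min_total_area_mm2 must be positive when given")
        if self.pooling_mode not in POOLING_MODES:
            raise ConfigError(f"pooling_mode must be one of {POOLING_MODES}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.scale_mm_per_unit <= 0:
            raise ConfigError("scale_mm_per_unit must be positive")

    def resolve_min_total_area(self, tissue_type: str) -> float:
        if self.min_total_area_mm2 is not None:
            return self.min_total_area_mm2
        if tissue_type not in TISSUE_TYPES:
            raise ConfigError(f"unknown tissue_type {tissue_type!r}")
        return DEFAULT_MIN_TOTAL_AREA[tissue_type]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None, **overrides) -> QuantConfig:
    """Load a QuantConfig from a YAML or JSON file, with keyword overrides.

    Override values of ``None`` are ignored so CLI flags can be passed
    through unconditionally.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        try:
            text = path.read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        try:
            if path.suffix.lower() == ".json":
                data = json.loads(text)
            else:
                data = yaml.safe_load(text) or {}
        except (json.JSONDecodeError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(QuantConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    return QuantConfig(**data)
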