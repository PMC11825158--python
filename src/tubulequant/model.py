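"""Core data model for annotated testis sections.

A *section* is one stained tissue slice exported from an annotation tool:
a testicular region of interest (ROI), seminiferous-tubule outlines as
polygons, and germ-cell marks as points.  Two germ-cell markers are
distinguished: AP2G (AP2γ-positive gonocytes, nuclear stain) and MAGEA4
(MAGE-A4-positive (pre)spermatogonia, cytoplasmic stain).

All coordinates are continuous Cartesian millimetres with y increasing
downward, matching image-export conventions; there is no pixel grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

MARKERS = ("AP2G", "MAGEA4")

TISSUE_TYPES = ("fetal", "prepubertal")


class TubuleQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(TubuleQuantError):
    """Invalid configuration or usage (CLI exit code 2)."""


class DataValidationError(TubuleQuantError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class GeometryError(DataValidationError):
    """Degenerate or invalid polygon geometry."""


class AnalysisError(TubuleQuantError):
    """A statistical analysis cannot be performed (CLI exit code 4)."""


class SimulationError(TubuleQuantError):
    """Synthetic-data generation failed (e.g. infeasible packing)."""


def validate_polygon(vertices, *, context: str = "polygon") -> Polygon:
    """Build a validated shapely Polygon from an (n, 2) vertex sequence.

    Requires >= 3 vertices, simplicity (no self-intersection) and nonzero
    area.  Closure is implicit (last vertex joins back to the first).
    """
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise GeometryError(f"{context}: need >=3 (x, y) vertices, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise GeometryError(f"{context}: non-finite vertex coordinates")
    poly = Polygon(arr)
    if not poly.is_valid:
        raise GeometryError(f"{context}: not a simple polygon ({shapely.is_valid_reason(poly)})")
    if poly.area <= 0.0:
        raise GeometryError(f"{context}: degenerate polygon with zero area")
    return poly


@dataclass(frozen=True)
class GermCellMark:
    """One annotator click on a positively stained germ cell."""

    cell_id: str
    x: float
    y: float
    marker: str  # "AP2G" or "MAGEA4"

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise DataValidationError(
                f"cell {self.cell_id!r}: unknown marker {self.marker!r}; expected one of {MARKERS}"
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise DataValidationError(f"cell {self.cell_id!r}: non-finite position")


@dataclass
class TubuleAnnotation:
    """One manually outlined seminiferous-tubule cross-section.

    ``intact_flag`` is an optional annotator judgement that the basement
    membrane is complete; when present it overrides the automatic
    edge-proximity test.
    """

    tubule_id: str
    outline: Polygon
    intact_flag: bool | None = None


@dataclass
class SectionAnnotation:
    """All annotations for one tissue section, in millimetres."""

    section_id: str
    sample_id: str
    roi: Polygon
    tubules: list[TubuleAnnotation] = field(default_factory=list)
    cells: list[GermCellMark] = field(default_factory=list)
    scale_mm_per_unit: float = 1.0

    def __post_init__(self) -> None:
        if self.scale_mm_per_unit <= 0:
            raise ConfigError(f"section {self.section_id!r}: scale must be positive")
        seen_t = set()
        for t in self.tubules:
            if t.tubule_id in seen_t:
                raise DataValidationError(
                    f"section {self.section_id!r}: duplicate tubule_id {t.tubule_id!r}"
                )
            seen_t.add(t.tubule_id)
        seen_c = set()
        for c in self.cells:
            if c.cell_id in seen_c:
                raise DataValidationError(
                    f"section {self.section_id!r}: duplicate cell_id {c.cell_id!r}"
                )
            seen_c.add(c.cell_id)


@dataclass
class StudyDesign:
    """Maps samples to subjects, experimental conditions and tissue type."""

    rows: "object"  # pandas.DataFrame with the four design columns

    REQUIRED = ("sample_id", "subject_id", "condition", "tissue_type")

    def __post_init__(self) -> None:
        import pandas as pd

        df = pd.DataFrame(self.rows)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise DataValidationError(f"study design missing columns: {missing}")
        df = df[list(self.REQUIRED)].astype(str)
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise DataValidationError(f"duplicate sample_id in design: {sorted(set(dup))}")
        bad = sorted(set(df["tissue_type"]) - set(TISSUE_TYPES))
        if bad:
            raise DataValidationError(
                f"tissue_type must be one of {TISSUE_TYPES}, got {bad}"
            )
        self.rows = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rows["sample_id"])

    def lookup(self, sample_id: str) -> dict:
        hit = self.rows[self.rows["sample_id"] == sample_id]
        if hit.empty:
            raise DataValidationError(f"sample_id {sample_id!r} not present in study design")
        return hit.iloc[0].to_dict()
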