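"""The four germ-cell quantification metrics and sample-level aggregation.

Method 1 — tubular germ cell density: germ cells per mm^2 of total
tubular area, every intact tubule included regardless of shape.
Method 2 — S/T: mean spermatogonia per round tubular cross-section.
Method 3 — fertility index (FI): percentage of round tubules containing
at least one germ cell.
Method 4 — round tubular germ cell density: germ cells in round tubules
per mm^2 of round tubular area.

Only intact tubules (complete basement membrane) enter any count or
area.  A metric whose denominator is zero is *missing* (``None``), never
an exception.  QC flags mark sections/samples falling below the
round-tubule count or total-area reliability floors; flags never exclude
data — exclusion is a reporting-time choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import QuantConfig
from .geometry import TubuleFeatures
from .model import MARKERS, DataValidationError, StudyDesign

log = logging.getLogger(__name__)

#: Names of the per-section/per-sample metric fields, in output order.
METHOD_FIELDS = ("method1", "method2", "method3", "method4")

QC_FEW_ROUND = "few_round_tubules"
QC_SMALL_AREA = "small_total_area"


@dataclass
class SectionMetrics:
    """Counts, areas and the four metric values for one section."""

    section_id: str
    sample_id: str
    n_tubules_analysed: int
    n_round: int
    total_tubular_area_mm2: float
    round_tubular_area_mm2: float
    n_cells_total: int
    n_cells_in_round: int
    n_round_with_cells: int
    method1: float | None
    method2: float | None
    method3: float | None
    method4: float | None
    cells_by_marker: dict[str, int] = field(default_factory=dict)
    qc_flags: set[str] = field(default_factory=set)


@dataclass
class SampleMetrics:
    """Per-sample aggregate of section metrics (one sample = one tissue
    fragment set from one subject under one condition)."""

    sample_id: str
    subject_id: str
    condition: str
    tissue_type: str
    n_sections: int
    n_round_total: int
    total_tubular_area_mm2: float
    method1: float | None
    method2: float | None
    method3: float | None
    method4: float | None
    qc_flags: set[str] = field(default_factory=set)


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_section_metrics(
    features: list[TubuleFeatures],
    config: QuantConfig | None = None,
    *,
    section_id: str = "",
    sample_id: str = "",
    tissue_type: str = "fetal",
) -> SectionMetrics:
    """Apply the four quantification formulas to one section's tubules."""
    config = config or QuantConfig()
    intact = [f for f in features if f.is_intact]
    rounds = [f for f in intact if f.is_round]
    total_area = sum(f.area_mm2 for f in intact)
    round_area = sum(f.area_mm2 for f in rounds)
    n_cells_total = sum(f.cell_count_total for f in intact)
    n_cells_in_round = sum(f.cell_count_total for f in rounds)
    n_round_with_cells = sum(1 for f in rounds if f.cell_count_total > 0)
    by_marker = {m: sum(f.cell_count_by_marker.get(m, 0) for f in intact) for m in MARKERS}

    m2 = _ratio(n_cells_in_round, len(rounds))
    m3 = None if not rounds else 100.0 * n_round_with_cells / len(rounds)
    qc: set[str] = set()
    if len(rounds) < config.min_round_tubules:
        qc.add(QC_FEW_ROUND)
    if total_area < config.resolve_min_total_area(tissue_type):
        qc.add(QC_SMALL_AREA)
    return SectionMetrics(
        section_id=section_id,
        sample_id=sample_id,
        n_tubules_analysed=len(intact),
        n_round=len(rounds),
        total_tubular_area_mm2=total_area,
        round_tubular_area_mm2=round_area,
        n_cells_total=n_cells_total,
        n_cells_in_round=n_cells_in_round,
        n_round_with_cells=n_round_with_cells,
        method1=_ratio(n_cells_total, total_area),
        method2=m2,
        method3=m3,
        method4=_ratio(n_cells_in_round, round_area),
        cells_by_marker=by_marker,
        qc_flags=qc,
    )


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return sum(defined) / len(defined) if defined else None


def aggregate_by_sample(
    sections: list[SectionMetrics],
    design: StudyDesign,
    config: QuantConfig | None = None,
) -> list[SampleMetrics]:
    """Aggregate section metrics to one record per sample.

    ``per_section_mean`` takes the unweighted mean of each metric over
    the sections where it is defined (mirroring per-fragment means in
    reported group plots); ``pooled_counts`` sums counts and areas across
    sections and re-applies the formulas.
    """
    config = config or QuantConfig()
    by_sample: dict[str, list[SectionMetrics]] = {}
    for s in sections:
        by_sample.setdefault(s.sample_id, []).append(s)
    out: list[SampleMetrics] = []
    for sample_id in sorted(by_sample):
        secs = by_sample[sample_id]
        meta = design.lookup(sample_id)  # raises if unknown
        n_round_total = sum(s.n_round for s in secs)
        total_area = sum(s.total_tubular_area_mm2 for s in secs)
        if config.pooling_mode == "per_section_mean":
            vals = {m: _mean_defined([getattr(s, m) for s in secs]) for m in METHOD_FIELDS}
        else:  # pooled_counts
            cells = sum(s.n_cells_total for s in secs)
            cells_round = sum(s.n_cells_in_round for s in secs)
            round_area = sum(s.round_tubular_area_mm2 for s in secs)
            round_with = sum(s.n_round_with_cells for s in secs)
            vals = {
                "method1": _ratio(cells, total_area),
                "method2": _ratio(cells_round, n_round_total),
                "method3": None if n_round_total == 0 else 100.0 * round_with / n_round_total,
                "method4": _ratio(cells_round, round_area),
            }
        qc: set[str] = set()
        if n_round_total < config.min_round_tubules:
            qc.add(QC_FEW_ROUND)
        if total_area < config.resolve_min_total_area(meta["tissue_type"]):
            qc.add(QC_SMALL_AREA)
        out.append(
            SampleMetrics(
                sample_id=sample_id,
                subject_id=meta["subject_id"],
                condition=meta["condition"],
                tissue_type=meta["tissue_type"],
                n_sections=len(secs),
                n_round_total=n_round_total,
                total_tubular_area_mm2=total_area,
                qc_flags=qc,
                **vals,
            )
        )
    return out
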