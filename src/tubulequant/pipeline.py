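"""End-to-end orchestration: annotations -> features -> metrics -> samples."""

from __future__ import annotations

import logging

from .config import QuantConfig
from .geometry import compute_tubule_features
from .metrics import (
    SampleMetrics,
    SectionMetrics,
    aggregate_by_sample,
    compute_section_metrics,
)
from .model import SectionAnnotation, StudyDesign

log = logging.getLogger(__name__)


def quantify_sections(
    sections: list[SectionAnnotation],
    design: StudyDesign,
    config: QuantConfig | None = None,
) -> tuple[list[SectionMetrics], list[SampleMetrics]]:
    """Run geometry and metrics over every section and aggregate by sample."""
    config = config or QuantConfig()
    section_metrics: list[SectionMetrics] = []
    for sec in sections:
        tissue = design.lookup(sec.sample_id)["tissue_type"]
        features = compute_tubule_features(sec, config)
        sm = compute_section_metrics(
            features,
            config,
            section_id=sec.section_id,
            sample_id=sec.sample_id,
            tissue_type=tissue,
        )
        log.info(
            "section %s: tubules=%d intact=%d round=%d cells=%d qc=%s",
            sec.section_id,
            len(sec.tubules),
            sm.n_tubules_analysed,
            sm.n_round,
            sm.n_cells_total,
            ",".join(sorted(sm.qc_flags)) or "-",
        )
        section_metrics.append(sm)
    sample_metrics = aggregate_by_sample(section_metrics, design, config)
    return section_metrics, sample_metrics
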