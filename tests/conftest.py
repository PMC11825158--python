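import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from tubulequant import (
    GermCellMark,
    QuantConfig,
    SectionAnnotation,
    StudyDesign,
    TubuleAnnotation,
)


@pytest.fixture
def unit_square_section() -> SectionAnnotation:
    """One unit-square tubule well inside a large ROI, two MAGEA4 cells
    inside and one interstitial cell outside."""
    return SectionAnnotation(
        section_id="sec1",
        sample_id="sample1",
        roi=box(-5, -5, 5, 5),
        tubules=[TubuleAnnotation("A", box(0, 0, 1, 1))],
        cells=[
            GermCellMark("c1", 0.25, 0.25, "MAGEA4"),
            GermCellMark("c2", 0.75, 0.75, "MAGEA4"),
            GermCellMark("c3", 3.0, 3.0, "AP2G"),
        ],
    )


@pytest.fixture
def default_config() -> QuantConfig:
    return QuantConfig()


@pytest.fixture
def small_design() -> StudyDesign:
    return StudyDesign(
        pd.DataFrame(
            {
                "sample_id": ["sample1", "sample2"],
                "subject_id": ["subjA", "subjB"],
                "condition": ["control", "treated"],
                "tissue_type": ["fetal", "fetal"],
            }
        )
    )


@pytest.fixture(scope="session")
def fetal_study():
    """One simulated fetal chemotherapy study, reused across tests."""
    from tubulequant import simulate_preset

    return simulate_preset("fetal_chemo", seed=7)


@pytest.fixture(scope="session")
def fetal_quantified(fetal_study):
    from tubulequant import quantify_sections

    return quantify_sections(fetal_study.sections, fetal_study.design)
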