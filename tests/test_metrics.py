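"""The four quantification formulas, degenerate denominators, QC flags
and sample aggregation."""

import pandas as pd
import pytest

from tubulequant import (
    DataValidationError,
    QuantConfig,
    StudyDesign,
    aggregate_by_sample,
    compute_section_metrics,
    quantify_sections,
)
from tubulequant.geometry import TubuleFeatures
from tubulequant.metrics import QC_FEW_ROUND, QC_SMALL_AREA


def tubule(tid, area, cells, *, is_round=True, is_intact=True):
    return TubuleFeatures(
        tubule_id=tid,
        area_mm2=area,
        diameter_long=1.0,
        diameter_short=1.0,
        roundness_ratio=1.0 if is_round else 2.0,
        is_round=is_round,
        is_intact=is_intact,
        cell_count_total=cells,
        cell_count_by_marker={"AP2G": 0, "MAGEA4": cells},
    )


class TestSectionMetrics:
    def test_method1_direct(self, default_config):
        feats = [tubule(f"T{i}", 0.05 / 6, 5, is_round=False) for i in range(6)]
        m = compute_section_metrics(feats, default_config)
        assert m.method1 == pytest.approx(30 / 0.05, rel=1e-12)  # 600 cells/mm^2

    def test_methods_2_to_4_direct(self, default_config):
        # 8 round tubules, combined area 0.02 mm^2, 20 cells, 7 with >= 1 cell
        cells = [6, 3, 2, 2, 3, 2, 2, 0]
        feats = [tubule(f"T{i}", 0.02 / 8, c) for i, c in enumerate(cells)]
        m = compute_section_metrics(feats, default_config)
        assert m.method2 == pytest.approx(2.5, rel=1e-12)
        assert m.method3 == pytest.approx(87.5, rel=1e-12)
        assert m.method4 == pytest.approx(1000.0, rel=1e-12)

    def test_zero_round_tubules_degenerate(self, default_config):
        feats = [tubule(f"T{i}", 0.01 / 4, 3, is_round=False) for i in range(4)]
        m = compute_section_metrics(feats, default_config)
        assert m.method1 == pytest.approx(1200.0, rel=1e-12)
        assert m.method2 is None and m.method3 is None and m.method4 is None
        assert QC_FEW_ROUND in m.qc_flags

    def test_zero_intact_tubules_all_missing_no_exception(self, default_config):
        feats = [tubule("T0", 0.01, 5, is_intact=False)]
        m = compute_section_metrics(feats, default_config)
        assert m.n_tubules_analysed == 0
        assert m.method1 is None
        assert {QC_FEW_ROUND, QC_SMALL_AREA} <= m.qc_flags

    def test_non_intact_tubules_excluded_from_counts(self, default_config):
        feats = [tubule("T0", 0.01, 5), tubule("T1", 0.01, 50, is_intact=False)]
        m = compute_section_metrics(feats, default_config)
        assert m.n_cells_total == 5
        assert m.total_tubular_area_mm2 == pytest.approx(0.01)

    def test_small_area_flag_by_tissue_type(self, default_config):
        feats = [tubule("T0", 0.01, 5)]
        fetal = compute_section_metrics(feats, default_config, tissue_type="fetal")
        prepub = compute_section_metrics(feats, default_config, tissue_type="prepubertal")
        assert QC_SMALL_AREA in fetal.qc_flags  # 0.01 < 0.015
        assert QC_SMALL_AREA not in prepub.qc_flags  # 0.01 >= 0.003


class TestMetricIdentities:
    def test_identities_on_simulated_sections(self, fetal_quantified):
        """method2 = method4 x mean round-tubule area; method3 in [0,100];
        all-round sections have method1 = method4."""
        sections, _ = fetal_quantified
        checked = 0
        for m in sections:
            if m.method2 is not None and m.method4 is not None:
                mean_round_area = m.round_tubular_area_mm2 / m.n_round
                assert m.method2 == pytest.approx(m.method4 * mean_round_area, rel=1e-12)
                checked += 1
            if m.method3 is not None:
                assert 0.0 <= m.method3 <= 100.0
            if m.n_round == m.n_tubules_analysed and m.method1 is not None and m.n_round > 0:
                assert m.method1 == m.method4
            assert m.n_round <= m.n_tubules_analysed
            assert m.n_round_with_cells <= m.n_round
            assert m.n_cells_in_round <= m.n_cells_total
            assert m.round_tubular_area_mm2 <= m.total_tubular_area_mm2 + 1e-15
        assert checked > 10

    def test_all_round_section_m1_equals_m4(self, default_config):
        feats = [tubule(f"T{i}", 0.005, i) for i in range(5)]
        m = compute_section_metrics(feats, default_config)
        assert m.method1 == m.method4
        assert m.n_cells_in_round == m.n_cells_total

    def test_fertility_index_extremes(self, default_config):
        all_filled = [tubule(f"T{i}", 0.005, 2) for i in range(4)]
        none_filled = [tubule(f"T{i}", 0.005, 0) for i in range(4)]
        assert compute_section_metrics(all_filled, default_config).method3 == 100.0
        assert compute_section_metrics(none_filled, default_config).method3 == 0.0

    def test_adding_a_cell_never_decreases_defined_metrics(self, default_config):
        base = [tubule("T0", 0.005, 2), tubule("T1", 0.005, 0)]
        plus = [tubule("T0", 0.005, 2), tubule("T1", 0.005, 1)]
        m0 = compute_section_metrics(base, default_config)
        m1 = compute_section_metrics(plus, default_config)
        for name in ("method1", "method2", "method3", "method4"):
            assert getattr(m1, name) >= getattr(m0, name)


class TestScaleInvariance:
    def test_unit_rescaling(self, fetal_study, default_config):
        """Rescaling coordinates by s leaves Methods 2-3 unchanged and
        multiplies Methods 1 and 4 by 1/s^2."""
        import shapely.affinity as aff

        from tubulequant import SectionAnnotation, TubuleAnnotation, GermCellMark
        from tubulequant.geometry import compute_tubule_features
        from tubulequant.metrics import compute_section_metrics

        sec = fetal_study.sections[0]
        s = 3.7
        scaled = SectionAnnotation(
            sec.section_id,
            sec.sample_id,
            aff.scale(sec.roi, s, s, origin=(0, 0)),
            [TubuleAnnotation(t.tubule_id, aff.scale(t.outline, s, s, origin=(0, 0)), t.intact_flag)
             for t in sec.tubules],
            [GermCellMark(c.cell_id, c.x * s, c.y * s, c.marker) for c in sec.cells],
        )
        cfg = default_config
        cfg_scaled = QuantConfig(edge_tolerance_mm=cfg.edge_tolerance_mm * s)
        m0 = compute_section_metrics(compute_tubule_features(sec, cfg), cfg)
        m1 = compute_section_metrics(compute_tubule_features(scaled, cfg_scaled), cfg_scaled)
        assert m1.method1 == pytest.approx(m0.method1 / s**2, rel=1e-9)
        assert m1.method4 == pytest.approx(m0.method4 / s**2, rel=1e-9)
        assert m1.method2 == pytest.approx(m0.method2, rel=1e-9)
        assert m1.method3 == pytest.approx(m0.method3, rel=1e-9)


class TestAggregation:
    def _sections(self, default_config, specs):
        out = []
        for sid, sample, feats in specs:
            m = compute_section_metrics(feats, default_config, section_id=sid, sample_id=sample)
            out.append(m)
        return out

    def _design(self, samples):
        return StudyDesign(pd.DataFrame({
            "sample_id": samples,
            "subject_id": [f"subj{i}" for i in range(len(samples))],
            "condition": ["control"] * len(samples),
            "tissue_type": ["fetal"] * len(samples),
        }))

    def test_per_section_mean(self, default_config):
        secs = self._sections(default_config, [
            ("s1", "A", [tubule("T0", 0.05, 30, is_round=False)]),   # m1 = 600
            ("s2", "A", [tubule("T0", 0.05, 40, is_round=False)]),   # m1 = 800
        ])
        samples = aggregate_by_sample(secs, self._design(["A"]), default_config)
        assert samples[0].method1 == pytest.approx(700.0, rel=1e-12)

    def test_pooled_counts(self):
        cfg = QuantConfig(pooling_mode="pooled_counts")
        secs = self._sections(cfg, [
            ("s1", "A", [tubule("T0", 0.02, 10, is_round=False)]),
            ("s2", "A", [tubule("T0", 0.02, 30, is_round=False)]),
        ])
        samples = aggregate_by_sample(secs, self._design(["A"]), cfg)
        assert samples[0].method1 == pytest.approx(1000.0, rel=1e-12)  # (10+30)/0.04

    def test_missing_sections_omitted_from_metric_mean(self, default_config):
        secs = self._sections(default_config, [
            ("s1", "A", [tubule("T0", 0.05, 9, is_round=False)]),  # method2 missing
            ("s2", "A", [tubule("T0", 0.05, 3, is_round=True)]),   # method2 = 3
        ])
        samples = aggregate_by_sample(secs, self._design(["A"]), default_config)
        assert samples[0].method2 == pytest.approx(3.0)

    def test_unknown_sample_is_design_error(self, default_config):
        secs = self._sections(default_config, [("s1", "ghost", [tubule("T0", 0.05, 1)])])
        with pytest.raises(DataValidationError, match="ghost"):
            aggregate_by_sample(secs, self._design(["A"]), default_config)

    def test_pooling_modes_agree_for_single_section_samples(self, fetal_study):
        cfg_mean = QuantConfig(pooling_mode="per_section_mean")
        cfg_pool = QuantConfig(pooling_mode="pooled_counts")
        sections = fetal_study.sections[:6]
        # restrict design to the samples present
        present = {s.sample_id for s in sections}
        # keep one section per sample
        seen, singles = set(), []
        for s in sections:
            if s.sample_id not in seen:
                seen.add(s.sample_id)
                singles.append(s)
        _, mean_samples = quantify_sections(singles, fetal_study.design, cfg_mean)
        _, pool_samples = quantify_sections(singles, fetal_study.design, cfg_pool)
        for a, b in zip(mean_samples, pool_samples):
            for name in ("method1", "method2", "method3", "method4"):
                va, vb = getattr(a, name), getattr(b, name)
                if va is None:
                    assert vb is None
                else:
                    assert va == pytest.approx(vb, rel=1e-12)
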