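"""QTL projection: homothetic transfer, one-flank completion, discard rules."""

import pytest
from hypothesis import given, strategies as st

from mqtlmap.consensus import ConsensusMap
from mqtlmap.core import (
    CoordSystem,
    ExperimentMeta,
    GeneticMap,
    MarkerLocus,
    QTLRecord,
    Trait,
)
from mqtlmap.projection import (
    ProjectionError,
    Provenance,
    project_position,
    project_qtl,
    project_qtls,
)
from mqtlmap.anchoring import physical_to_genetic


def _consensus(group_markers, map_id="consensus"):
    groups = {
        g: [
            MarkerLocus(n, g, pos, physical_pos=bp)
            for n, pos, *rest in markers
            for bp in [rest[0] if rest else None]
        ]
        for g, markers in group_markers.items()
    }
    return ConsensusMap(map_id, groups)


@pytest.fixture
def experiment():
    return ExperimentMeta("e1", "AxB", "F2", 265, 1, "CIM")


class TestProjectPosition:
    # shared markers: A(source 5 -> consensus 10), B(source 15 -> consensus 30)
    XS, YS = [5.0, 15.0], [10.0, 30.0]

    def test_midpoint_maps_to_midpoint(self):
        assert project_position(10.0, self.XS, self.YS) == (20.0, False)

    def test_identity_at_anchor(self):
        assert project_position(5.0, self.XS, self.YS) == (10.0, False)

    def test_extrapolation_uses_nearest_interval_ratio(self):
        value, extrapolated = project_position(20.0, self.XS, self.YS)
        assert value == pytest.approx(40.0)
        assert extrapolated

    @given(
        pos_a=st.floats(min_value=0, max_value=20),
        pos_b=st.floats(min_value=0, max_value=20),
    )
    def test_order_preservation(self, pos_a, pos_b):
        xs = [0.0, 4.0, 12.0, 20.0]
        ys = [0.0, 10.0, 15.0, 40.0]
        va, _ = project_position(pos_a, xs, ys)
        vb, _ = project_position(pos_b, xs, ys)
        if pos_a < pos_b:
            assert va <= vb


class TestPhysicalToGenetic:
    ANCHORS = [(10.0, 1_000_000.0), (20.0, 3_000_000.0)]

    def test_linear(self):
        g, _ = physical_to_genetic(2_000_000, self.ANCHORS)
        assert g == pytest.approx(15.0)

    def test_identity_at_anchor(self):
        g, extrapolated = physical_to_genetic(1_000_000, self.ANCHORS)
        assert g == pytest.approx(10.0) and not extrapolated

    def test_extrapolation_flagged(self):
        g, extrapolated = physical_to_genetic(500_000, self.ANCHORS)
        assert g == pytest.approx(7.5)
        assert extrapolated


class TestProjectQTL:
    def _setup(self):
        source = GeneticMap(
            "s1", {"1": [MarkerLocus("A", "1", 5.0), MarkerLocus("B", "1", 15.0)]}
        )
        consensus = _consensus(
            {"1": [("A2", 0.0), ("A", 10.0), ("B", 30.0), ("Z", 60.0)]}
        )
        return source, consensus

    def test_peak_and_ci_projected_independently(self, experiment):
        source, consensus = self._setup()
        qtl = QTLRecord("q1", Trait.GDR, "e1", "1", 10.0, 6.0, 14.0, lod=3.0)
        p = project_qtl(qtl, source, consensus, experiment)
        assert p.peak_pos == pytest.approx(20.0)
        assert (p.ci_start, p.ci_end) == (pytest.approx(12.0), pytest.approx(28.0))
        assert p.sigma == pytest.approx(16.0 / 3.92)
        assert p.provenance is Provenance.BOTH_FLANKS

    def test_one_flank_completion_rule(self, experiment):
        consensus = _consensus({"1": [("F", 50.0), ("G", 120.0)]})
        # imputed width: 530 / (265 * 0.25) = 8 cM
        qtl = QTLRecord(
            "q2",
            Trait.GDR,
            "e1",
            "1",
            flank_left="F",
            flank_right="unknown",
            r_squared=0.25,
        )
        p = project_qtl(qtl, None, consensus, experiment)
        assert (p.ci_start, p.ci_end) == (pytest.approx(50.0), pytest.approx(58.0))
        assert p.peak_pos == pytest.approx(54.0)
        assert p.provenance is Provenance.ONE_FLANK_PLUS_FORMULA

    def test_both_flanks_on_consensus(self, experiment):
        consensus = _consensus({"1": [("F", 50.0), ("G", 120.0)]})
        qtl = QTLRecord(
            "q3", Trait.GDR, "e1", "1", flank_left="F", flank_right="G", r_squared=0.1
        )
        p = project_qtl(qtl, None, consensus, experiment)
        assert (p.ci_start, p.ci_end) == (50.0, 120.0)

    def test_unmappable_qtl_discarded_with_reason(self, experiment):
        consensus = _consensus({"1": [("F", 50.0), ("G", 120.0)]})
        qtl = QTLRecord(
            "q4",
            Trait.GDR,
            "e1",
            "1",
            flank_left="nope1",
            flank_right="nope2",
            r_squared=0.1,
        )
        with pytest.raises(ProjectionError, match="neither flanking marker"):
            project_qtl(qtl, None, consensus, experiment)
        projected, discarded = project_qtls(
            [qtl], {}, consensus, {"e1": experiment}
        )
        assert projected == []
        assert discarded[0].qtl_id == "q4"

    def test_physical_route_through_anchors(self, experiment):
        consensus = _consensus(
            {"1": [("F", 10.0, 1_000_000), ("G", 20.0, 3_000_000)]}
        )
        qtl = QTLRecord(
            "q5",
            Trait.GDR,
            "e1",
            "1",
            peak_pos=2_000_000.0,
            ci_start=1_500_000.0,
            ci_end=2_500_000.0,
            r_squared=0.1,
            coord_system=CoordSystem.PHYSICAL,
        )
        p = project_qtl(qtl, None, consensus, experiment)
        assert p.peak_pos == pytest.approx(15.0)
        assert (p.ci_start, p.ci_end) == (pytest.approx(12.5), pytest.approx(17.5))
        assert p.provenance is Provenance.PHYSICAL_CONVERTED

    def test_extrapolation_beyond_cap_discards(self, experiment):
        source, consensus = self._setup()
        # group span 0-60; cap 0.2 -> 12 cM allowance
        qtl = QTLRecord("q6", Trait.GDR, "e1", "1", 60.0, 55.0, 65.0, lod=3.0)
        with pytest.raises(ProjectionError, match="extrapolates"):
            project_qtl(qtl, source, consensus, experiment, extrapolation_cap=0.2)

    def test_every_projected_ci_positive(self, sim_data):
        from mqtlmap.consensus import merge_maps

        consensus = merge_maps(sim_data.reference, list(sim_data.study_maps.values()))
        projected, discarded = project_qtls(
            sim_data.qtls,
            sim_data.study_maps,
            consensus,
            sim_data.experiments,
            sim_data.experiment_to_map,
        )
        assert len(projected) + len(discarded) == len(sim_data.qtls)
        assert all(p.ci_end - p.ci_start > 0 for p in projected)
        assert all(p.ci_start <= p.peak_pos <= p.ci_end for p in projected)
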