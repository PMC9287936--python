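"""The synthetic study generator: determinism, round trips, planted truth."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from mqtlmap import io as mio
from mqtlmap.ci import impute_ci
from mqtlmap.consensus import merge_maps
from mqtlmap.core import CoordSystem, PopulationType, Trait
from mqtlmap.genes import (
    GeneAnnotation,
    classify_expression_window,
    genes_in_interval,
    go_enrichment,
    profiles_from_matrix,
)
from mqtlmap.meta import select_model
from mqtlmap.projection import Provenance, project_qtls
from mqtlmap.simulate import (
    SimulationScenario,
    plan_true_mqtls,
    simulate,
    simulate_reference_map,
    write_bundle,
)

from conftest import small_scenario


class TestReferenceMap:
    def test_structure_and_density(self):
        scenario = small_scenario()
        ref = simulate_reference_map(scenario)
        assert len(ref.groups) == scenario.n_chromosomes
        assert ref.n_markers == scenario.n_chromosomes * scenario.ref_markers_per_group
        for loci in ref.groups.values():
            pos = [m.genetic_pos for m in loci]
            assert pos == sorted(pos)
            bps = [m.physical_pos for m in loci if m.physical_pos is not None]
            assert bps == sorted(bps)  # monotone cM -> bp
            assert loci[0].is_anchor and loci[-1].is_anchor

    def test_determinism(self):
        a = simulate_reference_map(small_scenario(seed=9))
        b = simulate_reference_map(small_scenario(seed=9))
        for group in a.groups:
            assert [(m.name, m.genetic_pos, m.physical_pos) for m in a.groups[group]] == [
                (m.name, m.genetic_pos, m.physical_pos) for m in b.groups[group]
            ]

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            small_scenario(ref_markers_per_group=0)


class TestScenarioValidation:
    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            small_scenario(missing_ci_fraction=1.5)

    def test_unordered_range_rejected(self):
        with pytest.raises(ValueError):
            small_scenario(r2_range=(0.9, 0.1))

    def test_true_mqtl_outside_span_rejected(self):
        scenario = small_scenario(true_mqtls={"GDR": {"1": [(999.0, 4)]}})
        with pytest.raises(ValueError, match="outside group span"):
            plan_true_mqtls(scenario)


class TestSimulatedStudy:
    def test_counts_match_scenario(self, sim_data):
        scenario = sim_data.scenario
        traits = pd.Series([q.trait.value for q in sim_data.qtls]).value_counts()
        assert traits["GDR"] == scenario.n_gdr_qtls
        assert traits["GWC"] == scenario.n_gwc_qtls
        assert len(sim_data.experiments) == scenario.n_experiments
        assert len(sim_data.study_maps) <= scenario.n_mapped_experiments
        assert len(sim_data.truth) == len(sim_data.qtls)

    def test_bundle_round_trips_through_readers(self, sim_data, bundle_dir):
        ref = mio.read_genetic_map(bundle_dir / "maps" / "reference.tsv", "reference")
        assert ref.n_markers == sim_data.reference.n_markers
        experiments = mio.read_experiment_table(bundle_dir / "experiments.tsv")
        assert set(experiments) == set(sim_data.experiments)
        accepted, rejected = mio.read_qtl_table(bundle_dir / "qtls.tsv", experiments)
        assert len(accepted) == len(sim_data.qtls)
        assert rejected == []
        by_id = {q.qtl_id: q for q in sim_data.qtls}
        for q in accepted:
            assert q == by_id[q.qtl_id]

    def test_bundle_byte_identical_across_runs(self, tmp_path):
        for run in ("a", "b"):
            write_bundle(simulate(small_scenario(seed=3)), tmp_path / run)
        for rel in ("qtls.tsv", "experiments.tsv", "maps/reference.tsv", "fpkm.tsv"):
            assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel, shallow=False)

    def test_missing_ci_records_expose_formula(self):
        data = simulate(small_scenario(seed=5, missing_ci_fraction=1.0, n_snp_experiments=0))
        mapped = {e for e in data.experiment_to_map}
        for q in data.qtls:
            if q.experiment_id in mapped:
                assert not q.has_ci and q.r_squared is not None
                meta = data.experiments[q.experiment_id]
                width = impute_ci(meta.population_size, q.r_squared, meta.population_type)
                expected = {
                    PopulationType.RIL: 163.0,
                    PopulationType.DH: 163.0,
                }.get(meta.population_type, 530.0)
                assert width == pytest.approx(
                    expected / (meta.population_size * q.r_squared)
                )

    def test_identity_limit_projection_recovers_peaks(self):
        data = simulate(
            small_scenario(
                seed=6,
                shared_marker_fraction=1.0,
                map_distortion=0.0,
                study_only_markers_per_group=0,
                missing_ci_fraction=0.0,
                n_snp_experiments=0,
                one_flank_fraction=0.0,
            )
        )
        consensus = merge_maps(data.reference, list(data.study_maps.values()))
        projected, discarded = project_qtls(
            data.qtls, data.study_maps, consensus, data.experiments, data.experiment_to_map
        )
        by_id = {q.qtl_id: q for q in data.qtls}
        checked = 0
        for p in projected:
            src = by_id[p.qtl_id]
            if src.coord_system is CoordSystem.GENETIC and src.peak_pos is not None and src.has_ci:
                assert p.peak_pos == pytest.approx(src.peak_pos, abs=1e-6)
                checked += 1
        assert checked > 10

    def test_two_planted_clusters_recovered(self):
        scenario = small_scenario(
            seed=8,
            true_mqtls={"GDR": {"1": [(30.0, 5), (70.0, 5)]}, "GWC": {"2": [(50.0, 3)]}},
            qtl_sigma_range=(1.5, 2.5),
            shared_marker_fraction=1.0,
            map_distortion=0.0,
            missing_ci_fraction=0.0,
            n_snp_experiments=0,
            one_flank_fraction=0.0,
        )
        data = simulate(scenario)
        consensus = merge_maps(data.reference, list(data.study_maps.values()))
        projected, _ = project_qtls(
            data.qtls, data.study_maps, consensus, data.experiments, data.experiment_to_map
        )
        gdr = [p for p in projected if p.source.trait is Trait.GDR]
        res = select_model([p.peak_pos for p in gdr], [p.sigma for p in gdr])
        assert res.k == 2
        assert res.means == pytest.approx([30.0, 70.0], abs=3.0)


class TestAnnotationAndExpression:
    def test_planted_profiles_classified_as_labelled(self, sim_data):
        profiles = {p.gene_id: p for p in profiles_from_matrix(sim_data.fpkm)}
        labels = sim_data.gene_labels.set_index("gene_id")["window_label"]
        agree = 0
        total = 0
        for gene_id, label in labels.items():
            window = classify_expression_window(profiles[gene_id])
            total += 1
            agree += window.value == label
        assert agree / total > 0.95

    def test_planted_term_enriched(self, sim_data):
        labels = sim_data.gene_labels
        study = labels.loc[labels["in_mqtl"], "gene_id"].tolist()
        population = labels["gene_id"].tolist()
        results = {
            r.term_id: r
            for r in go_enrichment(study, population, sim_data.go_table)
        }
        assert results["GO:1111111"].enriched
        assert results["GO:1111111"].p_value < 0.01

    def test_interval_recovers_planted_genes(self, sim_data, bundle_dir):
        annotation = GeneAnnotation.from_gff3(bundle_dir / "annotation.gff3")
        assert len(annotation) == len(sim_data.genes)
        chrom = sim_data.genes[0].interval.chromosome
        subset = [g for g in sim_data.genes if g.interval.chromosome == chrom][:5]
        lo = min(g.interval.start for g in subset)
        hi = max(g.interval.end for g in subset)
        from mqtlmap.core import GenomicInterval

        hits = genes_in_interval(annotation, GenomicInterval(chrom, lo, hi))
        assert {g.gene_id for g in subset} <= {g.gene_id for g in hits}
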