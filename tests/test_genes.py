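"""Candidate genes, GO enrichment and expression-window classification."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mqtlmap.core import GenomicInterval
from mqtlmap.genes import (
    ExpressionProfile,
    ExpressionWindow,
    GeneAnnotation,
    classify_expression_window,
    genes_in_interval,
    go_enrichment,
    intersect_gene_lists,
    profiles_from_matrix,
)

GFF = """##gff-version 3
1\ttest\tgene\t100\t200\t.\t+\t.\tID=g1
1\ttest\tgene\t250\t350\t.\t-\t.\tID=g2
1\ttest\tgene\t400\t500\t.\t+\t.\tID=g3
1\ttest\tgene\t600\t700\t.\t+\t.\tID=g4
2\ttest\tgene\t100\t200\t.\t+\t.\tID=g5
"""


@pytest.fixture(scope="module")
def annotation(tmp_path_factory):
    path = tmp_path_factory.mktemp("gff") / "genes.gff3"
    path.write_text(GFF)
    return GeneAnnotation.from_gff3(path)


class TestGenesInInterval:
    def test_partial_overlap_included(self, annotation):
        hits = genes_in_interval(annotation, GenomicInterval("1", 150, 300))
        assert [g.gene_id for g in hits] == ["g1", "g2"]

    def test_adjacent_gene_excluded(self, annotation):
        hits = genes_in_interval(annotation, GenomicInterval("1", 201, 249))
        assert hits == []

    def test_interval_spanning_three_genes(self, annotation):
        hits = genes_in_interval(annotation, GenomicInterval("1", 150, 450))
        assert [g.gene_id for g in hits] == ["g1", "g2", "g3"]

    def test_whole_chromosome_returns_all(self, annotation):
        hits = genes_in_interval(annotation, GenomicInterval("1", 1, 10_000))
        assert [g.gene_id for g in hits] == ["g1", "g2", "g3", "g4"]

    def test_absent_chromosome_empty(self, annotation):
        assert genes_in_interval(annotation, GenomicInterval("9", 1, 100)) == []


class TestIntersect:
    def test_order_follows_first_list(self):
        assert intersect_gene_lists(["g1", "g2", "g3"], ["g3", "g2"]) == ["g2", "g3"]

    def test_disjoint(self):
        assert intersect_gene_lists(["g1"], ["g2"]) == []

    def test_idempotent(self):
        assert intersect_gene_lists(["g1", "g2"], ["g1", "g2"]) == ["g1", "g2"]


class TestEnrichment:
    def test_closed_form_hypergeometric(self):
        annotation = {"g1": {"T"}, "g2": {"T"}}
        results = go_enrichment(["g1", "g2"], ["g1", "g2", "g3", "g4"], annotation)
        (r,) = results
        assert r.p_value == pytest.approx(1 / 6)
        assert not r.enriched
        assert (r.study_count, r.population_count) == (2, 2)

    def test_term_absent_from_study_has_p_one(self):
        annotation = {"g3": {"T"}}
        (r,) = go_enrichment(["g1"], ["g1", "g2", "g3"], annotation)
        assert r.p_value == pytest.approx(1.0)
        assert not r.enriched

    def test_study_must_be_subset(self):
        with pytest.raises(ValueError):
            go_enrichment(["gX"], ["g1"], {})

    def test_relabeling_invariance(self):
        ann1 = {"g1": {"T"}, "g2": {"T"}}
        ann2 = {"x1": {"T"}, "x2": {"T"}}
        p1 = go_enrichment(["g1", "g2"], ["g1", "g2", "g3"], ann1)[0].p_value
        p2 = go_enrichment(["x1", "x2"], ["x1", "x2", "x3"], ann2)[0].p_value
        assert p1 == p2

    def test_degenerate_all_genes_in_term(self):
        annotation = {f"g{i}": {"T"} for i in range(4)}
        genes = [f"g{i}" for i in range(4)]
        (r,) = go_enrichment(genes, genes, annotation)
        assert r.p_value == pytest.approx(1.0)

    def test_permutation_oracle(self, rng):
        # empirical tail frequency under random term assignment matches the
        # hypergeometric upper-tail probability within Monte-Carlo error
        population = [f"g{i}" for i in range(20)]
        study = population[:8]
        n_term = 6
        observed_k = 4
        # term on 4 study genes and 2 non-study genes -> study_count = 4
        annotation = {g: {"T"} for g in study[:4] + population[8:10]}
        (r,) = go_enrichment(study, population, annotation)
        p_obs = sum(
            math.comb(n_term, k) * math.comb(20 - n_term, 8 - k)
            for k in range(observed_k, n_term + 1)
        ) / math.comb(20, 8)
        assert r.p_value == pytest.approx(p_obs, rel=1e-12)
        hits = 0
        n_perm = 400
        for _ in range(n_perm):
            term_genes = set(rng.choice(population, size=n_term, replace=False))
            k = len(term_genes & set(study))
            hits += k >= observed_k
        mc_se = math.sqrt(p_obs * (1 - p_obs) / n_perm)
        assert hits / n_perm == pytest.approx(p_obs, abs=4 * mc_se)


class TestExpressionClassification:
    T = np.arange(0.0, 39.0, 2.0)

    def _profile(self, values):
        return ExpressionProfile("g", self.T, np.asarray(values, dtype=float))

    def test_early_peak(self):
        values = np.where(self.T <= 6, 50.0, 0.01)
        assert classify_expression_window(self._profile(values)) is ExpressionWindow.EARLY

    def test_early_and_late(self):
        values = np.where((self.T <= 6) | (self.T >= 32), 40.0, 0.01)
        assert (
            classify_expression_window(self._profile(values))
            is ExpressionWindow.EARLY_AND_LATE
        )

    def test_mid_window(self):
        values = np.where((self.T >= 12) & (self.T <= 28), 30.0, 0.01)
        assert classify_expression_window(self._profile(values)) is ExpressionWindow.MID

    def test_late_window(self):
        values = np.where(self.T >= 32, 30.0, 0.01)
        assert classify_expression_window(self._profile(values)) is ExpressionWindow.LATE

    def test_all_zero_not_expressed(self):
        profile = self._profile(np.zeros_like(self.T))
        assert not profile.expressed
        assert classify_expression_window(profile) is ExpressionWindow.NOT_EXPRESSED

    def test_low_fpkm_not_expressed(self):
        values = np.full_like(self.T, 0.4)
        assert (
            classify_expression_window(self._profile(values))
            is ExpressionWindow.NOT_EXPRESSED
        )

    @given(scale=st.floats(min_value=0.01, max_value=1000.0))
    def test_normalization_scale_invariant(self, scale):
        base = np.where(self.T <= 6, 50.0, 0.5)
        p1 = ExpressionProfile("g", self.T, base)
        p2 = ExpressionProfile("g", self.T, base * scale)
        assert np.allclose(p1.normalized, p2.normalized)
        assert p2.normalized.max() == pytest.approx(1.0)

    def test_profiles_from_matrix(self):
        import pandas as pd

        fpkm = pd.DataFrame(
            [[0.0, 10.0], [5.0, 0.0]], index=["gA", "gB"], columns=[4.0, 34.0]
        )
        profiles = profiles_from_matrix(fpkm)
        assert [p.gene_id for p in profiles] == ["gA", "gB"]
        assert profiles[0].normalized[1] == 1.0
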