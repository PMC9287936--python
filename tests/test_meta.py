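"""The mixture core: closed forms, EM vs exhaustive oracle, MQTL extraction."""

import numpy as np
import pytest

from mqtlmap.core import Trait
from mqtlmap.meta import (
    QTLMixture,
    extract_mqtls,
    filter_mqtls,
    fit_mixture,
    n_parameters,
    select_model,
)

from conftest import make_projected
from oracles import select_k_oracle


class TestClosedForms:
    def test_equal_sigmas_k1_is_plain_mean(self):
        res = fit_mixture([10.0, 20.0], [2.0, 2.0], 1)
        assert res.means[0] == pytest.approx(15.0, abs=1e-12)

    def test_k1_is_inverse_variance_weighted_mean(self):
        res = fit_mixture([10.0, 20.0], [1.0, 2.0], 1)
        assert res.means[0] == pytest.approx(12.0, abs=1e-12)
        assert res.aic == pytest.approx(-2 * res.loglik + 2)

    def test_two_tight_clusters_k2(self):
        res = fit_mixture([10.0, 10.5, 50.0, 50.5], [1.0] * 4, 2)
        assert res.means == pytest.approx([10.25, 50.25], abs=1e-4)
        assert res.proportions == pytest.approx([0.5, 0.5], abs=1e-6)


class TestModelSelection:
    def test_single_qtl_selects_k1(self):
        res = select_model([42.0], [3.0])
        assert res.k == 1 and res.means[0] == pytest.approx(42.0)

    def test_two_separated_clusters_select_k2(self):
        res = select_model([10.0, 10.5, 50.0, 50.5], [1.0] * 4)
        assert res.k == 2

    def test_identical_positions_select_k1(self):
        res = select_model([30.0] * 12, [2.0] * 12)
        assert res.k == 1

    def test_loglik_nondecreasing_and_aic_definition(self, rng):
        x = rng.uniform(0, 100, 7)
        s = rng.uniform(0.5, 5.0, 7)
        res = select_model(x, s)
        prof = res.aic_profile
        # non-decreasing up to EM tolerance (the proportion floor can cost
        # a few 1e-6 at k close to n)
        assert (np.diff(prof["loglik"]) > -1e-4).all()
        assert np.allclose(
            prof["aic"], -2 * prof["loglik"] + 2 * (2 * prof["k"] - 1)
        )

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_exhaustive_partition_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 9))
        x = rng.uniform(0, 100, n)
        s = np.exp(rng.uniform(np.log(0.5), np.log(15), n))
        res = select_model(x, s)
        k_oracle, ll_oracle = select_k_oracle(list(x), list(s))
        assert res.k == k_oracle
        assert res.loglik == pytest.approx(ll_oracle, abs=1e-6)

    def test_permutation_invariance(self, rng):
        x = rng.uniform(0, 100, 10)
        s = rng.uniform(0.5, 5.0, 10)
        perm = rng.permutation(10)
        a = select_model(x, s)
        b = select_model(x[perm], s[perm])
        assert a.k == b.k
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)
        assert np.allclose(a.means, b.means)
        assert np.array_equal(a.assignments()[perm], b.assignments())

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            QTLMixture([1.0], [0.0])
        with pytest.raises(ValueError):
            QTLMixture([np.nan], [1.0])
        with pytest.raises(ValueError):
            QTLMixture([1.0, 2.0], [1.0, 1.0]).fit(3)

    def test_k_capped_at_n(self):
        res = select_model([1.0, 2.0, 3.0], [1.0] * 3, k_max=10)
        assert res.aic_profile["k"].max() == 3


class TestExtractMQTLs:
    def test_consensus_se_and_ci(self):
        members = [
            make_projected(f"q{i}", f"e{i}", "2", 50.0, 4 * 3.92) for i in range(4)
        ]
        fit = QTLMixture([m.peak_pos for m in members], [m.sigma for m in members]).fit(1)
        (mqtl,) = extract_mqtls(fit, members, Trait.GDR, "2")
        assert mqtl.se == pytest.approx(2.0)
        assert mqtl.ci_width == pytest.approx(7.84)
        assert mqtl.n_experiments == 4
        assert mqtl.name == "mGdr2-1"

    def test_single_member_keeps_its_ci_width(self):
        members = [make_projected("q0", "e0", "3", 20.0, 10.0)]
        fit = QTLMixture([20.0], [members[0].sigma]).fit(1)
        (mqtl,) = extract_mqtls(fit, members, Trait.GWC, "3")
        assert mqtl.ci_width == pytest.approx(10.0)
        assert mqtl.name == "mGwc3-1"

    def test_pve_is_mean_of_member_r2(self):
        members = [
            make_projected("q0", "e0", "1", 10.0, 8.0, r_squared=0.08),
            make_projected("q1", "e1", "1", 10.5, 8.0, r_squared=0.12),
        ]
        fit = QTLMixture([10.0, 10.5], [m.sigma for m in members]).fit(1)
        (mqtl,) = extract_mqtls(fit, members, Trait.GDR, "1")
        assert mqtl.pve_percent == pytest.approx(10.0)

    def test_consensus_ci_never_wider_than_narrowest_member(self, rng):
        members = [
            make_projected(f"q{i}", f"e{i}", "1", float(rng.uniform(40, 42)), float(rng.uniform(4, 30)))
            for i in range(6)
        ]
        fit = QTLMixture(
            [m.peak_pos for m in members], [m.sigma for m in members]
        ).fit(1)
        (mqtl,) = extract_mqtls(fit, members, Trait.GDR, "1")
        assert mqtl.ci_width <= min(m.ci_end - m.ci_start for m in members) + 1e-9

    def test_empty_component_dropped(self):
        members = [
            make_projected("q0", "e0", "1", 10.0, 8.0),
            make_projected("q1", "e1", "1", 10.0, 8.0),
        ]
        fit = QTLMixture([10.0, 10.0], [m.sigma for m in members]).fit(2)
        mqtls = extract_mqtls(fit, members, Trait.GDR, "1")
        # both observations land in one component; the other is dropped
        assert len(mqtls) == 1 and len(mqtls[0].members) == 2

    def test_names_ranked_by_position(self):
        members = [
            make_projected("qa", "e0", "2", 80.0, 4.0),
            make_projected("qb", "e1", "2", 10.0, 4.0),
        ]
        fit = QTLMixture([80.0, 10.0], [m.sigma for m in members]).fit(2)
        mqtls = extract_mqtls(fit, members, Trait.GDR, "2")
        assert [m.name for m in mqtls] == ["mGdr2-1", "mGdr2-2"]
        assert mqtls[0].position < mqtls[1].position


class TestFilter:
    def _mqtls(self):
        m1 = make_projected("q0", "e0", "1", 10.0, 8.0)
        m2 = make_projected("q1", "e0", "1", 11.0, 8.0)
        m3 = make_projected("q2", "e1", "1", 50.0, 8.0)
        fit = QTLMixture([10.0, 11.0, 50.0], [m.sigma for m in (m1, m2, m3)]).fit(2)
        return extract_mqtls(fit, [m1, m2, m3], Trait.GDR, "1")

    def test_single_experiment_mqtl_removed(self):
        mqtls = self._mqtls()
        kept = filter_mqtls(mqtls, min_experiments=2)
        assert kept == []  # both clusters are single-experiment

    def test_min_experiments_one_is_identity(self):
        mqtls = self._mqtls()
        assert filter_mqtls(mqtls, min_experiments=1) == mqtls


def test_parameter_count():
    assert [n_parameters(k) for k in (1, 2, 5)] == [1, 3, 9]


def test_summary_contains_fit_facts():
    res = select_model([10.0, 10.5, 50.0, 50.5], [1.0] * 4)
    text = res.summary()
    assert "K: 2" in text and "AIC" in text
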