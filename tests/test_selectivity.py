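import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuerank.core_model import partition_from_labels
from tissuerank.selectivity import (
    SelectivityConfig,
    attach_p_values,
    candidate_filter,
    count_significant,
    expression_means,
    is_significant,
    permutation_pvalue,
    priority_score,
    rank_tissue,
    raw_priority_score,
    score1,
    score2,
    score_probe,
)


class TestIsSignificant:
    def test_definition(self):
        assert is_significant(1.2, "P", 1.0)
        assert not is_significant(0.8, "P", 1.0)
        assert not is_significant(5.0, "A", 1.0)

    def test_theta_zero_call_only(self):
        assert is_significant(0.0, "P", 0.0)

    def test_marginal_not_significant(self):
        assert not is_significant(1.0, "M", 1.0)

    def test_boundary_inclusive(self):
        assert is_significant(1.0, "P", 1.0)


class TestCountSignificant:
    def test_saturation(self, partition_10_90):
        values = np.full(100, 2.0)
        calls = np.full(100, "P")
        assert count_significant(values, calls, partition_10_90, 1.0) == (10, 90)

    def test_all_absent(self, partition_10_90):
        values = np.full(100, 2.0)
        calls = np.full(100, "A")
        assert count_significant(values, calls, partition_10_90, 1.0) == (0, 0)

    def test_matches_loop_oracle(self, partition_10_90):
        rng = np.random.default_rng(0)
        values = rng.lognormal(0, 1, 100)
        calls = rng.choice(["P", "M", "A"], 100)
        se, sc = count_significant(values, calls, partition_10_90, 1.0)
        se_oracle = sum(
            1 for i in partition_10_90.experiment_index
            if calls[i] == "P" and values[i] >= 1.0
        )
        sc_oracle = sum(
            1 for i in partition_10_90.control_index
            if calls[i] == "P" and values[i] >= 1.0
        )
        assert (se, sc) == (se_oracle, sc_oracle)


class TestCandidateFilter:
    def test_boundary_inclusive_both_sides(self):
        config = SelectivityConfig(min_se=62, max_sc=24)
        assert candidate_filter(62, 24, config)

    def test_below_min(self):
        assert not candidate_filter(61, 0, SelectivityConfig(min_se=62, max_sc=24))

    def test_above_max(self):
        assert not candidate_filter(100, 25, SelectivityConfig(min_se=62, max_sc=24))


class TestExpressionMeans:
    def test_hand_arithmetic(self):
        part = partition_from_labels(["t"] * 3 + ["c"] * 4, "t")
        values = np.array([2.0, 2.0, 4.0, 1.0, 0.5, 0.2, 3.0])
        calls = np.array(["P"] * 3 + ["A"] * 4)
        ee, ec = expression_means(values, calls, part, 0.0)
        assert ee == pytest.approx(8 / 3)
        assert ec == pytest.approx((3.0 + 1.0 + 0.5) / 3)

    def test_constant_controls(self, partition_10_90):
        values = np.concatenate([np.full(10, 5.0), np.full(90, 0.7)])
        calls = np.full(100, "P")
        ee, ec = expression_means(values, calls, partition_10_90, 1.0)
        assert ec == pytest.approx(0.7)

    def test_matches_topk_oracle(self, partition_10_90):
        rng = np.random.default_rng(1)
        values = rng.lognormal(0, 1, 100)
        calls = rng.choice(["P", "A"], 100)
        try:
            ee, ec = expression_means(values, calls, partition_10_90, 1.0)
        except ValueError:
            pytest.skip("Se = 0 for this seed")
        exp = list(partition_10_90.experiment_index)
        sig = [i for i in exp if calls[i] == "P" and values[i] >= 1.0]
        ctl_sorted = sorted(
            (values[i] for i in partition_10_90.control_index), reverse=True
        )
        assert ee == pytest.approx(np.mean([values[i] for i in sig]))
        assert ec == pytest.approx(np.mean(ctl_sorted[: len(sig)]))

    def test_se_zero_error(self, partition_10_90):
        values = np.ones(100)
        calls = np.full(100, "A")
        with pytest.raises(ValueError, match="Se = 0"):
            expression_means(values, calls, partition_10_90, 1.0)


class TestScores:
    def test_score1_brain_top_row(self):
        # oracle: printed priority score minus log10 of printed fold
        assert score1(284, 0, 616, 2352, 0.1) == pytest.approx(4.0353, abs=5e-5)

    def test_score1_liver_top_row(self):
        assert score1(116, 0, 117, 2851, 0.1) == pytest.approx(4.4516, abs=1e-4)

    def test_score1_symmetry_zero(self):
        assert score1(10, 10, 100, 100, 0.1) == 0.0

    def test_score2_folds(self):
        assert score2(13.64, 1.0) == pytest.approx(1.1348, abs=5e-5)
        assert score2(4.54, 1.0) == pytest.approx(0.6571, abs=5e-5)

    def test_score2_boundary(self):
        assert score2(3.0, 3.0) == 0.0

    def test_score2_nonpositive_error(self):
        with pytest.raises(ValueError):
            score2(0.0, 1.0)

    def test_priority_score_brain(self):
        s = priority_score(score1(284, 0, 616, 2352), math.log10(4.54))
        assert round(s, 2) == 4.69

    def test_priority_score_liver(self):
        s = priority_score(score1(116, 0, 117, 2851), math.log10(26.61))
        assert round(s, 2) == 5.88

    def test_zero_weights(self):
        assert priority_score(3.2, 1.1, 0.0, 0.0) == 0.0

    @given(
        se=st.integers(1, 99),
        sc=st.integers(0, 899),
        fold=st.floats(1.1, 100.0),
    )
    @settings(max_examples=200)
    def test_monotonicity(self, se, sc, fold):
        ne, nc = 100, 900
        base = priority_score(score1(se, sc, ne, nc), math.log10(fold))
        if se < ne:
            assert priority_score(score1(se + 1, sc, ne, nc), math.log10(fold)) > base
        assert priority_score(score1(se, sc + 1, ne, nc), math.log10(fold)) < base
        assert priority_score(score1(se, sc, ne, nc), math.log10(fold * 1.01)) > base


class TestScoreProbe:
    def test_fields_consistent(self, partition_10_90):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.uniform(3, 6, 10), rng.uniform(0, 0.5, 90)])
        calls = np.array(["P"] * 10 + ["A"] * 90)
        config = SelectivityConfig(theta=1.0, min_se=5, max_sc=0)
        res = score_probe(values, calls, partition_10_90, config, "x")
        assert res is not None
        assert res.Se == 10 and res.Sc == 0
        assert res.fold == pytest.approx(res.Ee / res.Ec)
        assert res.score == pytest.approx(res.score1 + res.score2)

    def test_filtered_out_returns_none(self, partition_10_90):
        values = np.ones(100)
        calls = np.full(100, "A")
        config = SelectivityConfig(theta=1.0, min_se=1, max_sc=0)
        assert score_probe(values, calls, partition_10_90, config, "x") is None

    def test_score2_nonpositive_dropped(self, partition_10_90):
        values = np.ones(100)
        calls = np.full(100, "P")
        config = SelectivityConfig(theta=1.0, min_se=1, max_sc=100)
        assert score_probe(values, calls, partition_10_90, config, "x") is None


class TestRankTissue:
    def test_planted_extreme_sole_result(self, small_compendium):
        config = SelectivityConfig(theta=1.0, min_se=2, max_sc=0)
        results = rank_tissue(small_compendium, "brain", config)
        assert [r.probe_id for r in results] == ["p1"]

    def test_min_se_above_ne_empty(self, small_compendium):
        config = SelectivityConfig(theta=1.0, min_se=4, max_sc=0)
        assert rank_tissue(small_compendium, "brain", config) == []

    def test_sorted_descending_with_id_ties(self, small_compendium):
        config = SelectivityConfig(theta=0.0, min_se=1, max_sc=3)
        results = rank_tissue(small_compendium, "brain", config)
        scores = [r.score for r in results]
        assert scores == sorted(scores, reverse=True)


class TestPermutation:
    def test_constant_row_p_one(self, partition_10_90):
        values = np.ones(100)
        calls = np.full(100, "P")
        config = SelectivityConfig(
            theta=0.5, min_se=1, max_sc=100, n_permutations=500, seed=1
        )
        actual = raw_priority_score(values, calls, partition_10_90, config)
        p, k = permutation_pvalue(
            values, calls, partition_10_90, actual, config, np.random.default_rng(0)
        )
        assert p == 1.0

    def test_planted_extreme_below_hypergeometric_bound(self, partition_10_90):
        # all 10 experiment samples high/Present, all 90 controls Absent:
        # a random 10-subset recovers the pattern w.p. 1/C(100,10) ~ 6e-14,
        # so 10,000 permutations should essentially never reach the score
        values = np.array([10.0] * 10 + [0.1] * 90)
        calls = np.array(["P"] * 10 + ["A"] * 90)
        config = SelectivityConfig(
            theta=1.0, min_se=5, max_sc=0, n_permutations=10_000, seed=3
        )
        res = score_probe(values, calls, partition_10_90, config, "x")
        p, k = permutation_pvalue(
            values, calls, partition_10_90, res.score, config, np.random.default_rng(3)
        )
        assert p < 10 / 10_000
        assert k == 0

    def test_determinism(self, partition_10_90):
        rng = np.random.default_rng(8)
        values = rng.lognormal(0, 1, 100)
        calls = rng.choice(["P", "A"], 100)
        config = SelectivityConfig(
            theta=1.0, min_se=1, max_sc=100, n_permutations=300, seed=5
        )
        actual = raw_priority_score(values, calls, partition_10_90, config)
        p1, _ = permutation_pvalue(
            values, calls, partition_10_90, actual, config, np.random.default_rng(5)
        )
        p2, _ = permutation_pvalue(
            values, calls, partition_10_90, actual, config, np.random.default_rng(5)
        )
        assert p1 == p2

    def test_attach_p_values(self, small_compendium):
        config = SelectivityConfig(
            theta=1.0, min_se=2, max_sc=0, n_permutations=200, seed=1
        )
        results = rank_tissue(small_compendium, "brain", config)
        attach_p_values(small_compendium, "brain", results, config)
        assert all(r.p_value is not None for r in results)
        assert all(0 <= r.p_value <= 1 for r in results)

    def test_attach_order_independent(self, small_compendium):
        config = SelectivityConfig(
            theta=0.0, min_se=1, max_sc=3, n_permutations=200, seed=1
        )
        results = rank_tissue(small_compendium, "brain", config)
        attach_p_values(small_compendium, "brain", results, config)
        by_id = {r.probe_id: r.p_value for r in results}
        results2 = list(reversed(rank_tissue(small_compendium, "brain", config)))
        attach_p_values(small_compendium, "brain", results2, config)
        assert {r.probe_id: r.p_value for r in results2} == by_id


class TestConfigValidation:
    def test_negative_theta(self):
        with pytest.raises(ValueError):
            SelectivityConfig(theta=-1.0)

    def test_zero_pseudocount(self):
        with pytest.raises(ValueError):
            SelectivityConfig(pseudocount=0.0)

    def test_min_se_zero(self):
        with pytest.raises(ValueError):
            SelectivityConfig(min_se=0)
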