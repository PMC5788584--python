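"""The two-criterion screen: median/ER conventions, t-test against the
textbook formula, Bonferroni handling, oracle equivalence on small
matrices, and the screen's invariance properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewingdx import (ScreenThresholds, ValidationError, log2_expression_ratios,
                     median_by_entity, pairwise_tests, two_criterion_screen,
                     volcano_table)

from _oracles import brute_force_screen, ttest_equal_variance_p
from conftest import make_matrix

REF = "Ewing sarcoma"


# a hand-built 3-gene, 3-entity toy: g1 passes both criteria, g2 only the
# ratio (huge spread kills the test), g3 only the test (ratio < 2)
TOY = {
    "g1": {REF: [10.0, 10.1, 9.9], "A": [5.0, 5.1, 4.9], "B": [5.0, 5.05, 4.95]},
    "g2": {REF: [12.0, 5.0, 13.0], "A": [5.0, 5.2, 4.8], "B": [5.0, 5.0, 5.0]},
    "g3": {REF: [6.0, 6.1, 5.9], "A": [5.0, 5.1, 4.9], "B": [5.0, 5.1, 4.9]},
}


class TestMedians:
    def test_median_conventions(self):
        matrix = make_matrix({
            "odd": {REF: [1.0, 2.0, 3.0], "A": [1.0, 2.0, 3.0, 10.0]},
            "flat": {REF: [7.0, 7.0, 7.0], "A": [7.0, 7.0, 7.0, 7.0]},
        })
        med = median_by_entity(matrix)
        assert med.at["odd", REF] == 2.0
        assert med.at["odd", "A"] == 2.5  # even count: mean of central pair
        assert (med.loc["flat"] == 7.0).all()


class TestExpressionRatios:
    def test_log2_difference_and_min(self):
        med = pd.DataFrame({REF: [10.0, 8.0], "A": [7.0, 8.0], "B": [9.0, 3.0]},
                           index=["g1", "g2"])
        er = log2_expression_ratios(med, REF)
        assert er.per_entity.at["g1", "A"] == 3.0
        assert er.per_entity.at["g2", "A"] == 0.0  # identical medians
        assert er.min_log2_er.tolist() == [1.0, 0.0]
        assert (er.min_log2_er <= er.per_entity.min(axis=1)).all()

    def test_antisymmetry_under_swap(self):
        med = pd.DataFrame({REF: [10.0], "A": [7.0]}, index=["g"])
        fwd = log2_expression_ratios(med, REF).per_entity.at["g", "A"]
        rev = log2_expression_ratios(med, "A").per_entity.at["g", REF]
        assert fwd == -rev

    def test_linear_scale_input(self):
        med = pd.DataFrame({REF: [1024.0], "A": [128.0]}, index=["g"])
        er = log2_expression_ratios(med, REF, input_scale="linear")
        assert er.per_entity.at["g", "A"] == pytest.approx(3.0)

    def test_missing_reference_rejected(self):
        med = pd.DataFrame({"A": [1.0]}, index=["g"])
        with pytest.raises(ValidationError, match="reference"):
            log2_expression_ratios(med, REF)


class TestPairwiseTests:
    def test_identical_groups_give_p_one(self):
        matrix = make_matrix({"g": {REF: [1.0, 2.0, 3.0], "A": [1.0, 2.0, 3.0]}})
        table = pairwise_tests(matrix, REF)
        assert table.raw.at["g", "A"] == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        matrix = make_matrix({"g": {REF: [1.0, 2.0, 3.0], "A": [4.0, 5.0, 6.0]}})
        table = pairwise_tests(matrix, REF)
        expected = ttest_equal_variance_p([1, 2, 3], [4, 5, 6])
        assert table.raw.at["g", "A"] == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_conventions(self):
        matrix = make_matrix({
            "same": {REF: [5.0, 5.0, 5.0], "A": [5.0, 5.0, 5.0]},
            "diff": {REF: [5.0, 5.0, 5.0], "A": [9.0, 9.0, 9.0]},
        })
        table = pairwise_tests(matrix, REF)
        assert table.raw.at["same", "A"] == 1.0
        assert table.raw.at["diff", "A"] == 0.0

    def test_bonferroni_adjustment_and_cap(self):
        matrix = make_matrix({
            f"g{i}": {REF: [1.0, 2.0, 3.0], "A": [1.0 + i, 2.0 + i, 3.0 + i]}
            for i in range(10)
        })
        table = pairwise_tests(matrix, REF)
        assert table.family_size == 10
        expected = np.minimum(1.0, table.raw["A"] * 10)
        assert np.allclose(table.adjusted["A"], expected)
        assert (table.adjusted["A"] <= 1.0).all()

    def test_family_policy_genes_times_entities(self):
        matrix = make_matrix({
            "g1": {REF: [1.0, 2.0], "A": [4.0, 5.0], "B": [2.0, 3.0]},
            "g2": {REF: [1.0, 2.0], "A": [1.0, 2.0], "B": [1.0, 2.0]},
        })
        table = pairwise_tests(matrix, REF, ScreenThresholds(
            family_policy="genes_times_entities"))
        assert table.family_size == 2 * 2


class TestScreen:
    def test_toy_matrix_gene_lists(self):
        matrix = make_matrix(TOY)
        result = two_criterion_screen(matrix, REF)
        assert result.er_pass == ["g1", "g2"]
        assert result.p_pass == ["g1", "g3"]
        assert result.intersection == ["g1"]

    def test_toy_matrix_matches_manual_computation(self):
        matrix = make_matrix(TOY)
        result = two_criterion_screen(matrix, REF)
        er_pass, p_pass, inter = brute_force_screen(TOY, REF)
        assert result.er_pass == er_pass
        assert result.p_pass == p_pass
        assert result.intersection == inter

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random_small_matrices(self, seed):
        """<= 10 genes, <= 4 entities: vectorized screen equals the
        explicit-loop reimplementation."""
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(2, 11))
        entities = [REF] + [f"E{i}" for i in range(int(rng.integers(1, 4)))]
        sizes = {e: int(rng.integers(2, 6)) for e in entities}
        values = {
            f"g{j}": {
                e: list(rng.normal(rng.uniform(4, 9), rng.uniform(0.1, 2.0),
                                   size=sizes[e]))
                for e in entities
            }
            for j in range(n_genes)
        }
        matrix = make_matrix(values)
        result = two_criterion_screen(matrix, REF)
        er_pass, p_pass, inter = brute_force_screen(values, REF)
        assert result.er_pass == er_pass
        assert result.p_pass == p_pass
        assert result.intersection == inter

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        values = {
            f"g{j}": {e: list(rng.normal(6 + (3 if e == REF and j % 3 == 0 else 0),
                                         0.8, size=4))
                      for e in (REF, "A", "B")}
            for j in range(12)
        }
        matrix = make_matrix(values)
        loose = two_criterion_screen(matrix, REF, ScreenThresholds(er_min=1.0,
                                                                   alpha=0.2))
        tight = two_criterion_screen(matrix, REF, ScreenThresholds(er_min=2.5,
                                                                   alpha=0.01))
        assert set(tight.er_pass) <= set(loose.er_pass)
        assert set(tight.p_pass) <= set(loose.p_pass)

    @given(shift=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_global_shift_invariance(self, shift):
        """Adding a constant to every value changes neither criterion."""
        matrix = make_matrix(TOY)
        shifted = make_matrix({
            g: {e: [v + shift for v in vals] for e, vals in ents.items()}
            for g, ents in TOY.items()
        })
        base = two_criterion_screen(matrix, REF)
        moved = two_criterion_screen(shifted, REF)
        assert base.er_pass == moved.er_pass
        assert base.p_pass == moved.p_pass
        assert np.allclose(base.er_table.min_log2_er, moved.er_table.min_log2_er)
        assert np.allclose(base.p_table.raw, moved.p_table.raw, rtol=1e-8)

    def test_intersection_is_set_intersection(self):
        matrix = make_matrix(TOY)
        result = two_criterion_screen(matrix, REF)
        assert set(result.intersection) == set(result.er_pass) & set(result.p_pass)


class TestVolcano:
    def test_flags_and_cross_check(self):
        matrix = make_matrix(TOY)
        result = two_criterion_screen(matrix, REF)
        table = volcano_table(result.er_table, result.p_table, "A")
        # flagged iff both thresholds cleared in this single comparison
        expected = (table["log2_er"] > 2.0) & (table["adjusted_p"] < 0.05)
        assert table["passes"].equals(expected)
        # a gene flagged in every comparison is exactly an intersection gene
        flagged_everywhere = set(table.index[table["passes"]])
        for entity in ("B",):
            t2 = volcano_table(result.er_table, result.p_table, entity)
            flagged_everywhere &= set(t2.index[t2["passes"]])
        assert flagged_everywhere == set(result.intersection)

    def test_unknown_entity_rejected(self):
        matrix = make_matrix(TOY)
        result = two_criterion_screen(matrix, REF)
        with pytest.raises(ValidationError, match="absent"):
            volcano_table(result.er_table, result.p_table, "Nope")
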