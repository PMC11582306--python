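"""Transition-matrix construction: values, labels, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rrbias import (
    BiasParams,
    DesignLayout,
    QuestionBlock,
    RandomizationSpec,
    append_cheater_column,
    asymmetric_2x2,
    build_design_matrix,
    everlastyear_matrix,
    identity_matrix,
    kronecker_chain,
    splastyear_matrix,
    subsamples_matrix,
    symmetric_2x2,
)


def _colsums_one(T):
    for b in np.unique(T.block_index):
        np.testing.assert_allclose(T.values[T.block_index == b].sum(axis=0), 1.0,
                                   atol=1e-12, rtol=0)


class TestSymmetric2x2:
    def test_warner_example(self):
        T = symmetric_2x2(RandomizationSpec(0.8))
        np.testing.assert_allclose(T.values, [[0.8, 0.2], [0.2, 0.8]])
        assert T.row_labels == ["n", "y"] and T.col_labels == ["n", "y"]

    def test_direct_questioning_is_identity(self):
        np.testing.assert_array_equal(symmetric_2x2(RandomizationSpec(1.0)).values, np.eye(2))

    def test_uninformative_design_flagged(self):
        rand = RandomizationSpec(0.5)
        assert rand.uninformative
        np.testing.assert_allclose(symmetric_2x2(rand).values, 0.5)
        assert not RandomizationSpec(0.8).uninformative

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.2])
    def test_invalid_probability_rejected(self, p):
        with pytest.raises(ValueError):
            RandomizationSpec(p)

    def test_asymmetric_general_form(self):
        T = asymmetric_2x2(0.8, 0.3)
        np.testing.assert_allclose(T.values, [[0.8, 0.3], [0.2, 0.7]])
        with pytest.raises(ValueError):
            asymmetric_2x2(0.5, 0.5)  # unidentified


class TestKronecker:
    def test_two_questions_entries_and_labels(self, rand08):
        T = kronecker_chain([symmetric_2x2(rand08)] * 2)
        assert T.row_labels == ["nn", "ny", "yn", "yy"]
        assert T.values[0, 0] == pytest.approx(0.64)  # p^2
        _colsums_one(T)

    def test_ely_times_single_shape(self, rand56):
        T = kronecker_chain([everlastyear_matrix(rand56), symmetric_2x2(rand56)])
        assert T.shape == (8, 6)
        _colsums_one(T)

    def test_identity_factor_leaves_variable_unrandomized(self, rand08):
        T = kronecker_chain([symmetric_2x2(rand08), identity_matrix(["a", "b", "c"])])
        assert T.shape == (6, 6)
        _colsums_one(T)
        # the non-randomized variable is never misclassified
        assert T.values[0, 1] == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            kronecker_chain([])


class TestSubsamples:
    def test_complementary_blocks(self, rand08):
        T = subsamples_matrix(rand08)
        np.testing.assert_allclose(T.values[:2], [[0.8, 0.2], [0.2, 0.8]])
        np.testing.assert_allclose(T.values[2:], [[0.2, 0.8], [0.8, 0.2]])
        assert list(T.block_index) == [0, 0, 1, 1]
        _colsums_one(T)

    def test_adherence_identity_for_any_truth(self, rng):
        T = subsamples_matrix(RandomizationSpec(0.75))
        for _ in range(5):
            pi_y = rng.uniform(0, 1)
            ps = T.values @ np.array([1 - pi_y, pi_y])
            assert ps[0] + ps[2] == pytest.approx(1.0)  # pi*_{n|1} + pi*_{n|2}

    def test_degenerate_at_half(self):
        T = subsamples_matrix(RandomizationSpec(0.5))
        np.testing.assert_allclose(T.values[:2], T.values[2:])


class TestEverLastYear:
    def test_lastyear_column(self, rand56):
        T = everlastyear_matrix(rand56)
        np.testing.assert_allclose(T.values[:, 2], [1 / 36, 5 / 36, 5 / 36, 25 / 36])
        assert T.col_labels == ["nn", "yn", "yy"]
        _colsums_one(T)

    def test_direct_questioning_makes_ny_impossible(self):
        T = everlastyear_matrix(RandomizationSpec(1.0))
        np.testing.assert_array_equal(T.values[1], 0.0)  # observed ny row


class TestCheaterColumn:
    def test_subsamples_indicator(self, rand08):
        T = append_cheater_column(subsamples_matrix(rand08))
        np.testing.assert_array_equal(T.values[:, 2], [1, 0, 1, 0])
        assert T.col_labels[-1] == "c"
        _colsums_one(T)

    def test_ely_indicator(self, rand56):
        T = append_cheater_column(everlastyear_matrix(rand56))
        np.testing.assert_array_equal(T.values[:, 3], [1, 0, 0, 0])
        _colsums_one(T)


class TestSpLastYear:
    def test_reduces_to_null_when_thetas_zero(self, rand56):
        T = splastyear_matrix(rand56, 0.0, 0.0)
        np.testing.assert_allclose(T.values, everlastyear_matrix(rand56).values)

    def test_reduces_to_spno_mixture_when_no_editing(self, rand56):
        theta = 0.12
        T = splastyear_matrix(rand56, theta, 0.0)
        base = everlastyear_matrix(rand56)
        e = np.array([1.0, 0, 0, 0])
        np.testing.assert_allclose(T.values, (1 - theta) * base.values + theta * e[:, None])

    def test_column_sums_with_both_parameters(self):
        T = splastyear_matrix(RandomizationSpec(5 / 6), 0.1, 0.2)
        np.testing.assert_allclose(T.values.sum(axis=0), 1.0, atol=1e-12)

    def test_editing_moves_yy_mass_to_yn(self, rand56):
        p = rand56.p
        T = splastyear_matrix(rand56, 0.0, 0.3)
        # last-year column: editors randomize normally but shift the yy
        # outcome to yn, so the yn entry gains exactly theta_e * p^2
        assert T.values[2, 2] == pytest.approx(p * (1 - p) + 0.3 * p * p)
        assert T.values[3, 2] == pytest.approx(0.7 * p * p)

    def test_inadmissible_weights_rejected(self, rand56):
        with pytest.raises(ValueError):
            splastyear_matrix(rand56, 0.6, 0.5)


class TestBuildDesignMatrix:
    def test_two_ely_sets_null(self, two_ely_layout):
        T = build_design_matrix(two_ely_layout)
        assert T.shape == (16, 9)
        _colsums_one(T)

    def test_ely_plus_question_cdm(self, ely_plus_q_layout):
        T = build_design_matrix(ely_plus_q_layout, bias_structure="cdm")
        assert T.shape == (8, 7)
        np.testing.assert_array_equal(T.values[:, -1], [1] + [0] * 7)

    def test_spno_theta_zero_equals_null(self, ely_plus_q_layout):
        T0 = build_design_matrix(ely_plus_q_layout)
        T1 = build_design_matrix(ely_plus_q_layout, BiasParams(theta=0.0),
                                 bias_structure="sp_no")
        np.testing.assert_allclose(T0.values, T1.values)

    def test_sply_without_ely_rejected(self, two_q_layout):
        with pytest.raises(ValueError):
            build_design_matrix(two_q_layout, BiasParams(theta_yy_yn=0.1),
                                bias_structure="sp_last_year")

    def test_sply_two_sets_symmetric_parameter(self, two_ely_layout):
        T = build_design_matrix(two_ely_layout, BiasParams(theta=0.05, theta_yy_yn=0.1),
                                bias_structure="sp_last_year")
        assert T.shape == (16, 9)
        _colsums_one(T)
        # the doubly-qualifying yyyy column loses editing mass twice
        jyy = T.col_labels.index("yyyy")
        p = 5 / 6
        base = build_design_matrix(two_ely_layout).values
        # adherent weight is 1 - theta - 2 theta_e in that column
        assert T.values[-1, jyy] == pytest.approx((1 - 0.05 - 0.2) * base[-1, jyy])

    def test_p4x4_row_label_order(self, rand08):
        T = kronecker_chain([symmetric_2x2(rand08)] * 2)
        assert T.row_labels == ["nn", "ny", "yn", "yy"]
        assert T.col_labels == ["nn", "ny", "yn", "yy"]


class TestLayoutValidation:
    def test_subsamples_needs_single_question(self, rand08):
        with pytest.raises(ValueError):
            DesignLayout([QuestionBlock("ever_last_year", rand08)], subsamples=True)

    def test_sply_structure_needs_ely(self, rand08):
        with pytest.raises(ValueError):
            DesignLayout([QuestionBlock("single", rand08)], bias_structure="sp_last_year")

    def test_question_names(self, ely_plus_q_layout):
        assert ely_plus_q_layout.question_names == ["q1_ever", "q1_last", "q2"]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(p=st.floats(0.55, 0.99), theta=st.floats(-0.2, 0.6),
       theta_e=st.floats(0.0, 0.35))
def test_all_structures_have_unit_column_sums(p, theta, theta_e):
    """Per-block column sums stay 1 and entries in [0,1] for admissible params."""
    if theta + theta_e > 1:
        theta_e = 1 - theta
    rand = RandomizationSpec(p)
    layout = DesignLayout([QuestionBlock("ever_last_year", rand),
                           QuestionBlock("single", rand)])
    for structure, bias in [("none", None), ("cdm", None),
                            ("sp_no", BiasParams(theta=max(theta, -0.2))),
                            ("sp_last_year", BiasParams(theta=max(theta, 0.0) / 2,
                                                        theta_yy_yn=theta_e / 2))]:
        T = build_design_matrix(layout, bias, bias_structure=structure)
        np.testing.assert_allclose(T.values.sum(axis=0), 1.0, atol=1e-10)
    sub = DesignLayout([QuestionBlock("single", rand)], subsamples=True)
    T = build_design_matrix(sub, bias_structure="cdm")
    for b in (0, 1):
        np.testing.assert_allclose(T.values[T.block_index == b].sum(axis=0), 1.0, atol=1e-12)
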