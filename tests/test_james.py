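"""James index: point estimate, components, and jackknife interval."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blindindex.james import (
    WeightScheme,
    james_jackknife_ci,
    james_point,
)
from blindindex.table import DegenerateDataError, GuessTable

from conftest import make_table


@st.composite
def nondegenerate_tables(draw, max_k=3, max_cell=40):
    k = draw(st.integers(2, max_k))
    rows = draw(
        st.lists(
            st.lists(st.integers(0, max_cell), min_size=k + 1, max_size=k + 1),
            min_size=k,
            max_size=k,
        )
    )
    arr = np.asarray(rows)
    # every arm answered at least once, and some disagreement mass exists
    if np.any(arr.sum(axis=1) < 1) or arr[:, :-1].sum() == 0:
        rng = np.random.default_rng(draw(st.integers(0, 2**16)))
        arr[:, :-1] += rng.integers(1, 4, size=(k, k))
    return make_table(arr, scale="ternary")


class TestPointEstimate:
    def test_random_guessing_scores_half(self, balanced_random):
        comp = james_point(balanced_random)
        assert comp.value == pytest.approx(0.5)
        assert comp.p_idk == 0.0

    def test_all_opposite_guessing_scores_one(self):
        comp = james_point(make_table([[0, 100, 0], [100, 0, 0]], scale="ternary"))
        assert comp.value == pytest.approx(1.0)

    def test_all_idk_is_undefined_by_default(self):
        comp = james_point(make_table([[0, 0, 100], [0, 0, 100]]))
        assert comp.undefined
        assert math.isnan(comp.value)
        assert comp.p_idk == 1.0

    def test_all_idk_convention_option_scores_one(self):
        comp = james_point(
            make_table([[0, 0, 100], [0, 0, 100]]), undefined_as_one=True
        )
        assert comp.undefined
        assert comp.value == 1.0

    def test_components_on_unbalanced_idk_table(self, unbalanced_idk):
        comp = james_point(unbalanced_idk)
        assert comp.p_idk == pytest.approx(0.28)
        assert comp.p_obs == pytest.approx(0.2083333333)
        assert comp.p_exp == pytest.approx(0.2083333333)
        assert comp.kappa == pytest.approx(0.0, abs=1e-12)
        assert comp.value == pytest.approx(0.64)

    def test_three_arm_generalization(self):
        t = make_table(
            [[41, 66, 30, 44], [27, 72, 24, 51], [22, 36, 64, 52]],
            scale="ternary",
        )
        assert james_point(t).value == pytest.approx(0.567, abs=5e-4)

    def test_likert_table_scored_on_collapsed_counts(self):
        lik = make_table([[38, 44, 21, 4, 170], [11, 16, 21, 8, 83]])
        tern = make_table([[82, 25, 170], [27, 29, 83]])
        assert james_point(lik).value == pytest.approx(james_point(tern).value)


class TestWeights:
    def test_default_matrix(self):
        w = WeightScheme().as_matrix(3)
        assert np.array_equal(w, [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])

    def test_out_of_range_weight_rejected(self):
        with pytest.raises(ValueError):
            WeightScheme(incorrect=1.5)

    def test_uniform_rescaling_of_weights_cancels(self, unbalanced_idk):
        # the kappa term is a ratio, so doubling every incorrect weight is a no-op
        doubled = WeightScheme(matrix=np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert james_point(unbalanced_idk, doubled).value == pytest.approx(
            james_point(unbalanced_idk).value
        )

    def test_asymmetric_matrix_changes_index(self, acupuncture):
        lopsided = WeightScheme(matrix=np.array([[0.0, 1.0], [0.25, 0.0]]))
        assert james_point(acupuncture, lopsided).value != pytest.approx(
            james_point(acupuncture).value
        )


class TestJackknife:
    def test_random_guess_interval(self, balanced_random):
        est = james_jackknife_ci(balanced_random)
        assert round(est.ci_low, 2) == 0.43
        assert round(est.ci_high, 2) == 0.57

    def test_large_trial_interval(self):
        est = james_jackknife_ci(make_table([[557, 427, 756], [418, 573, 764]]))
        assert est.value == pytest.approx(0.68, abs=5e-3)
        assert round(est.ci_low, 2) == 0.66
        assert round(est.ci_high, 2) == 0.69

    def test_constant_replicates_give_zero_width(self):
        est = james_jackknife_ci(make_table([[0, 100, 0], [100, 0, 0]], scale="ternary"))
        assert est.zero_width
        assert (est.ci_low, est.ci_high) == (1.0, 1.0)

    def test_interval_attached_to_point_not_jackknife_mean(self, unbalanced_idk):
        est = james_jackknife_ci(unbalanced_idk)
        point = james_point(unbalanced_idk).value
        assert (est.ci_low + est.ci_high) / 2 == pytest.approx(point)

    def test_grouped_equals_naive_leave_one_out(self, unbalanced_idk):
        """Cell-weighted jackknife == literal per-respondent loop (oracle)."""
        est = james_jackknife_ci(unbalanced_idk)
        counts = unbalanced_idk.counts
        n = counts.sum()
        loo = []
        for j in range(counts.shape[0]):
            for i in range(counts.shape[1]):
                for _ in range(counts[j, i]):  # one pass per respondent
                    reduced = counts.copy()
                    reduced[j, i] -= 1
                    t = GuessTable(
                        unbalanced_idk.arm_labels,
                        unbalanced_idk.guess_labels,
                        reduced,
                        "ternary",
                    )
                    loo.append(james_point(t).value)
        loo = np.asarray(loo)
        var = (n - 1) / n * ((loo - loo.mean()) ** 2).sum()
        assert est.se == pytest.approx(math.sqrt(var), rel=1e-12)


class TestProperties:
    @given(nondegenerate_tables())
    def test_index_in_unit_interval(self, t):
        try:
            comp = james_point(t)
        except DegenerateDataError:
            return
        if not comp.undefined:
            assert -1e-12 <= comp.value <= 1 + 1e-12

    @given(nondegenerate_tables(max_k=3))
    def test_simultaneous_arm_and_guess_permutation_invariance(self, t):
        perm = np.arange(t.k)[::-1]
        permuted = GuessTable(
            tuple(t.arm_labels[p] for p in perm),
            tuple(t.guess_labels[p] for p in perm),
            np.column_stack([t.treatment_counts[np.ix_(perm, perm)], t.idk_counts[perm]]),
            t.scale,
        )
        try:
            a, b = james_point(t), james_point(permuted)
        except DegenerateDataError:
            return
        if not a.undefined:
            assert b.value == pytest.approx(a.value, abs=1e-12)

    @given(nondegenerate_tables(max_k=2, max_cell=20), st.integers(2, 5))
    @settings(max_examples=25)
    def test_count_scaling_fixes_point_and_shrinks_se(self, t, c):
        try:
            base = james_jackknife_ci(t)
        except DegenerateDataError:
            return
        if not base.defined or base.se == 0:
            return
        scaled = james_jackknife_ci(
            GuessTable(t.arm_labels, t.guess_labels, t.counts * c, t.scale)
        )
        assert scaled.value == pytest.approx(base.value, abs=1e-12)
        assert scaled.se < base.se

    @given(nondegenerate_tables())
    def test_equal_observed_and_expected_reduce_to_idk_formula(self, t):
        """When P_O == P_E the index is exactly (1 + P_D) / 2."""
        try:
            comp = james_point(t)
        except DegenerateDataError:
            return
        if comp.undefined:
            return
        if math.isclose(comp.p_obs, comp.p_exp, abs_tol=1e-12):
            assert comp.value == pytest.approx((1 + comp.p_idk) / 2, abs=1e-12)
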