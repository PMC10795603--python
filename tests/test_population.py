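import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaconcord import (
    CSMFVector,
    PopulationComparison,
    chance_corrected_csmf_accuracy,
    csmf,
    csmf_accuracy,
    redistribution_matrix,
    spearman_rank_correlation,
)

from _oracles import oracle_csmf_accuracy
from conftest import make_cohort


def vec(cause_list, fractions, n=100, includes_undetermined=True):
    codes = cause_list.codes if includes_undetermined else cause_list.substantive_codes
    s = pd.Series(dict(zip(codes, fractions)), index=list(codes)).fillna(0.0)
    return CSMFVector(cause_list, s, n, includes_undetermined)


class TestCSMF:
    def test_uniform_toy_cohort(self, toy_cause_list):
        pairs = [("A", "A")] * 10 + [("B", "B")] * 10 + [("C", "C")] * 10
        v = csmf(make_cohort(pairs, toy_cause_list), "reference")
        assert v["A"] == v["B"] == v["C"] == pytest.approx(1 / 3)
        assert v["undet"] == 0.0

    def test_single_cause_degenerate_vector(self, toy_cause_list):
        v = csmf(make_cohort([("A", "A")] * 5, toy_cause_list), "reference")
        assert v["A"] == 1.0

    def test_undetermined_fraction_of_printed_cohort_shape(self, toy_cause_list):
        pairs = [("undet", "A")] * 852 + [("A", "A")] * (5386 - 852)
        v = csmf(make_cohort(pairs, toy_cause_list), "reference")
        assert v["undet"] == pytest.approx(0.158, abs=5e-4)

    def test_excluding_undetermined_renormalises(self, toy_cause_list):
        pairs = [("A", "undet")] * 5 + [("A", "B")] * 5
        v = csmf(make_cohort(pairs, toy_cause_list), "algo", include_undetermined=False)
        assert v["B"] == 1.0
        assert v.n == 5

    def test_empty_cohort_undefined(self, toy_cause_list):
        with pytest.raises(ValueError, match="empty"):
            csmf(make_cohort([], toy_cause_list), "reference")

    def test_fractions_must_sum_to_one(self, toy_cause_list):
        with pytest.raises(ValueError, match="sum to 1"):
            vec(toy_cause_list, [0.5, 0.2, 0.1, 0.0])


class TestCSMFAccuracy:
    def test_hand_worked_example(self, toy_cause_list):
        ref = vec(toy_cause_list, [0.5, 0.3, 0.2, 0.0])
        pred = vec(toy_cause_list, [0.4, 0.4, 0.2, 0.0])
        # sum|diff| = 0.2, denom = 2*(1-0) = 2 over the 4-component vector
        assert csmf_accuracy(ref, pred) == pytest.approx(1 - 0.2 / 2)

    def test_three_cause_closed_form(self, toy_cause_list):
        sub = toy_cause_list
        ref = vec(sub, [0.5, 0.3, 0.2], includes_undetermined=False)
        pred = vec(sub, [0.4, 0.4, 0.2], includes_undetermined=False)
        assert csmf_accuracy(ref, pred) == pytest.approx(1 - 0.2 / 1.6)

    def test_identical_vectors_score_one(self, toy_cause_list):
        ref = vec(toy_cause_list, [0.5, 0.3, 0.2, 0.0])
        assert csmf_accuracy(ref, ref) == 1.0

    def test_worst_case_scores_zero(self, toy_cause_list):
        ref = vec(toy_cause_list, [0.5, 0.3, 0.2], includes_undetermined=False)
        pred = vec(toy_cause_list, [0.0, 0.0, 1.0], includes_undetermined=False)
        assert csmf_accuracy(ref, pred) == pytest.approx(0.0, abs=1e-15)

    def test_convention_mismatch_rejected(self, toy_cause_list):
        ref = vec(toy_cause_list, [0.5, 0.3, 0.2, 0.0])
        pred = vec(toy_cause_list, [0.5, 0.3, 0.2], includes_undetermined=False)
        with pytest.raises(ValueError):
            csmf_accuracy(ref, pred)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=50)
    def test_bounds_and_oracle_on_random_simplex_points(self, toy_cause_list, seed):
        rng = np.random.default_rng(seed)
        t = rng.dirichlet(np.ones(3))
        p = rng.dirichlet(np.ones(3))
        ref = vec(toy_cause_list, t, includes_undetermined=False)
        pred = vec(toy_cause_list, p, includes_undetermined=False)
        acc = csmf_accuracy(ref, pred)
        assert acc == pytest.approx(oracle_csmf_accuracy(list(t), list(p)), abs=1e-12)
        assert 0.0 <= acc <= 1.0
        assert (acc == 1.0) == bool(np.allclose(t, p))


class TestChanceCorrected:
    def test_zero_point_is_the_chance_constant(self):
        assert chance_corrected_csmf_accuracy(0.632) == pytest.approx(0.0)

    def test_one_is_a_fixed_point(self):
        assert chance_corrected_csmf_accuracy(1.0) == pytest.approx(1.0)

    def test_worked_value(self):
        assert chance_corrected_csmf_accuracy(0.875) == pytest.approx(
            (0.875 - 0.632) / 0.368, abs=5e-4
        )

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True, max_examples=100)
    def test_strictly_increasing_affine_with_exact_inverse(self, a, b):
        fa, fb = chance_corrected_csmf_accuracy(a), chance_corrected_csmf_accuracy(b)
        if b - a > 1e-9:
            assert fa < fb
        inv = fa * (1 - 0.632) + 0.632
        assert inv == pytest.approx(a, abs=1e-12)


class TestSpearman:
    def test_tied_ranks_hand_example(self, toy_cause_list):
        # reference ranks (1,2,3); predicted has a tie -> ranks (1.5,1.5,3)
        ref = vec(toy_cause_list, [0.5, 0.3, 0.2], includes_undetermined=False)
        pred = vec(toy_cause_list, [0.4, 0.4, 0.2], includes_undetermined=False)
        rho = spearman_rank_correlation(ref, pred)
        assert rho.value == pytest.approx(1.5 / np.sqrt(3), abs=1e-12)

    def test_identical_vectors_give_one(self, toy_cause_list):
        ref = vec(toy_cause_list, [0.5, 0.3, 0.2], includes_undetermined=False)
        assert spearman_rank_correlation(ref, ref).value == pytest.approx(1.0)

    def test_reversed_ranking_gives_minus_one(self, toy_cause_list):
        ref = vec(toy_cause_list, [0.5, 0.3, 0.2], includes_undetermined=False)
        pred = vec(toy_cause_list, [0.2, 0.3, 0.5], includes_undetermined=False)
        assert spearman_rank_correlation(ref, pred).value == pytest.approx(-1.0)

    def test_all_equal_csmfs_undefined_not_zero(self, toy_cause_list):
        ref = vec(toy_cause_list, [0.5, 0.3, 0.2], includes_undetermined=False)
        flat = vec(toy_cause_list, [1 / 3] * 3, includes_undetermined=False)
        res = spearman_rank_correlation(ref, flat)
        assert not res.is_defined and "constant" in res.reason

    def test_matches_scipy_spearmanr(self, toy_cause_list):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.dirichlet(np.ones(3))
            p = rng.dirichlet(np.ones(3))
            ref = vec(toy_cause_list, t, includes_undetermined=False)
            pred = vec(toy_cause_list, p, includes_undetermined=False)
            ours = spearman_rank_correlation(ref, pred).value
            # scipy ranks ascending; rank-1-largest is the same correlation
            assert ours == pytest.approx(float(spearmanr(t, p).statistic), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_invariant_under_monotone_transform(self, toy_cause_list, seed):
        rng = np.random.default_rng(seed)
        t = rng.dirichlet(np.ones(3))
        p = rng.dirichlet(np.ones(3))
        squashed = np.sqrt(p) / np.sqrt(p).sum()  # strictly monotone in p
        ref = vec(toy_cause_list, t, includes_undetermined=False)
        r1 = spearman_rank_correlation(ref, vec(toy_cause_list, p, includes_undetermined=False))
        r2 = spearman_rank_correlation(ref, vec(toy_cause_list, squashed, includes_undetermined=False))
        assert r1.value == pytest.approx(r2.value, abs=1e-12)


class TestRedistribution:
    def test_all_to_one_cause(self, toy_cause_list):
        cohort = make_cohort([("undet", "A")] * 10, toy_cause_list)
        v = redistribution_matrix(cohort.reference_undetermined_subset(), "algo")
        assert v["A"] == 1.0

    def test_mirroring_coder_keeps_undetermined(self, toy_cause_list):
        cohort = make_cohort([("undet", "undet")] * 10, toy_cause_list)
        v = redistribution_matrix(cohort.reference_undetermined_subset(), "algo")
        assert v["undet"] == 1.0

    def test_fraction_counts(self, toy_cause_list):
        pairs = [("undet", "undet")] * 48 + [("undet", "A")] * 30 + [("undet", "B")] * 22
        cohort = make_cohort(pairs, toy_cause_list)
        v = redistribution_matrix(cohort.reference_undetermined_subset(), "algo")
        assert v["undet"] == pytest.approx(0.48)
        assert float(v.fractions.sum()) == pytest.approx(1.0)

    def test_rejects_non_undetermined_input(self, toy_cause_list):
        cohort = make_cohort([("A", "B")], toy_cause_list)
        with pytest.raises(ValueError, match="reference-undetermined"):
            redistribution_matrix(cohort, "algo")

    def test_empty_subset_undefined(self, toy_cause_list):
        cohort = make_cohort([("A", "B")], toy_cause_list)
        with pytest.raises(ValueError, match="empty"):
            redistribution_matrix(cohort.reference_undetermined_subset(), "algo")


class TestPopulationComparison:
    def test_bundle_consistency(self, toy_cause_list):
        ref = vec(toy_cause_list, [0.5, 0.3, 0.2], includes_undetermined=False)
        pred = vec(toy_cause_list, [0.4, 0.4, 0.2], includes_undetermined=False)
        comp = PopulationComparison(ref, pred)
        assert comp.csmf_accuracy == pytest.approx(0.875)
        assert comp.chance_corrected == pytest.approx((0.875 - 0.632) / 0.368)
        assert list(comp.ranks_reference) == [1, 2, 3]
        assert list(comp.ranks_predicted) == [1.5, 1.5, 3]
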