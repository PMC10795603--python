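import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaconcord import (
    UnsupportedCoderError,
    build_confusion,
    ccc,
    cohens_kappa,
    interpret_kappa,
    mean_ccc,
    overall_agreement,
    ppv,
    proportion_ci,
    sensitivity,
)

from _oracles import oracle_kappa, oracle_overall_agreement
from conftest import make_cohort, random_pairs


@pytest.fixture(scope="module")
def toy_table(toy_cohort):
    return build_confusion(toy_cohort, "algo")


class TestBuildConfusion:
    def test_toy_tallies(self, toy_table):
        assert toy_table.n == 30
        assert [toy_table.tp(c) for c in "ABC"] == [8, 6, 8]
        assert toy_table.fp("B") == 3
        assert toy_table.fn("A") == 2

    def test_perfect_coder_is_diagonal(self, toy_cause_list):
        cohort = make_cohort([("A", "A")] * 4 + [("B", "B")] * 2, toy_cause_list)
        table = build_confusion(cohort, "algo")
        counts = table.counts
        off_diag = counts.to_numpy().sum() - np.trace(
            counts.loc[["A", "B", "C"], ["A", "B", "C"]].to_numpy()
        )
        assert off_diag == 0

    def test_empty_cohort_gives_zero_table(self, toy_cause_list):
        table = build_confusion(make_cohort([], toy_cause_list), "algo")
        assert table.n == 0

    def test_unknown_coder_rejected(self, toy_cohort):
        with pytest.raises(KeyError, match="unknown coder"):
            build_confusion(toy_cohort, "nope")

    def test_reference_undetermined_must_be_excluded_first(self, toy_cause_list):
        cohort = make_cohort([("undet", "A"), ("A", "A")], toy_cause_list)
        with pytest.raises(ValueError, match="exclude_reference_undetermined"):
            build_confusion(cohort, "algo")

    def test_coder_undetermined_kept_as_column(self, toy_cause_list):
        cohort = make_cohort([("A", "undet"), ("A", "A")], toy_cause_list)
        table = build_confusion(cohort, "algo")
        assert table.counts.at["A", "undet"] == 1
        assert "undet" not in table.counts.index


class TestPPVSensitivity:
    def test_toy_values(self, toy_table):
        assert ppv(toy_table, "B").value == pytest.approx(6 / 9)
        assert sensitivity(toy_table, "A").value == pytest.approx(0.8)
        assert sensitivity(toy_table, "B").value == pytest.approx(0.6)

    def test_never_predicted_cause_is_undefined_not_zero(self, toy_cause_list):
        cohort = make_cohort([("A", "B"), ("B", "B")], toy_cause_list)
        table = build_confusion(cohort, "algo")
        res = ppv(table, "C")
        assert not res.is_defined and res.reason is not None

    def test_no_reference_deaths_gives_undefined_sensitivity(self, toy_cause_list):
        cohort = make_cohort([("A", "A")], toy_cause_list)
        res = sensitivity(build_confusion(cohort, "algo"), "C")
        assert not res.is_defined

    def test_always_wrong_coder_has_zero_sensitivity(self, toy_cause_list):
        cohort = make_cohort([("A", "B")] * 5, toy_cause_list)
        assert sensitivity(build_confusion(cohort, "algo"), "A").value == 0.0


class TestProportionCI:
    def test_wald_interval_truncated(self):
        low, high = proportion_ci(8, 10)
        assert low == pytest.approx(0.8 - 1.96 * np.sqrt(0.8 * 0.2 / 10), abs=1e-3)
        assert high == 1.0  # 0.8 + 0.248 truncates

    def test_boundary_truncation(self):
        assert proportion_ci(0, 7)[0] == 0.0
        assert proportion_ci(7, 7)[1] == 1.0

    def test_wilson_option_stays_inside(self):
        low, high = proportion_ci(8, 10, method="wilson")
        assert 0.0 < low < 0.8 < high < 1.0

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(0, 0)


class TestCCC:
    def test_closed_form(self, toy_table):
        assert ccc(toy_table, "A", C=3).value == pytest.approx(0.7)
        assert ccc(toy_table, "B", C=3).value == pytest.approx(0.4)

    def test_chance_level_scores_zero(self, toy_cause_list):
        # sensitivity exactly 1/C: 1 hit of 3 reference deaths, C=3
        cohort = make_cohort([("A", "A"), ("A", "B"), ("A", "C")], toy_cause_list)
        assert ccc(build_confusion(cohort, "algo"), "A", C=3).value == pytest.approx(0.0)

    def test_zero_sensitivity_floor(self, toy_cause_list):
        cohort = make_cohort([("A", "B")] * 4, toy_cause_list)
        res = ccc(build_confusion(cohort, "algo"), "A", C=25)
        assert res.value == pytest.approx(-1 / 24)

    def test_mean_over_eligible_causes(self, toy_table):
        assert mean_ccc(toy_table, C=3).value == pytest.approx(0.6)

    def test_perfect_coder_scores_one(self, toy_cause_list):
        cohort = make_cohort([("A", "A")] * 3 + [("B", "B")] * 3, toy_cause_list)
        assert mean_ccc(build_confusion(cohort, "algo"), C=3).value == pytest.approx(1.0)

    def test_single_cause_perfect_degenerate_mean(self, toy_cause_list):
        cohort = make_cohort([("A", "A")] * 5, toy_cause_list)
        assert mean_ccc(build_confusion(cohort, "algo"), C=3).value == pytest.approx(1.0)


class TestOverallAgreement:
    def test_toy_top1(self, toy_cohort):
        res = overall_agreement(toy_cohort, "algo", top_k=1)
        assert res.value == pytest.approx(22 / 30)

    def test_rank2_reference_scores_zero_then_one(self, toy_cause_list):
        pairs = [("A", "B")] * 6
        cohort = make_cohort(
            pairs,
            toy_cause_list,
            extra_cols={
                "algo_rank1": ["B"] * 6,
                "algo_rank2": ["A"] * 6,
                "algo_rank3": ["C"] * 6,
            },
        )
        assert overall_agreement(cohort, "algo", 1).value == 0.0
        assert overall_agreement(cohort, "algo", 3).value == 1.0

    def test_identical_coders_agree_everywhere(self, toy_cause_list):
        pairs = [("A", "A"), ("B", "B")] * 3
        cohort = make_cohort(
            pairs,
            toy_cause_list,
            extra_cols={
                "algo_rank1": [p[0] for p in pairs],
                "algo_rank2": ["C"] * 6,
                "algo_rank3": ["B" if p[0] != "B" else "A" for p in pairs],
            },
        )
        assert overall_agreement(cohort, "algo", 1).value == 1.0
        assert overall_agreement(cohort, "algo", 3).value == 1.0

    def test_single_cause_coder_rejected_for_top3(self, toy_cohort):
        with pytest.raises(UnsupportedCoderError):
            overall_agreement(toy_cohort, "algo", top_k=3)


class TestCohensKappa:
    def test_toy_breakdown(self, toy_table):
        res, breakdown = cohens_kappa(toy_table)
        assert breakdown.p_o == pytest.approx(22 / 30, abs=1e-12)
        assert breakdown.p_e == pytest.approx(1 / 3, abs=1e-12)
        assert res.value == pytest.approx(0.6, abs=1e-12)

    def test_identical_assignments_score_one(self, toy_cause_list):
        cohort = make_cohort([("A", "A")] * 3 + [("B", "B")] * 7, toy_cause_list)
        res, _ = cohens_kappa(build_confusion(cohort, "algo"))
        assert res.value == pytest.approx(1.0)

    def test_independent_coder_with_matched_marginals_near_zero(self, toy_cause_list):
        """Large-sample simulation: independent assignment drives kappa to 0."""
        rng = np.random.default_rng(11)
        p = [0.5, 0.3, 0.2]
        refs = rng.choice(list("ABC"), size=20000, p=p)
        coders = rng.choice(list("ABC"), size=20000, p=p)  # independent
        cohort = make_cohort(list(zip(refs, coders)), toy_cause_list)
        res, _ = cohens_kappa(build_confusion(cohort, "algo"))
        assert abs(res.value) < 0.02

    def test_matches_statsmodels_on_random_tables(self, toy_cause_list):
        """Independent library cross-check of the value and its SE."""
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        rng = np.random.default_rng(5)
        for _ in range(20):
            pairs = random_pairs(rng, list("ABC"), n=60)
            table = build_confusion(make_cohort(pairs, toy_cause_list), "algo")
            square = table.counts.loc[:, ["A", "B", "C"]].to_numpy()
            sm = sm_kappa(square, return_results=True)
            ours, _ = cohens_kappa(table)
            assert ours.value == pytest.approx(float(sm.kappa), abs=1e-12)
            half_width = ours.value - ours.ci_low
            # statsmodels truncates CIs to [-1, 1] too; compare untruncated widths
            assert half_width == pytest.approx(
                min(1.96 * float(np.sqrt(sm.var_kappa)), ours.value + 1), abs=2e-3
            )

    def test_brute_force_oracle_equivalence(self, toy_cause_list):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pairs = random_pairs(rng, list("ABC"))
            table = build_confusion(make_cohort(pairs, toy_cause_list), "algo")
            expected = oracle_kappa(pairs, ["A", "B", "C", "undet"])
            res, _ = cohens_kappa(table)
            assert res.value == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self, toy_cause_list, toy_pairs):
        """Kappa is unchanged by relabelling the cause axis."""
        perm = {"A": "C", "B": "A", "C": "B"}
        permuted = [(perm[r], perm[c]) for r, c in toy_pairs]
        k1, _ = cohens_kappa(build_confusion(make_cohort(toy_pairs, toy_cause_list), "algo"))
        k2, _ = cohens_kappa(build_confusion(make_cohort(permuted, toy_cause_list), "algo"))
        assert k1.value == pytest.approx(k2.value, abs=1e-12)


class TestInvariants:
    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_micro_identity_and_ranges(self, toy_cause_list, seed):
        """Sum_j TP_j / N equals top-1 overall agreement; metric ranges hold."""
        rng = np.random.default_rng(seed)
        pairs = random_pairs(rng, list("ABC"))
        cohort = make_cohort(pairs, toy_cause_list)
        table = build_confusion(cohort, "algo")
        micro = sum(table.tp(c) for c in "ABC") / table.n
        assert overall_agreement(cohort, "algo", 1).value == pytest.approx(micro, abs=1e-15)
        assert micro == pytest.approx(oracle_overall_agreement(pairs), abs=1e-15)
        for c in "ABC":
            for metric in (ppv, sensitivity):
                r = metric(table, c)
                assert r.value is None or 0.0 <= r.value <= 1.0
            r = ccc(table, c, C=3)
            assert r.value is None or -0.5 - 1e-12 <= r.value <= 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_csmf_weighted_sensitivity_equals_p_o(self, toy_cause_list, seed):
        """Algebraic identity: reference-CSMF-weighted sensitivity is p_o."""
        rng = np.random.default_rng(seed)
        pairs = random_pairs(rng, list("ABC"))
        table = build_confusion(make_cohort(pairs, toy_cause_list), "algo")
        total = 0.0
        for c in "ABC":
            s = sensitivity(table, c)
            if s.is_defined:
                total += (table.row_total(c) / table.n) * s.value
        _, breakdown = cohens_kappa(table)
        assert total == pytest.approx(breakdown.p_o, abs=1e-12)


class TestInterpretKappa:
    @pytest.mark.parametrize(
        ("kappa", "label"),
        [
            (-1.0, "None"),
            (-0.05, "None"),
            (0.20, "None"),
            (0.21, "Minimal"),
            (0.39, "Minimal"),
            (0.40, "Weak"),
            (0.45, "Weak"),
            (0.59, "Weak"),
            (0.60, "Moderate"),
            (0.79, "Moderate"),
            (0.80, "Strong"),
            (0.90, "Strong"),
            (0.91, "Almost Perfect"),
            (1.0, "Almost Perfect"),
        ],
    )
    def test_bands(self, kappa, label):
        assert interpret_kappa(kappa) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)
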