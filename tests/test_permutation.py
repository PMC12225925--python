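"""Paired permutation test: statistics, null schemes, p-values, effect sizes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beefield.permutation import (
    PairedTrial,
    distribution_diagnostics,
    effect_size,
    exhaustive_signflip_null,
    median_reduction,
    null_summary,
    observed_statistic,
    p_value,
    paired_permutation_test,
    permutation_null,
)
from conftest import make_pairs


class TestObservedStatistic:
    @pytest.mark.parametrize(
        "controls, treatments, expected",
        [
            ([5, 3], [5, 3], 0.0),  # identical pairs
            ([5, 4, 6], [2, 1, 3], 3.0),  # hand arithmetic
            ([10], [2], 8.0),
        ],
    )
    def test_mean_of_control_minus_treatment(self, controls, treatments, expected):
        assert observed_statistic(make_pairs(controls, treatments)) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            observed_statistic([])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            PairedTrial(0, -1, 5)


class TestNullDistribution:
    def test_exhaustive_enumeration_matches_brute_force(self):
        # differences {3,3,3}: the 8 sign-assignment means
        pairs = make_pairs([6, 6, 6], [3, 3, 3])
        null = np.sort(exhaustive_signflip_null(pairs))
        assert null.tolist() == [-3, -1, -1, -1, 1, 1, 1, 3]
        assert null.mean() == 0.0

    def test_zero_differences_give_degenerate_null(self):
        pairs = make_pairs([4, 7, 2], [4, 7, 2])
        assert np.all(permutation_null(pairs, 200, "signflip", seed=1) == 0.0)
        assert np.all(exhaustive_signflip_null(pairs) == 0.0)

    @pytest.mark.parametrize("scheme", ["signflip", "full_relabel"])
    def test_deterministic_under_fixed_seed(self, poisson_pairs, scheme):
        a = permutation_null(poisson_pairs, 500, scheme=scheme, seed=42)
        b = permutation_null(poisson_pairs, 500, scheme=scheme, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_unknown_scheme_lists_valid_ones(self, poisson_pairs):
        with pytest.raises(ValueError, match="signflip.*full_relabel"):
            permutation_null(poisson_pairs, 10, scheme="bootstrap")

    def test_full_relabel_preserves_pooled_counts(self, poisson_pairs):
        # each relabelled statistic is expressible from a subset of the
        # pooled counts; its null mean is ~0 by symmetry
        null = permutation_null(poisson_pairs, 4000, "full_relabel", seed=3)
        assert abs(null.mean()) < 0.5


class TestPValue:
    def test_observed_zero_ties_with_everything(self, poisson_pairs):
        null = permutation_null(poisson_pairs, 100, seed=0)
        assert p_value(0.0, null) == 1.0

    def test_enumeration_oracle_three_equal_differences(self):
        pairs = make_pairs([6, 6, 6], [3, 3, 3])
        null = exhaustive_signflip_null(pairs)
        assert p_value(3.0, null) == pytest.approx(2 / 8)

    def test_invariant_to_trial_order(self, poisson_pairs, rng):
        obs = observed_statistic(poisson_pairs)
        p1 = p_value(obs, exhaustive_signflip_null(poisson_pairs))
        shuffled = list(poisson_pairs)
        rng.shuffle(shuffled)
        p2 = p_value(observed_statistic(shuffled), exhaustive_signflip_null(shuffled))
        assert p1 == p2

    def test_label_swap_negates_statistic_and_keeps_p(self, poisson_pairs):
        swapped = [
            PairedTrial(p.trial_id, p.control_count, p.treatment_count)
            for p in poisson_pairs
        ]
        assert observed_statistic(swapped) == -observed_statistic(poisson_pairs)
        p_orig = p_value(
            observed_statistic(poisson_pairs), exhaustive_signflip_null(poisson_pairs)
        )
        p_swap = p_value(
            observed_statistic(swapped), exhaustive_signflip_null(swapped)
        )
        assert p_orig == p_swap

    def test_smallest_attainable_two_sided_p_at_n8(self, rng):
        # no zero differences: the extreme arrangement and its mirror
        c = rng.integers(10, 20, size=8)
        pairs = make_pairs(c, c - rng.integers(1, 5, size=8))
        null = exhaustive_signflip_null(pairs)
        p_min = min(p_value(v, null) for v in np.unique(np.abs(null)))
        assert p_min == pytest.approx(2 / 256)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        diffs=st.lists(st.integers(min_value=-15, max_value=15), min_size=2, max_size=9)
    )
    def test_monte_carlo_agrees_with_enumeration(self, diffs):
        pairs = make_pairs([max(d, 0) + 5 for d in diffs], [5 - min(d, 0) for d in diffs])
        obs = observed_statistic(pairs)
        p_exact = p_value(obs, exhaustive_signflip_null(pairs))
        p_mc = p_value(obs, permutation_null(pairs, 4000, "signflip", seed=7))
        tol = 3 * np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(p_mc - p_exact) <= tol + 1e-12


class TestSummariesAndEffects:
    def test_null_summary_degenerate(self):
        mean, sd, (lo, hi) = null_summary(np.zeros(50))
        assert (mean, sd, lo, hi) == (0.0, 0.0, 0.0, 0.0)

    def test_null_summary_hand_values(self):
        mean, sd, _ = null_summary(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert mean == 0.0
        assert sd == pytest.approx(np.sqrt(2.5))

    def test_null_interval_ordering(self, poisson_pairs):
        _, _, (lo, hi) = null_summary(permutation_null(poisson_pairs, 2000, seed=5))
        assert lo <= hi

    @pytest.mark.parametrize(
        "observed, null_sd, expected",
        # the printed (difference, null SD, d) triplets of the study this
        # pipeline reproduces, as an arithmetic consistency check
        [(8.25, 3.01, 2.74), (6.75, 2.57, 2.63), (-0.63, 0.72, -0.875)],
    )
    def test_null_sd_effect_size_reproduces_triplets(self, observed, null_sd, expected):
        assert effect_size(observed, null_sd=null_sd) == pytest.approx(expected, abs=0.005)

    def test_zero_observed_is_zero_effect(self):
        assert effect_size(0.0, null_sd=2.0) == 0.0
        assert effect_size(0.0, pairs=make_pairs([3, 3], [3, 3]), kind="classical") == 0.0

    def test_classical_paired_d(self):
        pairs = make_pairs([2, 4, 6], [1, 2, 3])  # differences {1,2,3}
        assert effect_size(None, pairs=pairs, kind="classical") == pytest.approx(2.0)

    def test_degenerate_denominators_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            effect_size(1.0, null_sd=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            effect_size(None, pairs=make_pairs([5, 5], [2, 2]), kind="classical")

    @pytest.mark.parametrize(
        "controls, treatments, expected",
        [([4, 5, 6], [4, 5, 6], 0.0), ([4, 5, 6], [1, 2, 3], 60.0)],
    )
    def test_median_reduction(self, controls, treatments, expected):
        assert median_reduction(make_pairs(controls, treatments)) == expected

    def test_median_reduction_zero_control_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            median_reduction(make_pairs([0, 0, 0], [1, 1, 1]))


class TestFullTest:
    def test_result_record_is_complete_and_consistent(self, poisson_pairs):
        res = paired_permutation_test(poisson_pairs, 2000, seed=11)
        assert res.n_pairs == 8
        assert res.n_permutations == 2000
        assert 0 <= res.p_value <= 1
        assert res.null_interval[0] <= res.null_interval[1]
        assert res.effect_size == pytest.approx(res.observed_difference / res.null_sd)
        d = res.to_dict()
        assert set(d) >= {
            "observed_difference", "p_value", "null_mean", "null_sd",
            "null_interval", "effect_size", "n_permutations", "scheme", "seed",
        }

    def test_exact_mode_uses_full_enumeration(self, poisson_pairs):
        res = paired_permutation_test(poisson_pairs, exact=True)
        assert res.n_permutations == 256
        with pytest.raises(ValueError, match="signflip"):
            paired_permutation_test(poisson_pairs, scheme="full_relabel", exact=True)


class TestDiagnostics:
    def test_too_few_pairs_is_advisory(self):
        report = distribution_diagnostics(make_pairs([3, 4], [1, 2]))
        assert report.shapiro_p is None
        assert any("not computed" in n for n in report.notes)

    def test_constant_differences_flagged_degenerate(self):
        report = distribution_diagnostics(make_pairs([5, 6, 7], [2, 3, 4]))
        assert report.shapiro_p is None
        assert any("degenerate" in n for n in report.notes)
        assert report.levene_p is not None  # groups still have spread

    def test_identical_groups_flagged_degenerate(self):
        report = distribution_diagnostics(make_pairs([5, 5, 5], [5, 5, 5]))
        assert any("degenerate" in n for n in report.notes)
        assert report.levene_p is None

    def test_normality_test_type_i_error_near_nominal(self, rng):
        # Normal(0,1) differences, n=50: Shapiro-Wilk should reject ~5%
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(size=50)
            pairs = make_pairs(np.round(x * 10 + 100).astype(int), np.full(50, 100))
            report = distribution_diagnostics(pairs)
            rejections += report.shapiro_p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.08
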