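"""Unit and property tests for the correlation statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qcc import (
    PairedReplicates,
    analytic_expected_pcc,
    evaluate_merge_candidates,
    initial_quantization,
    joint_contingency,
    pearson_correlation,
    pearson_from_contingency,
    qcc,
    quantize_equal_count,
    spearman_correlation,
)
from qcc.exceptions import DataError, ParameterError, UndefinedCorrelationError

from conftest import (
    expand_table,
    naive_contingency,
    naive_greedy_qcc,
    naive_quantize,
    random_pair,
)


class TestPairedReplicates:
    def test_rejects_length_mismatch_short_and_nonfinite(self):
        with pytest.raises(DataError):
            PairedReplicates([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(DataError):
            PairedReplicates([1.0], [2.0])
        with pytest.raises(DataError):
            PairedReplicates([1.0, np.nan], [1.0, 2.0])

    def test_swapped_exchanges_replicates(self):
        pair = PairedReplicates([1.0, 2.0, 3.0], [4.0, 5.0, 7.0])
        np.testing.assert_array_equal(pair.swapped().values_x, pair.values_y)


class TestPlainCorrelations:
    def test_identity_gives_one(self):
        x = np.array([0.3, -1.2, 2.5, 0.0])
        assert pearson_correlation(PairedReplicates(x, x)) == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # direct evaluation of the sample-correlation formula on 4 points
        pair = PairedReplicates([1, 2, 3, 4], [1, 2, 3, 5])
        assert pearson_correlation(pair) == pytest.approx(
            0.9827076298239908, abs=1e-12
        )

    def test_constant_vector_raises(self):
        pair = PairedReplicates([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation(pair)
        with pytest.raises(UndefinedCorrelationError):
            spearman_correlation(pair)

    def test_pearson_affine_invariance_and_symmetry(self, rng):
        x, y = random_pair(rng, 200)
        pair = PairedReplicates(x, y)
        r = pearson_correlation(pair)
        assert pearson_correlation(pair.swapped()) == pytest.approx(r, abs=1e-12)
        scaled = PairedReplicates(3.0 * x + 7.0, y)
        assert pearson_correlation(scaled) == pytest.approx(r, abs=1e-10)

    def test_spearman_is_one_for_monotone_transform(self, rng):
        x = rng.normal(size=100)
        pair = PairedReplicates(x, np.exp(x))
        assert spearman_correlation(pair) == pytest.approx(1.0)

    def test_spearman_equals_pearson_on_ranks_when_tie_free(self, rng):
        x, y = random_pair(rng, 150)
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        expected = pearson_correlation(PairedReplicates(rx, ry))
        assert spearman_correlation(PairedReplicates(x, y)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_spearman_average_rank_convention_on_ties(self):
        # ranks of (1,1,2) are (1.5, 1.5, 3); Pearson vs (1,2,3) = sqrt(3)/2
        pair = PairedReplicates([1.0, 1.0, 2.0], [3.0, 5.0, 9.0])
        assert spearman_correlation(pair) == pytest.approx(
            math.sqrt(3) / 2, abs=1e-12
        )


class TestQuantize:
    def test_one_probe_per_bin_recovers_ranks(self, rng):
        x = rng.permutation(10).astype(float)
        labels = quantize_equal_count(x, 10)
        np.testing.assert_array_equal(labels, np.argsort(np.argsort(x)) + 1)

    def test_exact_equal_sizes_when_divisible(self, rng):
        labels = quantize_equal_count(rng.normal(size=3000), 100)
        sizes = np.bincount(labels)[1:]
        assert (sizes == 30).all()
        assert labels.min() == 1 and labels.max() == 100

    def test_sizes_differ_by_at_most_one(self, rng):
        labels = quantize_equal_count(rng.normal(size=103), 10)
        sizes = np.bincount(labels)[1:]
        assert sizes.min() >= 1 and sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 103

    def test_smallest_values_get_bin_one(self):
        labels = quantize_equal_count([10.0, -5.0, 3.0, 7.0], 2)
        np.testing.assert_array_equal(labels, [2, 1, 1, 2])

    def test_stable_tie_rule_on_seven_points(self):
        # sorted (stable): 1@i1, 1@i2, 2@i6 | 3@i3, 3@i4 | 3@i5, 5@i0
        labels = quantize_equal_count([5.0, 1.0, 1.0, 3.0, 3.0, 3.0, 2.0], 3)
        np.testing.assert_array_equal(labels, [3, 1, 1, 2, 2, 3, 1])

    def test_matches_naive_block_assignment(self, rng):
        for n, b in [(17, 3), (50, 7), (64, 8), (100, 10)]:
            x = rng.normal(size=n).round(1)  # induce ties
            np.testing.assert_array_equal(
                quantize_equal_count(x, b), naive_quantize(x, b)
            )

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            quantize_equal_count([1.0, 2.0, 3.0], 4)
        with pytest.raises(ParameterError):
            quantize_equal_count([1.0, 2.0, 3.0], 1)


class TestContingency:
    def test_small_example(self):
        table = joint_contingency([1, 2, 2], [1, 2, 2], 2)
        np.testing.assert_array_equal(table, [[1, 0], [0, 2]])

    def test_matches_nested_loop_oracle_and_marginals(self, rng):
        B = 4
        lx = rng.integers(1, B + 1, size=60)
        ly = rng.integers(1, B + 1, size=60)
        table = joint_contingency(lx, ly, B)
        np.testing.assert_array_equal(table, naive_contingency(lx, ly, B))
        np.testing.assert_array_equal(table.sum(axis=1), np.bincount(lx)[1:])
        np.testing.assert_array_equal(table.sum(axis=0), np.bincount(ly)[1:])
        assert table.sum() == 60

    def test_label_out_of_range_raises(self):
        with pytest.raises(DataError):
            joint_contingency([1, 3], [1, 2], 2)

    def test_diagonal_gives_one_antidiagonal_minus_one(self):
        assert pearson_from_contingency(np.diag([3, 5, 2])) == pytest.approx(1.0)
        assert pearson_from_contingency([[0, 4], [6, 0]]) == pytest.approx(-1.0)

    def test_matches_expanded_vector_pearson(self, rng):
        table = rng.integers(0, 6, size=(4, 4))
        table[0, 0] += 1  # ensure a defined, non-trivial table
        table[3, 3] += 1
        xs, ys = expand_table(table)
        expected = pearson_correlation(PairedReplicates(xs, ys))
        assert pearson_from_contingency(table) == pytest.approx(expected, abs=1e-10)

    def test_degenerate_margin_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_from_contingency([[3, 4], [0, 0]])


class TestMergeCandidates:
    def test_candidate_count_is_b_minus_one(self, rng):
        x, y = random_pair(rng, 90)
        state = initial_quantization(PairedReplicates(x, y), 3)
        assert len(evaluate_merge_candidates(state)) == 2

    def test_no_candidates_below_three_bins(self, rng):
        x, y = random_pair(rng, 40)
        state = initial_quantization(PairedReplicates(x, y), 2)
        assert evaluate_merge_candidates(state) == []

    def test_each_candidate_matches_full_recompute(self, rng):
        x, y = random_pair(rng, 120)
        state = initial_quantization(PairedReplicates(x, y), 6)
        for k, corr in evaluate_merge_candidates(state):
            nlx = np.where(state.labels_x > k, state.labels_x - 1, state.labels_x)
            nly = np.where(state.labels_y > k, state.labels_y - 1, state.labels_y)
            expected = np.corrcoef(nlx, nly)[0, 1]
            assert corr == pytest.approx(expected, abs=1e-10), k

    def test_merging_inside_noise_block_raises_correlation(self):
        # bins 1..2 are independent noise; bins 3..4 agree perfectly
        noise = np.full((2, 2), 10)
        table = np.zeros((4, 4), dtype=int)
        table[:2, :2] = noise
        table[2, 2] = 20
        table[3, 3] = 20
        state = initial_quantization(
            PairedReplicates(*expand_table(table)), 4
        )
        np.testing.assert_array_equal(state.joint_counts, table)
        cands = dict(evaluate_merge_candidates(state))
        assert cands[1] > state.current_pcc  # merging the noise bins helps
        assert cands[3] < cands[1]  # merging the signal bins does not


class TestQCC:
    def test_perfect_replicates_give_one(self, rng):
        x = rng.normal(size=400)
        res = qcc(PairedReplicates(x, x), initial_bins=50)
        assert res.qcc == pytest.approx(1.0)

    def test_matches_naive_greedy_reference(self, rng):
        for _ in range(10):
            n = int(rng.integers(30, 200))
            b0 = int(rng.integers(3, 9))
            x, y = random_pair(rng, n, rho=0.6)
            res = qcc(PairedReplicates(x, y), initial_bins=b0)
            ref_val, ref_trace, ref_init = naive_greedy_qcc(x, y, b0)
            assert [k for k, _ in res.merge_trace] == [k for k, _ in ref_trace]
            assert res.qcc == pytest.approx(ref_val, abs=1e-10)
            assert res.initial_pcc_quantized == pytest.approx(ref_init, abs=1e-10)

    def test_merge_trace_strictly_increasing_and_consistent(self, rng):
        x, y = random_pair(rng, 500, rho=0.4)
        res = qcc(PairedReplicates(x, y), initial_bins=20)
        corrs = [c for _, c in res.merge_trace]
        assert all(b > a for a, b in zip(corrs, corrs[1:]))
        assert res.qcc >= res.initial_pcc_quantized
        assert res.qcc == (corrs[-1] if corrs else res.initial_pcc_quantized)
        assert -1.0 <= res.qcc <= 1.0
        assert res.final_state.B == res.initial_bins - len(res.merge_trace)
        # evaluation budget: at most B0-2 merges ever possible
        assert len(res.merge_trace) <= res.initial_bins - 2

    def test_final_state_is_internally_consistent(self, rng):
        x, y = random_pair(rng, 300, rho=0.5)
        res = qcc(PairedReplicates(x, y), initial_bins=15)
        fs = res.final_state
        table = joint_contingency(fs.labels_x, fs.labels_y, fs.B)
        np.testing.assert_array_equal(table, fs.joint_counts)
        assert pearson_from_contingency(table) == pytest.approx(
            fs.current_pcc, abs=1e-12
        )
        assert fs.joint_counts.sum() == 300
        assert set(np.unique(fs.labels_x)) == set(range(1, fs.B + 1))
        assert set(np.unique(fs.labels_y)) == set(range(1, fs.B + 1))
        assert len(fs.boundaries_x) == fs.B + 1

    def test_rank_invariance_is_exact(self, rng):
        x, y = random_pair(rng, 250, rho=0.5)
        base = qcc(PairedReplicates(x, y), initial_bins=12)
        warped = qcc(
            PairedReplicates(np.exp(x), np.arctan(y) * 5 + 2), initial_bins=12
        )
        assert warped.qcc == base.qcc
        assert warped.merge_trace == base.merge_trace

    def test_replicate_swap_symmetry_is_exact(self, rng):
        x, y = random_pair(rng, 300, rho=0.3)
        pair = PairedReplicates(x, y)
        assert qcc(pair, 15).qcc == qcc(pair.swapped(), 15).qcc

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            qcc(PairedReplicates(np.ones(50), np.arange(50.0)), initial_bins=5)

    def test_initial_bins_out_of_range(self, rng):
        x, y = random_pair(rng, 20)
        with pytest.raises(ParameterError):
            qcc(PairedReplicates(x, y), initial_bins=21)
        with pytest.raises(ParameterError):
            qcc(PairedReplicates(x, y), initial_bins=1)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(20, 120),
        b0=st.integers(3, 8),
    )
    def test_qcc_bounded_and_never_below_initial(self, seed, n, b0):
        r = np.random.default_rng(seed)
        x, y = random_pair(r, n, rho=0.5)
        res = qcc(PairedReplicates(x, y), initial_bins=b0)
        assert -1.0 <= res.qcc <= 1.0
        assert res.qcc >= res.initial_pcc_quantized


class TestAnalyticExpectedPcc:
    def test_zero_at_degenerate_coverage(self):
        assert analytic_expected_pcc(0.0, 3.0) == 0.0
        assert analytic_expected_pcc(1.0, 3.0) == 0.0

    @pytest.mark.parametrize(
        "coverage,expected",
        [(0.05, 0.29947460595446584), (0.20, 0.5901639344262295)],
    )
    def test_hand_evaluated_closed_form(self, coverage, expected):
        # p(1-p)S^2 / (p(1-p)S^2 + 1) at S=3, sigma=1
        assert analytic_expected_pcc(coverage, 3.0, 1.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_independent_of_noise_scale(self):
        assert analytic_expected_pcc(0.1, 4.0, 1.0) == pytest.approx(
            analytic_expected_pcc(0.1, 4.0, 2.5), abs=1e-12
        )

    def test_range_checks(self):
        with pytest.raises(ParameterError):
            analytic_expected_pcc(1.5, 3.0)
        with pytest.raises(ParameterError):
            analytic_expected_pcc(0.5, -1.0)
        with pytest.raises(ParameterError):
            analytic_expected_pcc(0.5, 3.0, 0.0)
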