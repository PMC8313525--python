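"""Entropy measures, the LZ estimator against a brute-force oracle, and Fano."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobipred.entropy import (
    lz_entropy_estimate,
    lz_match_lengths,
    markov_entropy_rate,
    predictability_profile,
    random_entropy,
    solve_fano,
    uncorrelated_entropy,
)


def brute_force_lambdas(seq):
    """Independent double-loop oracle for the LZ match-length vector."""
    n = len(seq)
    lam = []
    for j in range(n):  # 0-indexed position
        prefix = seq[:j]
        found_all = True
        for length in range(1, n - j + 1):
            sub = seq[j : j + length]
            occurs = any(prefix[p : p + length] == sub for p in range(0, j - length + 1))
            if not occurs:
                lam.append(length)
                found_all = False
                break
        if found_all:
            lam.append(n - j + 1)  # = n - (j+1) + 2 in 1-indexed form
    return lam


class TestBasicEntropies:
    @pytest.mark.parametrize("L,expected", [(1, 0.0), (2, 1.0), (8, 3.0)])
    def test_random_entropy(self, L, expected):
        assert random_entropy(L) == expected

    def test_random_entropy_rejects_zero(self):
        with pytest.raises(ValueError):
            random_entropy(0)

    @pytest.mark.parametrize(
        "counts,expected",
        [({"A": 1}, 0.0), ({"A": 2, "B": 2}, 1.0), ({"A": 9, "B": 1}, 0.4690)],
    )
    def test_uncorrelated_entropy(self, counts, expected):
        assert uncorrelated_entropy(counts) == pytest.approx(expected, abs=1e-4)

    def test_zero_count_symbols_ignored(self):
        assert uncorrelated_entropy({"A": 4, "B": 0}) == 0.0

    def test_s_unc_below_s_rand_with_equality_iff_uniform(self, rng):
        for _ in range(20):
            counts = dict(enumerate(rng.integers(1, 50, size=rng.integers(2, 9))))
            s_unc = uncorrelated_entropy(counts)
            s_rand = random_entropy(len(counts))
            assert s_unc <= s_rand + 1e-12
            uniform = len(set(counts.values())) == 1
            assert (abs(s_unc - s_rand) < 1e-12) == uniform


class TestLZ:
    def test_two_distinct_symbols(self):
        assert list(lz_match_lengths(list("AB"))) == [1, 1]
        assert lz_entropy_estimate(list("AB")) == pytest.approx(1.0)

    def test_constant_sequence_with_boundary_rule(self):
        assert list(lz_match_lengths(list("AAAA"))) == [1, 2, 3, 2]
        assert lz_entropy_estimate(list("AAAA")) == pytest.approx(1.0)

    def test_nulls_dropped_before_estimation(self):
        assert lz_entropy_estimate(["A", None, "B"]) == pytest.approx(
            lz_entropy_estimate(["A", "B"])
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lz_entropy_estimate(["A"])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=40))
    def test_matches_brute_force_on_quaternary_sequences(self, seq):
        assert list(lz_match_lengths(seq)) == brute_force_lambdas(seq)

    def test_iid_uniform_estimate_converges(self):
        seq = np.random.default_rng(2024).integers(0, 4, 20_000).tolist()
        assert 1.85 <= lz_entropy_estimate(seq) <= 2.05


class TestFano:
    def test_two_region_worked_example(self):
        assert solve_fano(1.0, 2) == pytest.approx(0.5, abs=1e-9)

    def test_zero_entropy_is_fully_predictable(self):
        for L in (1, 2, 10):
            assert solve_fano(0.0, L) == 1.0

    @pytest.mark.parametrize("L", [2, 3, 10, 100])
    def test_maximal_entropy_gives_uniform_floor(self, L):
        assert solve_fano(math.log2(L), L) == pytest.approx(1 / L, abs=1e-9)

    def test_monotone_decreasing_in_entropy(self):
        pis = [solve_fano(e, 5) for e in np.linspace(0.0, math.log2(5), 30)]
        assert all(b <= a + 1e-12 for a, b in zip(pis, pis[1:]))

    def test_clamps_and_warns_above_log2L(self):
        with pytest.warns(RuntimeWarning):
            assert solve_fano(2.5, 4) == 0.25

    def test_negative_entropy_rejected(self):
        with pytest.raises(ValueError):
            solve_fano(-0.1, 4)


class TestProfile:
    def test_single_symbol_sequence_completely_predictable(self):
        ent, pred = predictability_profile(["A"])
        assert (pred.pi_rand, pred.pi_unc, pred.pi_max) == (1.0, 1.0, 1.0)
        assert ent.s_est == 0.0 and ent.L == 1

    def test_two_region_memoryless_data(self):
        # equal-frequency iid over two regions: pi_rand = 0.5
        seq = np.random.default_rng(9).integers(0, 2, 5000).tolist()
        ent, pred = predictability_profile(seq)
        assert pred.pi_rand == pytest.approx(0.5, abs=1e-9)
        assert ent.L == 2

    def test_pi_rand_is_reciprocal_alphabet_size(self, rng):
        seq = rng.integers(0, 6, 800).tolist()
        ent, pred = predictability_profile(seq)
        assert pred.pi_rand == pytest.approx(1 / ent.L, abs=1e-9)

    def test_entropy_ordering_gives_predictability_ordering(self, rng):
        seq = rng.choice(4, 2000, p=[0.6, 0.2, 0.1, 0.1]).tolist()
        ent, pred = predictability_profile(seq)
        assert ent.s_unc <= ent.s_rand
        assert pred.pi_rand <= pred.pi_unc + 1e-12


class TestMarkovRate:
    def test_uniform_four_state(self):
        assert markov_entropy_rate(np.full((4, 4), 0.25)) == pytest.approx(2.0)

    def test_two_state_sticky_chain(self):
        # binary entropy of 0.9
        expected = -(0.9 * math.log2(0.9) + 0.1 * math.log2(0.1))
        assert markov_entropy_rate([[0.9, 0.1], [0.1, 0.9]]) == pytest.approx(expected)

    def test_deterministic_single_state(self):
        assert markov_entropy_rate([[1.0]]) == 0.0

    def test_reducible_chain_rejected(self):
        with pytest.raises(ValueError, match="reducible"):
            markov_entropy_rate(np.eye(2))
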