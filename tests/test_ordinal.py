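"""Ordinal encoding, entropies, LZ76 parsing and PLZC."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeprofile import (
    InvalidParameterError,
    add_tiebreak_noise,
    bins_entropy,
    encode_ordinal,
    lz76_parse,
    lz_normalize,
    op_entropy,
    ordinal_pattern,
    plzc,
    shannon_entropy_normalized,
    symbol_distribution,
)


def lz76_count_bruteforce(seq):
    """Independent word-count oracle: novelty by exhaustive position-by-position
    substring comparison against the text preceding the word's final symbol."""
    seq = tuple(seq)
    n = len(seq)

    def occurs(word, upto):
        L = len(word)
        return any(tuple(seq[k : k + L]) == word for k in range(upto - L + 1))

    count = 0
    start = 0
    while start < n:
        j = start
        while j < n and occurs(tuple(seq[start : j + 1]), j):
            j += 1
        if j == n:
            j = n - 1
        count += 1
        start = j + 1
    return count


class TestOrdinalPattern:
    def test_convention_anchors(self):
        assert ordinal_pattern((1, 2, 3)) == 0
        assert ordinal_pattern((3, 2, 1)) == 5

    def test_all_orderings_map_to_distinct_symbols(self):
        symbols = {ordinal_pattern(p) for p in itertools.permutations((1.0, 2.0, 3.0))}
        assert symbols == set(range(6))

    def test_ties_are_rejected(self):
        with pytest.raises(InvalidParameterError, match="tie"):
            ordinal_pattern((1.0, 1.0, 2.0))

    @given(st.integers(2, 4), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_symbol_range_and_rank_consistency(self, d, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0, 1, d)
        s = ordinal_pattern(w)
        assert 0 <= s < math.factorial(d)
        # monotone transform of the window leaves the symbol unchanged
        assert ordinal_pattern(np.exp(w)) == s


class TestEncodeOrdinal:
    def test_offset_window_counts_at_standard_length(self, iid_isi_225):
        enc = encode_ordinal(iid_isi_225, D=3, offsets=(0, 1))
        assert len(enc.symbols[0]) == 75
        assert len(enc.symbols[1]) == 74
        assert len(enc.pooled()) == 149

    def test_monotone_sequence_yields_single_symbol(self, monotone_isi_225):
        enc = encode_ordinal(monotone_isi_225, D=3, offsets=(0, 1))
        assert set(enc.pooled().tolist()) == {0}

    def test_too_short_sequence_rejected(self):
        with pytest.raises(InvalidParameterError):
            encode_ordinal(np.array([0.1, 0.2]), D=3)

    @given(st.integers(7, 400), st.integers(2, 4), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_pooled_count_bookkeeping(self, n, d, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0.01, 1.0, n)
        enc = encode_ordinal(v, D=d, offsets=(0, 1))
        assert len(enc.pooled()) == n // d + (n - 1) // d


class TestSymbolDistribution:
    def test_probabilities_sum_to_one(self, iid_isi_225):
        dist = symbol_distribution(encode_ordinal(iid_isi_225))
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.counts.sum() == 149

    def test_single_pattern_is_degenerate(self, monotone_isi_225):
        dist = symbol_distribution(encode_ordinal(monotone_isi_225))
        assert dist.probabilities[0] == 1.0
        assert dist.probabilities[1:].sum() == 0.0


class TestShannonEntropy:
    def test_uniform_is_one(self):
        assert shannon_entropy_normalized(np.full(6, 1 / 6), 6) == pytest.approx(1.0)

    def test_degenerate_is_zero(self):
        assert shannon_entropy_normalized(np.array([1.0, 0, 0, 0, 0, 0]), 6) == 0.0

    def test_two_equal_of_six(self):
        p = np.array([0.5, 0.5, 0, 0, 0, 0])
        expected = math.log(2) / math.log(6)  # 0.38685...
        assert shannon_entropy_normalized(p, 6) == pytest.approx(expected, abs=1e-12)

    def test_small_alphabet_rejected(self):
        with pytest.raises(InvalidParameterError):
            shannon_entropy_normalized(np.array([1.0]), 1)


class TestTiebreakNoise:
    def test_constant_input_becomes_distinct(self):
        out = add_tiebreak_noise(np.full(225, 0.1), seed=0)
        assert np.unique(out).size == 225

    def test_zero_scale_is_identity(self, iid_isi_225):
        assert np.array_equal(add_tiebreak_noise(iid_isi_225, scale=0.0), iid_isi_225)

    def test_perturbation_bounded_by_gaussian_tail(self, iid_isi_225):
        sd = np.std(iid_isi_225)
        for seed in range(20):
            out = add_tiebreak_noise(iid_isi_225, scale=1e-6, seed=seed)
            assert np.all(np.abs(out - iid_isi_225) <= 6e-6 * sd)


class TestOpEntropy:
    def test_monotone_sequence_is_zero(self, monotone_isi_225):
        assert op_entropy(monotone_isi_225, tiebreak_scale=0.0) == 0.0

    def test_iid_sequences_are_near_maximal(self):
        rng = np.random.default_rng(21)
        vals = [
            op_entropy(rng.exponential(0.1, 225), tiebreak_seed=k) for k in range(100)
        ]
        assert 0.97 < float(np.mean(vals)) < 1.0

    def test_bounded_by_one(self, iid_isi_225):
        assert op_entropy(iid_isi_225, tiebreak_seed=0) <= 1.0

    def test_invariant_under_monotone_transform(self, iid_isi_225):
        a = op_entropy(iid_isi_225, tiebreak_scale=0.0)
        b = op_entropy(np.sqrt(iid_isi_225), tiebreak_scale=0.0)
        assert a == b


class TestBinsEntropy:
    def test_constant_sequence_is_zero(self):
        assert bins_entropy(np.full(225, 0.1)) == 0.0

    def test_evenly_spread_values_near_one(self):
        # 225 values spread evenly over 18 bins: 9 bins of 13, 9 bins of 12
        centers = (np.arange(18) + 0.5) / 18
        v = np.concatenate([np.repeat(centers, 12), centers[:9]])
        assert bins_entropy(v, nb=18) >= 0.999

    def test_exact_permutation_invariance(self, iid_isi_225, rng):
        shuffled = rng.permutation(iid_isi_225)
        assert bins_entropy(shuffled) == bins_entropy(iid_isi_225)

    def test_bounded_in_unit_interval(self, iid_isi_225):
        assert 0.0 <= bins_entropy(iid_isi_225) <= 1.0


class TestLZ76:
    def test_printed_worked_example(self):
        parse = lz76_parse("100110111001010001011")
        assert parse.c_lz == 7
        assert ["".join(w) for w in parse.words] == [
            "1", "0", "01", "101", "1100", "1010", "001011",
        ]

    def test_single_symbol(self):
        assert lz76_parse("0").c_lz == 1

    def test_constant_run_parses_into_two_words(self):
        parse = lz76_parse("0000000000")
        assert parse.c_lz == 2
        assert ["".join(w) for w in parse.words] == ["0", "000000000"]

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            lz76_parse("")

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_words_concatenate_to_input(self, seq):
        parse = lz76_parse(seq)
        flat = [s for w in parse.words for s in w]
        assert flat == seq

    @given(
        st.integers(1, 30),
        st.sampled_from([2, 6]),
        st.integers(0, 10**6),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_oracle(self, length, alpha, seed):
        rng = np.random.default_rng(seed)
        seq = rng.integers(0, alpha, length).tolist()
        assert lz76_parse(seq).c_lz == lz76_count_bruteforce(seq)


class TestLZNormalize:
    def test_printed_parse_normalization(self):
        assert lz_normalize(7, 21, 2) == pytest.approx(7 * math.log2(21) / 21, abs=1e-12)
        assert lz_normalize(7, 21, 2) == pytest.approx(1.4641, abs=5e-4)

    def test_minimal_case(self):
        assert lz_normalize(1, 2, 2) == 0.5

    def test_decreases_with_length_at_fixed_count(self):
        vals = [lz_normalize(5, t, 2) for t in (8, 16, 32, 64)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestPlzc:
    def test_monotone_sequence_closed_form(self, monotone_isi_225):
        # one repeated symbol, T=75: parse = 2 words -> 2*log6(75)/75
        expected = 2 * math.log(75, 6) / 75
        assert plzc(monotone_isi_225, tiebreak_scale=0.0) == pytest.approx(expected, abs=1e-12)

    def test_iid_sequences_near_unity(self):
        rng = np.random.default_rng(31)
        vals = [plzc(rng.exponential(0.1, 225), tiebreak_seed=k) for k in range(100)]
        assert 0.7 < float(np.mean(vals)) < 1.1

    def test_not_permutation_invariant_witness(self, monotone_isi_225, rng):
        ordered = plzc(monotone_isi_225, tiebreak_scale=0.0)
        shuffled = plzc(rng.permutation(monotone_isi_225), tiebreak_seed=1)
        assert shuffled > ordered + 0.5
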