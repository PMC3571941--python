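"""Unit and property tests for the Bernoulli change-point engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bicseg import (
    BinarySequence,
    best_pair,
    loglik_constant,
    loglik_pair,
    segment,
    summarize_segments,
)
from tests.conftest import naive_best_pair, naive_segment

bits_strategy = st.lists(st.integers(0, 1), min_size=1, max_size=40).map(np.array)


class TestBinarySequence:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0 and 1"):
            BinarySequence(np.array([0, 2, 1]))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            BinarySequence(np.array([], dtype=int))

    def test_rejects_non_increasing_positions(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            BinarySequence(np.array([0, 1]), positions=np.array([5, 5]))


class TestLoglikConstant:
    @pytest.mark.parametrize(
        "bits, expected",
        [
            ((0, 0, 0, 0), 0.0),  # degenerate all-zero: rate 0, every factor 1
            ((1, 1, 1), 0.0),  # degenerate all-one
            ((1, 0, 1, 0), 4 * math.log(0.5)),  # rate 1/2
        ],
    )
    def test_examples(self, bits, expected):
        assert loglik_constant(BinarySequence(np.array(bits))) == pytest.approx(
            expected, abs=1e-12
        )

    def test_never_positive(self, rng):
        for _ in range(50):
            bits = (rng.random(rng.integers(1, 30)) < 0.5).astype(int)
            assert loglik_constant(BinarySequence(bits)) <= 0.0


class TestLoglikPair:
    def test_perfect_separation(self, toy_bits):
        # arc [4,6] is all ones, complement all zeros: likelihood 1
        assert loglik_pair(BinarySequence(toy_bits), 3, 6) == pytest.approx(0.0)

    def test_hand_evaluated_arc(self):
        # arc [2,4] holds one 1 of three, complement [1,1] is a single 1
        seq = BinarySequence(np.array([1, 0, 1, 0]))
        expected = math.log(1.0) + math.log(1 / 3) + 2 * math.log(2 / 3)
        assert loglik_pair(seq, 1, 4) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("c1, c2", [(0, 3), (2, 2), (3, 2), (1, 11)])
    def test_invalid_indices(self, toy_bits, c1, c2):
        with pytest.raises(ValueError):
            loglik_pair(BinarySequence(toy_bits), c1, c2)

    @given(bits=bits_strategy, data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_nesting(self, bits, data):
        """The two-rate model at its MLEs never fits worse than one rate."""
        m = len(bits)
        if m < 2:
            return
        c1 = data.draw(st.integers(1, m - 1))
        c2 = data.draw(st.integers(c1 + 1, m))
        seq = BinarySequence(bits)
        assert loglik_pair(seq, c1, c2) >= loglik_constant(seq) - 1e-12


class TestBestPair:
    def test_worked_example(self, toy_bits):
        pair = best_pair(BinarySequence(toy_bits))
        assert (pair.c1, pair.c2) == (3, 6)
        expected = -(3 * math.log(0.3) + 7 * math.log(0.7)) - 1.5 * math.log(10)
        assert pair.bic10 == pytest.approx(expected, abs=1e-12)
        assert pair.bic10 > 0

    @pytest.mark.parametrize("m", [2, 5, 17])
    def test_all_zeros_penalty_dominates(self, m):
        pair = best_pair(BinarySequence(np.zeros(m, dtype=int)))
        assert pair.bic10 == pytest.approx(-1.5 * math.log(m))
        assert pair.bic10 < 0

    @pytest.mark.parametrize("m", [8, 20, 100])
    def test_single_one_closed_form(self, m):
        """Isolating a lone 1 never beats the penalty once m >= 8."""
        bits = np.zeros(m, dtype=int)
        bits[m // 2] = 1
        pair = best_pair(BinarySequence(bits))
        expected = math.log(m) + (m - 1) * math.log(m / (m - 1)) - 1.5 * math.log(m)
        assert pair.bic10 == pytest.approx(expected, abs=1e-9)
        assert pair.bic10 < 0

    def test_short_sequence_sentinel(self):
        pair = best_pair(BinarySequence(np.array([1])))
        assert not pair.testable
        assert pair.bic10 < 0  # treated as accepting the constant model

    @given(bits=bits_strategy)
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_scan(self, bits):
        """Prefix-sum scan is bit-identical to the exhaustive double loop."""
        if len(bits) < 2:
            return
        pair = best_pair(BinarySequence(bits))
        c1, c2, bic = naive_best_pair(bits.tolist())
        assert (pair.c1, pair.c2) == (c1, c2)
        assert pair.bic10 == pytest.approx(bic, abs=1e-9)


class TestSegment:
    def test_interior_block(self, toy_bits):
        result = segment(BinarySequence(toy_bits))
        assert result.changepoints == (3, 6)
        assert [(s.start, s.end, s.rate) for s in result.segments] == [
            (1, 3, 0.0),
            (4, 6, 1.0),
            (7, 10, 0.0),
        ]
        assert result.K == 2

    def test_circular_wrap(self):
        """The best arc is the interior zero run; its complement wraps."""
        result = segment(BinarySequence(np.array([1, 1, 1, 0, 0, 0, 0, 1, 1, 1])))
        assert result.changepoints == (3, 7)
        assert [s.rate for s in result.segments] == [1.0, 0.0, 1.0]

    @pytest.mark.parametrize("bits", [np.zeros(12, dtype=int), np.ones(7, dtype=int)])
    def test_constant_sequence(self, bits):
        result = segment(BinarySequence(bits))
        assert result.K == 0
        assert len(result.segments) == 1

    @given(bits=bits_strategy)
    @settings(max_examples=60, deadline=None)
    def test_complement_symmetry(self, bits):
        """Flipping every bit leaves the change-point set unchanged."""
        a = segment(BinarySequence(bits))
        b = segment(BinarySequence(1 - bits))
        assert a.changepoints == b.changepoints

    @given(bits=bits_strategy)
    @settings(max_examples=60, deadline=None)
    def test_tiling_and_rates(self, bits):
        """Segments tile [1, m]; each rate is the segment's empirical mean."""
        result = segment(BinarySequence(bits))
        assert result.segments[0].start == 1
        assert result.segments[-1].end == len(bits)
        for left, right in zip(result.segments, result.segments[1:]):
            assert right.start == left.end + 1
        for s in result.segments:
            assert s.rate == pytest.approx(bits[s.start - 1 : s.end].mean())
        assert result.K == len(result.segments) - 1

    @given(bits=st.lists(st.integers(0, 1), min_size=2, max_size=18).map(np.array))
    @settings(max_examples=40, deadline=None)
    def test_matches_naive_recursion(self, bits):
        assert segment(BinarySequence(bits)).changepoints == naive_segment(
            bits.tolist()
        )

    def test_deterministic(self, rng):
        bits = (rng.random(200) < 0.3).astype(int)
        assert segment(BinarySequence(bits)) == segment(BinarySequence(bits))


class TestSummarize:
    def test_single_segment_mean(self):
        result = segment(BinarySequence(np.array([0, 0, 0])))
        out = summarize_segments(result, np.array([0.1, 0.2, 0.3]))
        assert out.segments[0].mean_log2 == pytest.approx(0.2)

    def test_two_segments(self):
        result = segment(BinarySequence(np.array([0, 0, 1, 1, 1, 1, 1, 1])))
        values = np.arange(8, dtype=float)
        out = summarize_segments(result, values)
        for seg in out.segments:
            assert seg.mean_log2 == pytest.approx(
                values[seg.start - 1 : seg.end].mean()
            )

    def test_threshold_invariance(self, rng):
        """Means read the raw values, not the binarization that tiled them."""
        values = rng.normal(size=30)
        for tau in (0.1, 0.5, 1.0):
            result = segment(BinarySequence((values > tau).astype(int)))
            out = summarize_segments(result, values)
            for seg in out.segments:
                assert seg.mean_log2 == pytest.approx(
                    values[seg.start - 1 : seg.end].mean()
                )

    def test_length_mismatch(self, toy_bits):
        result = segment(BinarySequence(toy_bits))
        with pytest.raises(ValueError, match="length"):
            summarize_segments(result, np.zeros(5))
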