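"""Circular binary segmentation of Bernoulli sequences by BIC model selection.

A copy-number profile is first reduced to a 0/1 indicator sequence (see
:mod:`bicseg.binarize`).  The engine here treats that sequence as a circle
and repeatedly tests whether some arc ``[c1+1, c2]`` has a different success
rate than its complement (the two-change-point model ``M1``) against the
constant-rate model ``M0``, choosing between them with the Bayesian
information criterion.  A positive ``BIC10`` splits the region in three and
each part is re-scanned recursively; the recursion stops when no region
yields a positive score.

All public indices are 1-based and inclusive, matching the usual
change-point convention: a change-point ``c`` separates probe ``c`` from
probe ``c + 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.special import xlogy

__all__ = [
    "BinarySequence",
    "ChangePointPair",
    "Segment",
    "SegmentationResult",
    "loglik_constant",
    "loglik_pair",
    "best_pair",
    "segment",
    "summarize_segments",
]

# M1 estimates two rates and two change-point indices, M0 one rate.
_Q1 = 4
_Q0 = 1


@dataclass(frozen=True)
class BinarySequence:
    """A Bernoulli indicator sequence, optionally carrying genomic positions.

    Parameters
    ----------
    bits
        Vector of 0/1 indicators, length ``m >= 1``.
    positions
        Optional base-pair coordinates, one per bit, strictly increasing.
        Present when the sequence lives on a single chromosome and genomic
        reporting or multi-source merging is wanted.
    """

    bits: np.ndarray
    positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int64)
        if bits.ndim != 1 or bits.size == 0:
            raise ValueError("bits must be a non-empty 1-D vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must contain only 0 and 1")
        object.__setattr__(self, "bits", bits)
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=np.int64)
            if pos.shape != bits.shape:
                raise ValueError("positions must match bits in length")
            if pos.size > 1 and not (np.diff(pos) > 0).all():
                raise ValueError("positions must be strictly increasing")
            object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return int(self.bits.size)


@dataclass(frozen=True)
class ChangePointPair:
    """Best-scoring arc ``[c1+1, c2]`` and its BIC score.

    ``testable`` is False for sequences too short to host a pair (m < 2);
    such a result is treated as accepting the constant model.
    """

    c1: int
    c2: int
    bic10: float
    testable: bool = True


@dataclass(frozen=True)
class Segment:
    """A maximal run of constant estimated success rate.

    ``start``/``end`` are 1-based inclusive probe indices; ``rate`` is the
    fraction of 1s over the segment; ``mean_log2`` is the mean of the
    original log2 ratios over the segment, filled by
    :func:`summarize_segments`.
    """

    start: int
    end: int
    rate: float
    mean_log2: Optional[float] = None

    @property
    def n_probes(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SegmentationResult:
    """Change-points and the segment tiling they induce on ``[1, m]``."""

    changepoints: tuple[int, ...]
    segments: tuple[Segment, ...]

    @property
    def K(self) -> int:
        """Number of change-points (= number of segments - 1)."""
        return len(self.changepoints)

    @property
    def m(self) -> int:
        return self.segments[-1].end


def _bern_loglik(successes, size):
    """Maximized Bernoulli log-likelihood of ``successes`` 1s in ``size``
    trials, with the convention 0*log(0) = 0 (via ``xlogy``)."""
    return xlogy(successes, successes / size) + xlogy(
        size - successes, (size - successes) / size
    )


def loglik_constant(seq: BinarySequence) -> float:
    """Log-likelihood of the no-change-point model at its MLE.

    The MLE of the common success rate is the overall fraction of 1s; the
    returned value is always <= 0.
    """
    m = len(seq)
    s = int(seq.bits.sum())
    return float(_bern_loglik(s, m))


def loglik_pair(seq: BinarySequence, c1: int, c2: int) -> float:
    """Log-likelihood of the two-change-point model at its MLEs.

    The arc is ``[c1+1, c2]``; the complement wraps around the circle as
    ``[1, c1] + [c2+1, m]``.  Requires ``1 <= c1 < c2 <= m``.  By nesting,
    the value is always >= :func:`loglik_constant`.
    """
    m = len(seq)
    if not (1 <= c1 < c2 <= m):
        raise ValueError(f"need 1 <= c1 < c2 <= m, got c1={c1}, c2={c2}, m={m}")
    arc_n = c2 - c1
    arc_s = int(seq.bits[c1:c2].sum())
    comp_n = m - arc_n
    comp_s = int(seq.bits.sum()) - arc_s
    return float(_bern_loglik(comp_s, comp_n) + _bern_loglik(arc_s, arc_n))


def _no_pair() -> ChangePointPair:
    return ChangePointPair(c1=0, c2=0, bic10=-math.inf, testable=False)


@lru_cache(maxsize=16)
def _pair_indices(m: int) -> tuple[np.ndarray, np.ndarray]:
    """All pairs 1 <= c1 < c2 <= m in c1-major order, as 1-based arrays."""
    i, j = np.triu_indices(m, k=1)
    return i + 1, j + 1


def best_pair(seq: BinarySequence) -> ChangePointPair:
    """Exhaustively maximize the arc likelihood over all pairs.

    Scans every ``1 <= c1 < c2 <= m`` with prefix sums (equivalent to the
    naive double loop, bit for bit) and returns the lexicographically
    smallest maximizing pair together with

        ``BIC10 = log L1 - log L0 - (3/2) * log m``,

    the dimensionality penalty being ``(q1 - q0)/2 * log m`` with ``q1 = 4``
    and ``q0 = 1``.  A positive score favours the two-change-point model.
    """
    bits = seq.bits
    m = bits.size
    if m < 2:
        return _no_pair()

    prefix = np.zeros(m + 1, dtype=np.int64)
    np.cumsum(bits, out=prefix[1:])
    total = int(prefix[m])
    ll0 = _bern_loglik(total, m)
    penalty = 1.5 * math.log(m)

    # Flat scan over the upper triangle, enumerated c1-major so np.argmax
    # (first maximum) realizes the lexicographic (c1, c2) tie-break.
    # Memory is O(m^2); fine for chromosome- and genome-scale inputs.
    c1, c2 = _pair_indices(m)
    arc_n = c2 - c1
    arc_s = prefix[c2] - prefix[c1]
    ll1 = _bern_loglik(total - arc_s, m - arc_n) + _bern_loglik(arc_s, arc_n)
    idx = int(np.argmax(ll1))
    return ChangePointPair(
        c1=int(c1[idx]),
        c2=int(c2[idx]),
        bic10=float(ll1[idx] - ll0 - penalty),
    )


def _tiling(bits: np.ndarray, changepoints: Sequence[int]) -> tuple[Segment, ...]:
    m = bits.size
    bounds = [0, *sorted(changepoints), m]
    segs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        n = hi - lo
        segs.append(Segment(start=lo + 1, end=hi, rate=float(bits[lo:hi].sum() / n)))
    return tuple(segs)


def segment(seq: BinarySequence) -> SegmentationResult:
    """Recursive circular binary segmentation of a Bernoulli sequence.

    The whole sequence is scanned with :func:`best_pair`.  A score
    ``BIC10 <= 0`` accepts the constant model and the region becomes one
    segment.  A positive score records the pair as change-points (``c2`` is
    dropped when it coincides with the region's right edge, where the pair
    degenerates to a single change-point) and the three induced subregions
    are scanned independently, each using its own length in the penalty.
    Deterministic: identical input yields identical output.
    """
    bits = seq.bits
    m = bits.size
    changepoints: set[int] = set()
    stack: list[tuple[int, int]] = [(1, m)]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo + 1
        if n < 2:
            continue
        pair = best_pair(BinarySequence(bits[lo - 1 : hi]))
        if not pair.testable or pair.bic10 <= 0:
            continue
        g1 = lo - 1 + pair.c1
        g2 = lo - 1 + pair.c2
        changepoints.add(g1)
        stack.append((lo, g1))
        if g2 < hi:
            changepoints.add(g2)
            stack.append((g1 + 1, g2))
            stack.append((g2 + 1, hi))
        else:
            stack.append((g1 + 1, g2))
    cps = tuple(sorted(changepoints))
    return SegmentationResult(changepoints=cps, segments=_tiling(bits, cps))


def summarize_segments(
    result: SegmentationResult, profile_values: np.ndarray
) -> SegmentationResult:
    """Fill each segment's ``mean_log2`` from the original log2 ratios.

    ``profile_values`` must align with the binarized sequence the result was
    computed on.  Missing values (NaN) are excluded from the mean.
    """
    values = np.asarray(profile_values, dtype=float)
    if values.ndim != 1 or values.size != result.m:
        raise ValueError(
            f"profile_values length {values.size} != sequence length {result.m}"
        )
    segs = tuple(
        replace(s, mean_log2=float(np.nanmean(values[s.start - 1 : s.end])))
        for s in result.segments
    )
    return replace(result, segments=segs)
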