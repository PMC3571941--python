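"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (pure-Python double loops, direct
slicing) so they stay independent of the vectorized library paths they
check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


def naive_bern_loglik(seg) -> float:
    """Maximized Bernoulli log-likelihood of a 0/1 list, 0*log0 = 0."""
    n = len(seg)
    s = sum(seg)
    out = 0.0
    if s:
        out += s * math.log(s / n)
    if n - s:
        out += (n - s) * math.log((n - s) / n)
    return out


def naive_best_pair(bits) -> tuple[int, int, float]:
    """Exhaustive double loop over all (c1, c2); first maximum wins.

    Returns (c1, c2, bic10) with 1-based indices.
    """
    bits = list(bits)
    m = len(bits)
    best = None
    for c1 in range(1, m):
        for c2 in range(c1 + 1, m + 1):
            arc = bits[c1:c2]
            complement = bits[:c1] + bits[c2:]
            ll = naive_bern_loglik(arc) + naive_bern_loglik(complement)
            if best is None or ll > best[2]:
                best = (c1, c2, ll)
    bic10 = best[2] - naive_bern_loglik(bits) - 1.5 * math.log(m)
    return best[0], best[1], bic10


def naive_segment(bits) -> tuple[int, ...]:
    """Recursive segmentation via the naive scan; returns sorted change-points."""
    bits = list(bits)
    cps: set[int] = set()

    def recurse(lo: int, hi: int) -> None:
        if hi - lo + 1 < 2:
            return
        c1, c2, bic = naive_best_pair(bits[lo - 1 : hi])
        if bic <= 0:
            return
        g1, g2 = lo - 1 + c1, lo - 1 + c2
        cps.add(g1)
        recurse(lo, g1)
        if g2 < hi:
            cps.add(g2)
            recurse(g1 + 1, g2)
            recurse(g2 + 1, hi)
        else:
            recurse(g1 + 1, g2)

    recurse(1, len(bits))
    return tuple(sorted(cps))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20121030)


@pytest.fixture
def toy_bits() -> np.ndarray:
    """The worked example: a clean interior block of three 1s."""
    return np.array([0, 0, 0, 1, 1, 1, 0, 0, 0, 0])
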