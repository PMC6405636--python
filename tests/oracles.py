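"""Independent brute-force oracles used across the test suite.

These never call into subclone_sampler: capture probabilities are
recovered by exhaustively enumerating every possible sample (subset) of
a small labelled population, so any agreement with the package is a
genuine cross-check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def exhaustive_capture_counts(N: int, K: int, s: int) -> dict[int, int]:
    """Number of size-s subsets of N labelled cells (cells 0..K-1 are
    subclonal) containing exactly x subclonal cells, for each x."""
    counts: dict[int, int] = {}
    for subset in itertools.combinations(range(N), s):
        x = sum(1 for cell in subset if cell < K)
        counts[x] = counts.get(x, 0) + 1
    return counts


def exhaustive_capture_probability(N: int, K: int, s: int, k: int) -> Fraction:
    """Exact P(at least k subclonal cells) by subset enumeration."""
    counts = exhaustive_capture_counts(N, K, s)
    hits = sum(c for x, c in counts.items() if x >= k)
    return Fraction(hits, math.comb(N, s))


# ---------------------------------------------------------------------------
# Frozen high-precision values for the tissue-scale worked example
# (N = 1e9 cells, subclone frequency 1e-4, so K = 1e5), computed with
# 50-digit arbitrary-precision arithmetic from
#   P(X=0) = prod_{i<s} (1 - K/(N-i))        [hypergeometric]
#   P(X=0) = (1 - K/N)**s                    [binomial limit]

#: P(X >= 1) at s = 46050, exact hypergeometric
TISSUE_TAIL_46050 = 0.990001661072476854
#: P(X >= 1) at s = 46049 and 46048 (the minimal-s boundary)
TISSUE_TAIL_46049 = 0.990000661092538
TISSUE_TAIL_46048 = 0.989999661012588
#: binomial P(X >= 1) at s = 46050
TISSUE_BINOM_TAIL_46050 = 0.99000060077558331184
#: minimal s with hypergeometric tail >= 0.99
TISSUE_MIN_CELLS_EXACT = 46049
#: minimal s with binomial tail >= 0.99 (= ceil(ln 0.01 / ln 0.9999))
TISSUE_MIN_CELLS_BINOMIAL = 46050
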