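"""Sample-size inversion: from "how likely?" to "how many cells?".

Given a tissue of N cells, a subclone at clonal frequency f (so
K = round(f*N) subclonal cells), a capture threshold k and a target
confidence p, find the minimal sample size s* with

    P(X >= k) >= p,    X ~ Hypergeom(N, K, s*).

The capture probability is monotone non-decreasing in s, so s* is found
by exponential bracketing followed by bisection.  A binomial
(infinite-population) companion is provided for comparison: sampling
with replacement never captures more easily, so its s* upper-bounds the
hypergeometric one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .hypergeom import (
    CaptureQuery,
    DomainError,
    Population,
    capture_probability,
)

__all__ = [
    "DesignRequirement",
    "DesignResult",
    "DesignTable",
    "UnattainableRequirementError",
    "DegenerateFrequencyError",
    "subclone_count_from_frequency",
    "min_cells_for_capture",
    "binomial_min_cells",
    "design_curve",
    "round_to_nearest",
    "DEFAULT_POPULATION_SIZE",
    "DEFAULT_FREQUENCIES",
    "DEFAULT_CONFIDENCES",
]

# Roundoff guard on confidence comparisons: accept s when
# P(capture) >= p - GUARD.  Far below one ulp of any design-scale
# probability difference, so it never changes an integer answer at
# realistic scales; it only absorbs last-bit noise.
CONFIDENCE_GUARD = 1e-12

DEFAULT_POPULATION_SIZE = 10**9
DEFAULT_FREQUENCIES: tuple[float, ...] = tuple(np.logspace(-6, -1, 25))
DEFAULT_CONFIDENCES: tuple[float, ...] = (0.50, 0.90, 0.95, 0.99)

TABLE_COLUMNS = [
    "frequency",
    "subclone_count",
    "confidence",
    "min_captured",
    "min_sample_size",
    "achieved_probability",
]


class UnattainableRequirementError(ValueError):
    """No sample size can meet the requirement (e.g. fewer than k
    subclonal cells exist in the whole tissue)."""


class DegenerateFrequencyError(ValueError):
    """A positive frequency that rounds to zero subclonal cells."""


def subclone_count_from_frequency(pop_size: int, frequency: float) -> int:
    """Subclone cell count K = round(f * N), half away from zero.

    Raises :class:`DegenerateFrequencyError` when f > 0 but the count
    rounds to zero (f < 1/(2N)): such a subclone does not exist in a
    tissue of this size and the design question is ill-posed.
    """
    if isinstance(pop_size, bool) or not isinstance(pop_size, (int, np.integer)):
        raise DomainError(f"pop_size must be an integer, got {pop_size!r}")
    pop_size = int(pop_size)
    if pop_size < 1:
        raise DomainError(f"pop_size must be >= 1, got {pop_size}")
    if not (0.0 <= frequency <= 1.0):
        raise DomainError(f"frequency must be in [0, 1], got {frequency}")
    K = math.floor(frequency * pop_size + 0.5)
    K = min(K, pop_size)
    if frequency > 0.0 and K == 0:
        raise DegenerateFrequencyError(
            f"frequency {frequency} rounds to zero cells in a population of {pop_size}"
        )
    return K


@dataclass(frozen=True)
class DesignRequirement:
    """An inversion question: capture at least ``min_captured`` subclonal
    cells with probability at least ``confidence``."""

    population: Population
    min_captured: int
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence <= 1.0):
            raise DomainError(
                f"confidence must be in (0, 1], got {self.confidence}"
            )
        # construct to validate k range
        CaptureQuery(0, self.min_captured)


@dataclass(frozen=True)
class DesignResult:
    """Minimal sample size with the probabilities at and just below it.

    ``achieved_probability >= confidence > probability_below`` is the
    defining boundary property; ``probability_below`` is evaluated at
    ``min_sample_size - 1`` (an exact 0 at the s* = k edge).
    """

    min_sample_size: int
    achieved_probability: float
    probability_below: float


def _prob(pop: Population, s: int, k: int) -> float:
    return capture_probability(pop, CaptureQuery(s, k))


def min_cells_for_capture(req: DesignRequirement) -> DesignResult:
    """Minimal integer s* with P(X >= k | s*) >= p.

    Exponential bracketing from s = k (doubling) followed by bisection,
    valid because the capture probability is non-decreasing in s.  The
    requirement is attainable for any p <= 1 whenever K >= k, since
    s = N - K + k guarantees the capture.
    """
    pop, k, p = req.population, req.min_captured, req.confidence
    N, K = pop.total_cells, pop.subclone_cells
    if K < k:
        raise UnattainableRequirementError(
            f"tissue holds only {K} subclonal cells; cannot capture {k}"
        )
    s_certain = N - K + k  # smallest s with capture probability exactly 1
    if p >= 1.0:
        s_star = s_certain
        return DesignResult(s_star, 1.0, _prob(pop, s_star - 1, k))
    target = p - CONFIDENCE_GUARD
    if _prob(pop, k, k) >= target:
        return DesignResult(k, _prob(pop, k, k), _prob(pop, k - 1, k))
    lo = k  # below target
    hi = k
    while True:
        hi = min(2 * hi, s_certain)
        if _prob(pop, hi, k) >= target:
            break
        lo = hi
        if hi == s_certain:  # cannot happen: probability there is exactly 1
            break
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _prob(pop, mid, k) >= target:
            hi = mid
        else:
            lo = mid
    return DesignResult(hi, _prob(pop, hi, k), _prob(pop, hi - 1, k))


def _binom_tail(s: int, k: int, f: float) -> float:
    # P(Binom(s, f) >= k)
    if s < k:
        return 0.0
    return float(binom.sf(k - 1, s, f))


def binomial_min_cells(frequency: float, min_captured: int, confidence: float) -> int:
    """Minimal s with binomial tail P(Binom(s, f) >= k) >= p.

    Infinite-population approximation: sampling with replacement, so the
    result upper-bounds the hypergeometric s* at any finite N.  For
    k = 1 the closed form ceil(ln(1-p) / ln(1-f)) is used (checked and
    nudged by one if floating-point put the ceiling on the wrong side);
    for k > 1, the same bracket-and-bisect as the exact solver.
    """
    if not (0.0 < frequency < 1.0):
        raise DomainError(f"frequency must be in (0, 1), got {frequency}")
    if not (0.0 < confidence < 1.0):
        raise DomainError(f"confidence must be in (0, 1), got {confidence}")
    k = CaptureQuery(0, min_captured).min_captured
    target = confidence - CONFIDENCE_GUARD
    if k == 1:
        s = max(1, math.ceil(math.log1p(-confidence) / math.log1p(-frequency)))
        while _binom_tail(s, 1, frequency) < target:
            s += 1
        while s > 1 and _binom_tail(s - 1, 1, frequency) >= target:
            s -= 1
        return s
    if _binom_tail(k, k, frequency) >= target:
        return k
    lo, hi = k, k
    while _binom_tail(hi, k, frequency) < target:
        lo, hi = hi, hi * 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _binom_tail(mid, k, frequency) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def round_to_nearest(value: int, base: int) -> int:
    """Presentation rounding (half away from zero) to a multiple of base."""
    if base < 1:
        raise DomainError(f"rounding base must be >= 1, got {base}")
    return base * math.floor(value / base + 0.5)


@dataclass(frozen=True)
class DesignTable:
    """The data behind one design-curve panel: minimal sample sizes over
    a grid of clonal frequencies (rows) and confidence levels."""

    population_size: int
    min_captured: int
    frequencies: tuple[float, ...]
    confidences: tuple[float, ...]
    frame: pd.DataFrame = field(compare=False)

    def __eq__(self, other: object) -> bool:  # frame compared by value
        if not isinstance(other, DesignTable):
            return NotImplemented
        return (
            self.population_size == other.population_size
            and self.min_captured == other.min_captured
            and self.frequencies == other.frequencies
            and self.confidences == other.confidences
            and self.frame.equals(other.frame)
        )


def design_curve(
    pop_size: int,
    frequency_grid: Sequence[float],
    confidences: Sequence[float],
    min_captured: int,
) -> DesignTable:
    """One solver run per (frequency, confidence) cell, rows ordered by
    frequency then confidence.

    Unattainable cells re-raise with their grid coordinates attached so
    a bad grid point is identifiable.
    """
    freqs = tuple(float(f) for f in frequency_grid)
    confs = tuple(float(p) for p in confidences)
    if not freqs or not confs:
        raise DomainError("frequency grid and confidence list must be non-empty")
    rows = []
    for f in freqs:
        K = subclone_count_from_frequency(pop_size, f)
        pop = Population(pop_size, K)
        for p in confs:
            try:
                res = min_cells_for_capture(
                    DesignRequirement(pop, min_captured, p)
                )
            except UnattainableRequirementError as exc:
                raise UnattainableRequirementError(
                    f"grid cell (frequency={f}, confidence={p}): {exc}"
                ) from exc
            rows.append(
                {
                    "frequency": f,
                    "subclone_count": K,
                    "confidence": p,
                    "min_captured": min_captured,
                    "min_sample_size": res.min_sample_size,
                    "achieved_probability": res.achieved_probability,
                }
            )
    frame = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return DesignTable(int(pop_size), min_captured, freqs, confs, frame)
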