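"""Numerically stable hypergeometric capture probabilities.

The central question of single-cell experimental design addressed here:
a tissue contains ``N`` cells of which ``K`` belong to a subclone of
interest; a sample of ``s`` cells is drawn without replacement.  The
number of subclonal cells captured, ``X``, follows the hypergeometric
distribution ``Hypergeom(N, K, s)``, and the design-relevant quantity is
the upper tail ``P(X >= k)`` — the probability that the sample contains
at least ``k`` subclonal cells.

Everything is computed in log space from the "short side" of the
distribution so that the same code is exact for toy populations
(``N = 5``) and tissue-scale populations (``N = 10**12``), where naive
binomial coefficients overflow and large-argument log-gamma differences
lose absolute precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Population",
    "CaptureQuery",
    "DomainError",
    "InternalConsistencyError",
    "log_pmf",
    "capture_probability",
    "tail_complement",
    "MAX_MIN_CAPTURED",
]

#: Largest supported "at least k" threshold.  The lower tail is summed
#: term by term over k terms, so k is capped to keep that sum short.
MAX_MIN_CAPTURED = 1000

#: Clamping beyond this distance outside [0, 1] indicates a bug rather
#: than last-bit roundoff.
_CLAMP_TOL = 1e-9


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InternalConsistencyError(ArithmeticError):
    """A computed probability fell outside [0, 1] by more than roundoff."""


def _check_count(name: str, value: int, minimum: int = 0) -> int:
    if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
        raise DomainError(f"{name} must be an integer, got {value!r}")
    value = int(value)
    if value < minimum:
        raise DomainError(f"{name} must be >= {minimum}, got {value}")
    return value


@dataclass(frozen=True)
class Population:
    """A tissue of ``total_cells`` cells containing ``subclone_cells``
    cells of the subclone of interest.

    Counts are plain Python integers (arbitrary precision) so that
    tissue-scale populations are represented exactly; floating point is
    used only inside the log-space routines.
    """

    total_cells: int
    subclone_cells: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "total_cells", _check_count("total_cells", self.total_cells, 1)
        )
        object.__setattr__(
            self, "subclone_cells", _check_count("subclone_cells", self.subclone_cells, 0)
        )
        if self.subclone_cells > self.total_cells:
            raise DomainError(
                f"subclone_cells ({self.subclone_cells}) exceeds "
                f"total_cells ({self.total_cells})"
            )

    @property
    def frequency(self) -> float:
        """Clonal frequency f = K / N."""
        return self.subclone_cells / self.total_cells


@dataclass(frozen=True)
class CaptureQuery:
    """A single capture-probability question: a sample of ``sample_size``
    cells, asking for at least ``min_captured`` subclonal cells."""

    sample_size: int
    min_captured: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sample_size", _check_count("sample_size", self.sample_size, 0)
        )
        object.__setattr__(
            self, "min_captured", _check_count("min_captured", self.min_captured, 1)
        )
        if self.min_captured > MAX_MIN_CAPTURED:
            raise DomainError(
                f"min_captured must be <= {MAX_MIN_CAPTURED}, got {self.min_captured}"
            )


def _log_pmf_zero(N: int, K: int, s: int) -> float:
    """ln P(X = 0) for X ~ Hypergeom(N, K, s).

    P(X=0) = C(N-K, s) / C(N, s) = prod_{i=0}^{s-1} (1 - K/(N-i)).
    By the K <-> s symmetry of the hypergeometric the same product can
    be taken over K terms instead; the shorter side is used, which keeps
    the cost at min(s, K) log1p evaluations even when the other count is
    tissue-scale.
    """
    if K == 0 or s == 0:
        return 0.0
    if s > N - K:  # sample larger than the non-subclone pool: X = 0 impossible
        return -math.inf
    t, other = (s, K) if s <= K else (K, s)
    i = np.arange(t, dtype=np.float64)
    return float(np.log1p(-other / (float(N) - i)).sum())


def _log_pmf_gammaln(N: int, K: int, s: int, x: int) -> float:
    """ln pmf via log-gamma binomial coefficients.

    Fallback base case for supports not starting at zero (s > N - K);
    adequate there because that regime only arises when the sample is a
    sizeable fraction of the tissue.
    """

    def lbc(n: int, r: int) -> float:
        return float(gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1))

    return lbc(K, x) + lbc(N - K, s - x) - lbc(N, s)


def _pmf_terms(N: int, K: int, s: int, kmax: int) -> list[float]:
    """pmf(x) for x = 0 .. kmax-1, in linear space.

    Built from the base term at the lower support bound and the exact
    one-step ratio pmf(x+1)/pmf(x) = (K-x)(s-x) / ((x+1)(N-K-s+x+1));
    every factor is an exactly-represented integer below 2**53, so each
    step costs at most a few ulps.
    """
    lower = max(0, s - (N - K))
    upper = min(s, K)
    terms = [0.0] * kmax
    if lower >= kmax:
        return terms
    if lower == 0:
        lp = _log_pmf_zero(N, K, s)
    else:
        lp = _log_pmf_gammaln(N, K, s, lower)
    p = math.exp(lp)
    terms[lower] = p
    for x in range(lower, min(kmax - 1, upper)):
        p *= (K - x) * (s - x) / ((x + 1) * (N - K - s + x + 1))
        terms[x + 1] = p
    return terms


def _validate(pop: Population, s: int, k: int | None = None) -> tuple[int, int, int]:
    N, K = pop.total_cells, pop.subclone_cells
    s = _check_count("sample_size", s, 0)
    if s > N:
        raise DomainError(f"sample_size ({s}) exceeds total_cells ({N})")
    if k is not None:
        k = _check_count("min_captured", k, 1)
        if k > MAX_MIN_CAPTURED:
            raise DomainError(f"min_captured must be <= {MAX_MIN_CAPTURED}, got {k}")
    return N, K, s


def log_pmf(pop: Population, sample_size: int, captured: int) -> float:
    """Natural log of P(X = captured) for X ~ Hypergeom(N, K, sample_size).

    Returns ``-inf`` where the mass is exactly zero (below the lower
    support bound ``max(0, s - (N - K))``).  Arguments outside
    ``0 <= captured <= min(sample_size, K)`` raise :class:`DomainError`.
    """
    N, K, s = _validate(pop, sample_size)
    x = _check_count("captured", captured, 0)
    if x > min(s, K):
        raise DomainError(
            f"captured ({x}) exceeds min(sample_size, subclone_cells) = {min(s, K)}"
        )
    lower = max(0, s - (N - K))
    if x < lower:
        return -math.inf
    if lower == 0:
        lp = _log_pmf_zero(N, K, s)
        if x == 0:
            return lp
        j = np.arange(x, dtype=np.float64)
        Nf, Kf, sf = float(N), float(K), float(s)
        lp += float(
            (
                np.log(Kf - j)
                + np.log(sf - j)
                - np.log(j + 1.0)
                - np.log(Nf - Kf - sf + j + 1.0)
            ).sum()
        )
        return lp
    return _log_pmf_gammaln(N, K, s, x)


def _clamp(p: float, what: str) -> float:
    if p < -_CLAMP_TOL or p > 1.0 + _CLAMP_TOL:
        raise InternalConsistencyError(f"{what} = {p!r} is outside [0, 1] beyond roundoff")
    return min(1.0, max(0.0, p))


def capture_probability(pop: Population, query: CaptureQuery) -> float:
    """P(X >= k): probability that a sample of ``s`` cells drawn without
    replacement contains at least ``k`` subclonal cells.

    Exactly 0 when the event is unattainable (``s = 0``, ``K = 0`` or
    ``k > min(s, K)``) and exactly 1 when it is guaranteed
    (``s >= N - K + k``); otherwise ``1 - P(X < k)`` with the short
    lower tail summed in compensated arithmetic.
    """
    N, K, s = _validate(pop, query.sample_size, query.min_captured)
    k = query.min_captured
    if s == 0 or K == 0 or k > min(s, K):
        return 0.0
    if s >= N - K + k:
        return 1.0
    lower = math.fsum(_pmf_terms(N, K, s, k))
    return _clamp(1.0 - _clamp(lower, "lower tail"), "capture probability")


def tail_complement(pop: Population, query: CaptureQuery) -> float:
    """P(X < k), the full-precision complement of :func:`capture_probability`.

    Near-certain designs have capture probabilities like 0.99999999
    whose distance from 1 is invisible in the direct value; the
    complement, summed directly from the k lowest pmf terms, preserves
    it.
    """
    N, K, s = _validate(pop, query.sample_size, query.min_captured)
    k = query.min_captured
    if s == 0 or K == 0 or k > min(s, K):
        return 1.0
    if s >= N - K + k:
        return 0.0
    return _clamp(math.fsum(_pmf_terms(N, K, s, k)), "tail complement")
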