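"""Monte-Carlo urn sampling: an independent stochastic check of the
analytic capture probabilities.

Each replicate draws ``s`` distinct cell indices uniformly from a
labelled tissue of ``N`` cells (indices ``0 .. K-1`` are subclonal) and
scores a success when at least ``k`` drawn indices are subclonal.
Distinct indices are obtained by drawing uniform integers and rejecting
duplicates — deliberately not via any hypergeometric-variate routine,
so the estimate shares no code path with the analytic model it checks.
This module must never import the analytic core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "ValidationReport",
    "simulate_capture",
    "validate_design",
    "DEFAULT_REPLICATES",
    "DEFAULT_SEED",
]

DEFAULT_REPLICATES = 100_000
DEFAULT_SEED = 42


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation setting; the seed is part of the record so every
    reported estimate is reproducible."""

    population_size: int
    subclone_count: int
    sample_size: int
    min_captured: int
    replicates: int = DEFAULT_REPLICATES
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        N, K, s = self.population_size, self.subclone_count, self.sample_size
        if N < 1 or not (0 <= K <= N):
            raise ValueError(f"invalid population: N={N}, K={K}")
        if not (0 <= s <= N):
            raise ValueError(f"sample_size {s} outside [0, {N}]")
        if self.min_captured < 1:
            raise ValueError(f"min_captured must be >= 1, got {self.min_captured}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")


@dataclass(frozen=True)
class SimulationResult:
    empirical_probability: float
    successes: int
    replicates: int
    standard_error: float
    seed: int


def _distinct_draw_hits(rng: np.random.Generator, N: int, K: int, t: int) -> int:
    """Draw t distinct uniform indices from {0..N-1} by rejection; return
    how many fall below K.  Efficient while t <= N/2 (the caller flips
    to the complement otherwise)."""
    seen: set[int] = set()
    while len(seen) < t:
        need = t - len(seen)
        for v in rng.integers(0, N, size=need + need // 4 + 1).tolist():
            if len(seen) == t:
                break
            seen.add(v)
    return sum(1 for v in seen if v < K)


def simulate_capture(config: SimulationConfig) -> SimulationResult:
    """Estimate P(at least k subclonal cells in a sample of s).

    For s > N/2 the rejection sampler would stall, so the complement set
    of N - s *excluded* cells is drawn instead and the captured count
    recovered as K minus the excluded subclonal cells.  Identical
    configs (including seed) give byte-identical results.
    """
    N, K = config.population_size, config.subclone_count
    s, k, R = config.sample_size, config.min_captured, config.replicates
    rng = np.random.default_rng(config.seed)
    successes = 0
    if s == 0 or K == 0:
        successes = 0  # no draw can ever contain a subclonal cell
    elif s == N:
        successes = R if K >= k else 0
    elif s <= N // 2:
        for _ in range(R):
            if _distinct_draw_hits(rng, N, K, s) >= k:
                successes += 1
    else:
        t = N - s
        for _ in range(R):
            if K - _distinct_draw_hits(rng, N, K, t) >= k:
                successes += 1
    phat = successes / R
    se = math.sqrt(phat * (1.0 - phat) / R)
    return SimulationResult(phat, successes, R, se, config.seed)


@dataclass(frozen=True)
class ValidationReport:
    passed: bool
    confidence: float
    at_minimum: SimulationResult
    below_minimum: SimulationResult

    def __str__(self) -> str:
        verdict = "PASS" if self.passed else "FAIL"
        return (
            f"{verdict}: p={self.confidence}, "
            f"P(s*)~{self.at_minimum.empirical_probability:.4f}"
            f"(SE {self.at_minimum.standard_error:.4f}), "
            f"P(s*-1)~{self.below_minimum.empirical_probability:.4f}"
            f"(SE {self.below_minimum.standard_error:.4f})"
        )


def validate_design(
    result,
    population_size: int,
    subclone_count: int,
    min_captured: int,
    confidence: float,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = DEFAULT_SEED,
) -> ValidationReport:
    """Check a solver result empirically: simulate at s* and s* - 1 and
    require the estimates to bracket the target confidence within three
    standard errors (the estimate at s* must not sit significantly below
    p; the estimate at s* - 1 must not sit significantly above it).

    ``result`` needs only a ``min_sample_size`` attribute, so solver
    results can be passed without importing the solver here.
    """
    s_star = int(result.min_sample_size)
    at = simulate_capture(
        SimulationConfig(
            population_size, subclone_count, s_star, min_captured, replicates, seed
        )
    )
    below = simulate_capture(
        SimulationConfig(
            population_size,
            subclone_count,
            max(s_star - 1, 0),
            min_captured,
            replicates,
            seed + 1,
        )
    )
    ok_at = at.empirical_probability >= confidence - 3.0 * at.standard_error
    ok_below = below.empirical_probability <= confidence + 3.0 * below.standard_error
    return ValidationReport(bool(ok_at and ok_below), confidence, at, below)
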