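"""Core capture-probability mathematics against brute-force and
high-precision oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, hypergeom as scipy_hypergeom

from subclone_sampler import (
    CaptureQuery,
    DomainError,
    InternalConsistencyError,
    Population,
    capture_probability,
    log_pmf,
    tail_complement,
)
from subclone_sampler.hypergeom import _clamp

from oracles import (
    TISSUE_TAIL_46050,
    exhaustive_capture_counts,
    exhaustive_capture_probability,
)


def P(N, K):
    return Population(N, K)


def Q(s, k):
    return CaptureQuery(s, k)


class TestLogPmf:
    @pytest.mark.parametrize(
        "N,K,s,x,expected",
        [
            (10, 3, 4, 0, math.log(35 / 210)),  # C(7,4)/C(10,4) by enumeration
            (17, 0, 9, 0, 0.0),  # no subclone cells: empty capture is certain
            (5, 5, 2, 2, 0.0),  # every cell subclonal
        ],
    )
    def test_exact_values(self, N, K, s, x, expected):
        assert log_pmf(P(N, K), s, x) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_across_support(self):
        N, K, s = 11, 4, 6
        counts = exhaustive_capture_counts(N, K, s)
        total = math.comb(N, s)
        for x in range(0, min(s, K) + 1):
            expect = counts.get(x, 0) / total
            assert math.exp(log_pmf(P(N, K), s, x)) == pytest.approx(
                expect, abs=1e-12
            )

    def test_zero_mass_below_support_is_minus_inf(self):
        # s=9 of N=10 with K=4: at least 3 subclonal cells always captured
        assert log_pmf(P(10, 4), 9, 2) == -math.inf

    @pytest.mark.parametrize(
        "N,K,s,x,name",
        [
            (10, 3, 4, 5, "captured"),  # x > min(s, K)
            (10, 3, 11, 0, "sample_size"),  # s > N
            (10, 3, 4, -1, "captured"),
        ],
    )
    def test_domain_errors_name_argument(self, N, K, s, x, name):
        with pytest.raises(DomainError, match=name):
            log_pmf(P(N, K), s, x)

    def test_normalization_small_populations(self):
        for N in (1, 2, 3, 7, 13, 30):
            for K in range(N + 1):
                for s in range(N + 1):
                    lo, hi = max(0, s - (N - K)), min(s, K)
                    total = math.fsum(
                        math.exp(log_pmf(P(N, K), s, x)) for x in range(lo, hi + 1)
                    )
                    assert total == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_in_K_and_s(self):
        # hypergeometric pmf is invariant under swapping drawn/marked roles
        rng = np.random.default_rng(7)
        for _ in range(200):
            N = int(rng.integers(2, 31))
            K = int(rng.integers(0, N + 1))
            s = int(rng.integers(0, N + 1))
            x = int(rng.integers(0, min(K, s) + 1))
            a = log_pmf(P(N, K), s, x)
            b = log_pmf(P(N, s), K, x)
            assert a == pytest.approx(b, abs=1e-10) or (a == b == -math.inf)


class TestCaptureProbability:
    @pytest.mark.parametrize(
        "N,K,s,k,expected",
        [
            (10, 3, 4, 1, 5 / 6),  # enumeration: 1 - C(7,4)/C(10,4)
            (10, 3, 0, 1, 0.0),
            (10, 3, 10, 3, 1.0),
            (10, 0, 5, 1, 0.0),
            (10, 3, 4, 4, 0.0),  # k beyond subclone size: unattainable
        ],
    )
    def test_examples(self, N, K, s, k, expected):
        assert capture_probability(P(N, K), Q(s, k)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_tissue_scale_worked_example(self):
        # 1e9-cell tissue, subclone at 0.01%: 46,050 sampled cells give a
        # >= 99% chance of capturing at least one subclonal cell
        prob = capture_probability(P(10**9, 10**5), Q(46050, 1))
        assert prob >= 0.99
        assert prob == pytest.approx(TISSUE_TAIL_46050, abs=1e-12)

    def test_exact_edges_are_exact(self):
        # guarantee edge s >= N-K+k must be identically 1, not 1-eps
        assert capture_probability(P(1000, 10), Q(991, 1)) == 1.0
        assert tail_complement(P(1000, 10), Q(991, 1)) == 0.0
        # one cell short of the guarantee: a tiny but strictly positive
        # miss probability, visible only through the complement
        assert 0.0 < tail_complement(P(1000, 10), Q(990, 1)) < 1e-20

    def test_enumeration_oracle_equivalence_small(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for s in range(N + 1):
                    for k in (1, 2):
                        expect = float(exhaustive_capture_probability(N, K, s, k))
                        got = capture_probability(P(N, K), Q(s, k))
                        assert got == pytest.approx(expect, abs=1e-12)

    def test_monotonicity_on_random_grids(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            N = int(rng.integers(10, 10**6))
            K = int(rng.integers(1, min(N, 10**4) + 1))
            s = int(rng.integers(1, min(N, 10**5)))
            k = int(rng.integers(1, 4))
            p = capture_probability(P(N, K), Q(s, k))
            assert capture_probability(P(N, K), Q(min(s + 1, N), k)) >= p - 1e-15
            if K + 1 <= N:
                assert capture_probability(P(N, K + 1), Q(s, k)) >= p - 1e-15
            assert capture_probability(P(N, K), Q(s, k + 1)) <= p + 1e-15

    def test_agrees_with_scipy_at_moderate_scale(self):
        # independent implementation route (scipy survival function)
        rng = np.random.default_rng(3)
        for _ in range(50):
            N = int(rng.integers(10, 10**6))
            K = int(rng.integers(0, min(N, 10**4) + 1))
            s = int(rng.integers(0, min(N, 10**4) + 1))
            k = int(rng.integers(1, 6))
            ours = capture_probability(P(N, K), Q(s, k))
            ref = float(scipy_hypergeom.sf(k - 1, N, K, s))
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_binomial_limit(self):
        # fixed f, s, k: the finite-population tail approaches the binomial
        # tail as N grows, and at tissue scale the gap is < 1e-4
        f, s, k = 1e-4, 1000, 1
        gaps = []
        for N in (10**5, 10**7, 10**9):
            K = round(f * N)
            hg = capture_probability(P(N, K), Q(s, k))
            bn = float(binom.sf(k - 1, s, f))
            gaps.append(abs(hg - bn))
        assert gaps[0] >= gaps[1] >= gaps[2]
        for s_big, k_big in ((1000, 1), (46050, 1), (100000, 3)):
            hg = capture_probability(P(10**9, 10**5), Q(s_big, k_big))
            bn = float(binom.sf(k_big - 1, s_big, f))
            assert abs(hg - bn) < 1e-4

    @pytest.mark.parametrize("k", [0, -2, 1001])
    def test_invalid_threshold_rejected(self, k):
        with pytest.raises(DomainError):
            CaptureQuery(5, k)

    def test_oversized_sample_rejected(self):
        with pytest.raises(DomainError, match="sample_size"):
            capture_probability(P(3, 1), Q(5, 1))


class TestComplement:
    @pytest.mark.parametrize(
        "N,K,s,k,expected",
        [
            (10, 3, 4, 1, 1 / 6),
            (50, 0, 10, 1, 1.0),
        ],
    )
    def test_examples(self, N, K, s, k, expected):
        assert tail_complement(P(N, K), Q(s, k)) == pytest.approx(expected, abs=1e-12)

    def test_tissue_scale_complement(self):
        assert tail_complement(P(10**9, 10**5), Q(46050, 1)) <= 0.01

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        N=st.integers(1, 60),
        K=st.integers(0, 60),
        s=st.integers(0, 60),
        k=st.integers(1, 5),
    )
    def test_complement_identity_property(self, N, K, s, k):
        K, s = min(K, N), min(s, N)
        pop, q = P(N, K), Q(s, k)
        a, b = capture_probability(pop, q), tail_complement(pop, q)
        assert 0.0 <= a <= 1.0 and 0.0 <= b <= 1.0
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_complement_identity_tissue_scale(self):
        pop = P(10**12, 10**6)
        for s in (1, 13_000_000, 46_050):
            q = Q(s, 1)
            assert capture_probability(pop, q) + tail_complement(pop, q) == (
                pytest.approx(1.0, abs=1e-12)
            )


def test_population_validation():
    with pytest.raises(DomainError, match="subclone_cells"):
        Population(5, 6)
    with pytest.raises(DomainError, match="total_cells"):
        Population(0, 0)
    assert Population(10**12, 7).frequency == 7e-12


def test_clamp_flags_gross_errors_only():
    assert _clamp(1.0 + 1e-13, "x") == 1.0
    assert _clamp(-1e-13, "x") == 0.0
    with pytest.raises(InternalConsistencyError):
        _clamp(1.1, "x")
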