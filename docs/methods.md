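# Methods

## Model

Sampling `s` cells without replacement from a tissue of `N` cells that
contains `K` subclonal cells is an urn draw; the captured subclonal
count is `X ~ Hypergeom(N, K, s)`. The design quantity is the upper
tail `P(X ≥ k)`, and the design answer is its inverse in `s`: the
minimal `s*` with `P(X ≥ k) ≥ p`.

Assumptions worth stating explicitly:

- every cell of the tissue is equally likely to be sampled (no spatial
  structure, no dissociation or viability bias);
- "captured" means "present in the sample" — sequencing the cell
  successfully is taken for granted (no capture-efficiency, doublet or
  dropout corrections);
- the subclone is a fixed fraction of a fixed tissue (no growth
  dynamics between sampling and assay).

Under these assumptions the model is exact, not asymptotic.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| `N` | total cells in the tissue | cells | 1e9 |
| `f` | clonal frequency; `K = round(f·N)`, half away from zero | fraction | — |
| `k` | minimum subclonal cells that must be captured | cells | 1 |
| `p` | target capture confidence | probability | — |
| `R` | Monte-Carlo replicates | draws | 1e5 |
| seed | RNG seed (always recorded in output) | — | 42 |

`N = 1e9` reflects a solid-tissue scale of order one billion cells;
`k = 1` answers "detect at all", `k = 3` the common requirement that a
phenotype be seen in several cells before it is believed. A positive
`f` smaller than `1/(2N)` rounds to zero cells and is rejected as
degenerate rather than silently reported as impossible.

The default design-curve grid is 25 log-spaced frequencies from 1e-6 to
1e-1 crossed with confidences {0.50, 0.90, 0.95, 0.99} at `N = 1e9`.
The confidence set is a conventional choice (the field plots these
lines routinely) and is fully config-overridable; nothing in the model
privileges it.

## Numerical strategy

Counts are handled as Python integers (so `N = 1e12` is exact at the
interface); floating point enters only inside log-space routines.

- `P(X = 0)` is the product `∏_{i<s} (N−K−i)/(N−i)`, evaluated as a sum
  of `log1p(−K/(N−i))` terms. By the `K ↔ s` symmetry of the
  hypergeometric the product can equivalently be taken over `K` terms;
  the implementation always sums the shorter side, so the cost is
  `min(s, K)` terms — small everywhere on a realistic design grid.
  Large-argument log-gamma differences are deliberately avoided: at
  `N = 1e9` they carry absolute errors around 1e-7·ln-units and at
  `N = 1e12` around 1e-3, which would corrupt tail complements.
- Higher pmf terms come from the exact one-step ratio
  `pmf(x+1)/pmf(x) = (K−x)(s−x) / ((x+1)(N−K−s+x+1))`; every factor is
  an integer below 2^53, so each step costs a few ulps. `k` is capped
  at 1000 and the tail is always obtained from the `k` lowest terms
  (`P(X ≥ k) = 1 − P(X < k)`), summed with compensated (`fsum`)
  addition — never by summing the long upper side.
- `tail_complement` returns `P(X < k)` directly so that designs with
  capture probabilities like `1 − 1e-24` keep a meaningful miss
  probability; the direct value and the complement agree to 1e-12.
- Support edges are exact by construction, not by rounding:
  `P(X ≥ k) = 0` when `s = 0`, `K = 0` or `k > min(s, K)`, and `= 1`
  when `s ≥ N − K + k`. Probabilities are clamped into `[0, 1]` after
  summation; a clamp larger than 1e-9 raises an internal-consistency
  error instead of being absorbed, to separate roundoff from bugs.
- The solver brackets `s*` by doubling from `s = k` and bisects,
  relying on monotonicity of the tail in `s`. Confidence comparisons
  use a 1e-12 guard (`accept when P ≥ p − 1e-12`); at design scales
  this never moves an integer answer, it only absorbs last-bit noise.
  Reported sample sizes are always exact; rounding (e.g. to the
  nearest thousand, half away from zero) is presentation only.
- The binomial companion uses `s* = ⌈ln(1−p)/ln(1−f)⌉` for `k = 1`
  (with a one-step correctness check against the tail, in case the
  ceiling lands on the wrong side of a float boundary) and the same
  bracket-and-bisect on `scipy.stats.binom.sf` for `k > 1`.

## Monte-Carlo validation

The simulator is an independent oracle: it draws `s` distinct cell
indices by uniform-integer rejection sampling (flipping to the
complement set when `s > N/2`) and never calls the analytic core or any
hypergeometric-variate generator, so agreement between the two routes
is evidence, not circularity. Each result records `p̂`, the success
count, `R`, the binomial standard error `√(p̂(1−p̂)/R)` and the seed.
`validate_design` re-simulates a solver result at `s*` and `s* − 1` and
requires the estimates to bracket the target confidence within three
standard errors.

The simulator emulates ideal urn sampling only. It shares the model's
assumptions above, so passing validation shows the analytics and the
urn agree — it says nothing about dissociation bias, capture
efficiency or other departures of real experiments from the urn.

## Design choices that were genuinely open

- **Exact hypergeometric versus binomial shortcut.** At `N = 1e9`,
  `f = 1e-4` the two tails differ by about 1e-6 and the minimal sample
  sizes by one cell (46,049 vs 46,050; both report as "about 46,000").
  The exact form is the implementation; the binomial is exposed
  separately as an explicitly-labelled infinite-population
  approximation.
- **Binomial-dominance caveat.** The folk rule "without replacement
  captures at least as easily", which makes the binomial `s*` an upper
  bound on the exact one, is provable for `k = 1` and holds for
  `k > 1` at design-relevant confidences (`p ≥ 0.5`). It *reverses*
  for `k > 1` at small `p`: the hypergeometric is more concentrated
  than the binomial, so when the threshold `k` sits above the sample
  mean, the binomial's heavier upper tail crosses a low bar with fewer
  draws (e.g. `N=100, K=13, k=2`: `P(X≥2 | s=5)` is 0.1248 without
  replacement vs 0.1292 with). The package documents the bound only in
  its valid regime.
- **Frequency-to-count rounding.** `K = round(f·N)` half away from
  zero, and tables always report the integer `K` actually used, so
  every row is reproducible from its own record. When rounding lowers
  the effective frequency `K/N` below `f`, the finite tissue is
  slightly *harder* than the binomial at `f`; comparisons between the
  two routes are therefore made at `K/N`.
- **Boundary reporting.** `probability_below` is evaluated at
  `s* − 1` even at the `s* = k` edge, where it is an exact 0, keeping
  the minimality property (`P(s*) ≥ p > P(s*−1)`) uniformly checkable.

## Problem sizes used in the shipped checks

Exhaustive subset-enumeration cross-checks run over all populations
with `N ≤ 12` (and pmf normalisation/symmetry up to `N = 30`);
randomized solver checks use `N` up to 1e6; the design-curve shape and
worked-example checks run at the full `N = 1e9`; Monte-Carlo
consistency uses 1e5 replicates per configuration on toy populations
where the exact answer is enumerable. These sizes make the full suite
a matter of seconds while still exercising the tissue-scale code path
exactly where the headline numbers live.

## Known limitations

- No cost model, batching or multiplexing: the answer is cells, not
  dollars or lanes.
- One subclone at a time; no multivariate (multi-clone) capture
  probabilities.
- The model stops at "the cell is in the tube": per-cell assay success
  must be folded in by the user (e.g. by inflating `s*` by the inverse
  capture efficiency of the platform).
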