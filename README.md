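# subclone-sampler

How many cells must a single-cell sequencing experiment analyse to
capture a rare subclone?

A tissue of `N` cells contains `K = round(f·N)` cells of a subclone at
clonal frequency `f`. If `s` cells are sampled without replacement, the
number of subclonal cells captured is

```
X ~ Hypergeom(N, K, s),    P(X = x) = C(K,x) · C(N−K, s−x) / C(N,s)
```

and the design question "how many cells should I sequence?" is the
inversion of the upper tail: the smallest `s*` with

```
P(X ≥ k) ≥ p
```

for a capture threshold `k` (typically 1, or 3 when several cells of a
phenotype are needed to call it) and a target confidence `p`. This
package computes the tail exactly and stably from `N = 5` up to
`N = 10¹²`, inverts it by monotone bracket-and-bisect, tabulates design
curves over frequency grids, provides the infinite-population binomial
companion (`s* = ⌈ln(1−p)/ln(1−f)⌉` for `k = 1`), and cross-checks the
analytics with an independent Monte-Carlo urn sampler. It is aimed at
anyone budgeting cell numbers for single-cell genomics, transcriptomics
or epigenomics of heterogeneous tissues and tumors.

## Worked example

A tissue of one billion cells holds an undefined stem-cell population at
0.01% (so `K = 100,000` cells). To have a 99% chance of sampling at
least one of them:

```sh
$ subclone-sampler design --population 1000000000 --frequency 0.0001 \
      --min-captured 1 --confidence 0.99 --round-to 1000 --quiet
population  subclone_count  frequency  min_captured  confidence  min_sample_size  achieved_probability  achieved_complement  probability_below  min_sample_size_rounded
1000000000  100000          0.0001     1             0.99        46049            0.990001              0.00999934           0.99               46000
```

(tabs shown as spaces). Reading the record: the exact minimum is
`s* = 46,049` cells — about 46,000 — where the capture probability first
reaches 0.99 (`achieved_probability`); one cell fewer falls just short
(`probability_below` < 0.99). `achieved_complement` is the miss
probability `P(X < k)` computed directly, which stays informative when
the capture probability is within floating-point roundoff of 1.

The forward question, and its Monte-Carlo check on a toy tissue:

```sh
$ subclone-sampler prob -N 1000000000 -f 0.0001 -s 46050 --quiet
...  capture_probability  capture_complement
...  0.990002             0.00999834

$ subclone-sampler simulate -N 10 -K 3 -s 4 -k 1 --reps 100000 --seed 42 --quiet
...  successes  empirical_probability  standard_error
...  83507      0.83507                0.00117358
```

The exact value for the toy case is 1 − C(7,4)/C(10,4) = 5/6 ≈ 0.8333;
the empirical estimate sits within two standard errors of it.

Design curves over a frequency grid (the data behind a
sample-size-versus-frequency figure; add `--plot panel.png` to render
it):

```sh
subclone-sampler curve -N 1000000000 --freq-min 1e-6 --freq-max 1e-1 \
    --freq-points 25 -p 0.5 -p 0.9 -p 0.95 -p 0.99 -k 1 -o panelA.tsv
```

All subcommands also accept `--config file` with `key=value` lines
(explicit flags win) and `--format csv`. Exit codes: 0 success, 2 flag
validation, 3 unattainable requirement, 4 I/O error.

The same operations are available as a library:

```python
from subclone_sampler import (Population, DesignRequirement, min_cells_for_capture)
res = min_cells_for_capture(DesignRequirement(Population(10**9, 10**5), 1, 0.99))
res.min_sample_size   # 46049
```

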