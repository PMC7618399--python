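# Methods

## The model

`numlot` models how often the numerals 1–99 are used in text. The core
hypothesis is compositional: a number concept is assembled from the
primitive **1** by binary **addition** and **multiplication**, and the
accessibility of a number is governed by the weight of its algebraic
expressions. Formally the grammar is a probabilistic context-free
grammar with three production weights:

- `f1` — the weight (frequency) of the leaf symbol 1, carrying the
  units of the data (parts per million for corpus tables);
- `cost_add` — the multiplicative weight of an addition node
  (dimensionless, < 1 in practice);
- `cost_mult` — the multiplicative weight of a multiplication node
  (0 disables multiplication).

An ordered binary expression tree `t` with `L` leaves, `A` additions
and `M` multiplications evaluating to `n` has

```
weight(t) = f1^L · cost_add^A · cost_mult^M
```

Two readings of "the frequency of n" are implemented:

- **shortest path**: `f_n = max_t weight(t)` — the single cheapest
  expression determines the frequency (a minimum-description-length
  reading, since the max weight corresponds to the min cost);
- **cumulative**: `f_n = Σ_t weight(t)` — every stored representation
  of `n` contributes.

Both are computed by an O(n²) recursion over top-level splits:

```
f_n = max/sum over  i + j = n            of  f_i · f_j · cost_add
      max/sum over  i × j = n, i,j ≥ 2   of  f_i · f_j · cost_mult
```

Pure addition alone predicts `log f_n` exactly linear in `n` (each
number is a chain of +1 steps) — far steeper than the observed ~1/n²
power law. Multiplication provides shortcuts to composite numbers;
their elevated frequencies propagate through addition to neighbours,
producing both the overall power-law-like decrease and the local peaks
at numbers with simple factorizations.

### Conventions

- **Ordered splits.** Additive splits run over ordered pairs
  (i, n−i), i = 1..n−1, and factorizations over ordered (i, j) with
  i, j ≥ 2. This makes the recursion *exactly* the sum/max over
  ordered binary trees, so a brute-force tree enumeration
  (`enumerate_expressions`, guarded at n ≤ 12) is an independent
  oracle for both recursions. An unordered convention would change
  cumulative values by factors of ~2 per asymmetric split; nothing
  else in the analysis depends on the choice, and fitting absorbs it.
- **No trivial factors.** `i × j = n` with i = 1 or j = 1 is excluded;
  otherwise `f_n = f_1 · f_n · cost_mult` is self-referential and the
  recursion is not well-founded.
- **Ties** in the shortest-path max are broken deterministically
  (addition before multiplication, then smallest operand) so reported
  best decompositions are reproducible; the max itself is
  tie-independent.
- **Optional primitives 5 and 10.** `primitive_overrides` replaces the
  computed `f_5`/`f_10` before larger numbers are derived, modelling
  the anatomical salience of 5 and 10 (finger counting) as extra
  grammar primitives. With overrides active the recursions are no
  longer a sum/max over trees of the three-symbol grammar, so
  `enumerate_expressions` refuses overridden parameter sets rather
  than silently disagreeing.
- Frequencies are stored in linear space in double precision. For
  n ≤ 99 and plausible parameters no underflow occurs; values below
  1e-300 raise an explicit `DegeneracyError`.

## The approximation stage

The bare grammar treats 10 like any other composite and cannot
reproduce the order-of-magnitude frequency peaks at decades: if `f_10`
were intrinsically high, `f_11 = f_10·f_1·cost_add` would be dragged
up with it, contrary to the data. The decade peaks have a different
source: round numerals are used for *approximate* quantities.

The probability that a quantity `p` is voiced as the round numeral `n`
follows the approximate-number-system convention — Gaussian in log
ratio with Weber fraction `w`:

```
P_approx(n, p) = κ · exp(−½ ((ln n − ln p) / w)²)
```

- `κ ∈ [0, 1]` scales the overall propensity to approximate and is a
  free parameter of the full model;
- `w > 0` is fixed at 0.15 by default, the standard Weber fraction
  for educated adults. The kernel uses the natural log: `w` values in
  the numerosity-perception literature are on that scale (log10 would
  merely rescale `w`, but then 0.15 would be the wrong number).

`redistribute` processes the targets (all multiples of 10 in range, by
default; 100 lies outside 1–99 and is not a sink) in increasing order.
For each target every other number donates `f_p · P_approx(n, p)` of
its *current* frequency and the target collects the total. Mass is
moved, never created: the total is conserved to floating precision,
and with κ < 1 every frequency stays positive (each donor is only ever
multiplied by factors 1 − P < 1).

Two readings of the donation semantics were possible: donations
computed from the pre-approximation frequencies for every decade, or
sequential depletion decade by decade. The sequential reading is
implemented. It is also the only safe one: in the simultaneous
reading a number midway between two decades (e.g. 85, within one
Weber fraction of both 80 and 90) can donate more than 100% of its
mass once κ exceeds ~0.5, going negative.

One consequence of taking the donor set literally (donors include
other targets) deserves note: adjacent top decades are close in log
space — ln(90/80) ≈ 0.79·w — so decades exchange mass directly, and
the processing order is substantive there, shifting `f'_80`/`f'_90`
at the percent level. For the same reason "every target gains" is a
property of realistic, power-law-shaped profiles (where it holds in
all 1000 simulated draws we checked) rather than a theorem: an
isolated spike at one decade can lose more to its neighbour decade
than it collects. Non-targets only ever donate, so their loss is
unconditional.

## Fitting

Parameters are estimated by minimizing the mean squared error between
predicted and observed log10 frequencies over the full range 1–99
(`mse_loss`). Two routes:

- **Naive closed form** (`naive_parameters`): `f1 = freq(1)`,
  `cost_add = freq(2)/freq(1)²`, and `cost_mult` from one of three
  anchors — `freq(6)/(freq(3)·freq(2))`, `freq(8)/(freq(4)·freq(2))`
  or `freq(9)/freq(3)²`. Exact if the data were generated by the
  grammar, and a good starting point otherwise; sensitive to
  `freq(1)` (in several languages "one" doubles as a determiner).
- **Derivative-free search** (`fit`): Nelder–Mead on the
  unconstrained coordinates `(ln f1, ln cost_add, ln cost_mult[,
  logit κ])`, so every evaluated candidate is valid by construction
  (no penalty terms). Loss tolerance 1e-10, at most 20 000
  evaluations per restart, 5 restarts by default — the first at the
  naive init, the rest jittered with seeded Gaussian noise (σ = 0.5
  in the transformed space). The best restart is returned, so the
  final loss never exceeds the naive-init loss. Identical seeds give
  bit-identical results. Candidates that underflow or overflow are
  assigned a large sentinel loss rather than crashing the simplex.

A global rescale of the data is absorbed exactly by the parameters
(`f1 → s·f1`, costs → cost/s rescales every tree weight by `s`), so
fit quality on the log10 scale is scale-free.

`permutation_test` assesses whether the fit quality reflects real
structure: the observed frequencies are shuffled uniformly across
positions 1..n_max (seeded), the same model is refitted to each
shuffle, and the add-one p-value `(1 + #{null ≤ observed})/(N + 1)`
is reported. The add-one estimator cannot return 0 and is the default;
an exact-fraction mode (`#{null ≤ observed}/N`) is available where a
plain `1/N`-style floor is wanted for comparison with reports that
quote it. Failed null fits count as worse than observed
(conservative).

## Corpus tables

`freq_data` builds corrected per-number frequency tables from raw
n-gram-style inputs:

1. **Numeral generation.** Spellings for en, fr, it, de, es, ru are
   produced by small per-language rules in `numerals.py`, including
   dash/space variants ("twenty-three"/"twenty three") and common
   gender variants (uno/una, un/une, один/одна/одно, ...). French
   covers 1–97 only: 98/99 need four words, beyond the 5-gram window
   of the corpus interface this package mirrors. The Russian variant
   list is curated best-effort (nominative forms only). Keeping the
   spellings as reviewed code rather than generated data files makes
   the fixtures reproducible and diffable.
2. **Year averaging.** Per-year frequencies are averaged
   arithmetically over an inclusive window (default 1950–2000);
   missing years are dropped from the denominator rather than
   zero-filled, since n-gram services omit zero years inconsistently.
3. **Variant merging.** A value's frequency is the sum over all its
   surface forms; missing forms count zero with a logged warning.
4. **Containment correction.** N-gram counts double-count numerals
   that occur inside longer numerals (every "twenty-two" also counts
   as one "twenty" and one "two"). The correction subtracts, from each
   numeral's raw frequency, the raw frequencies of every other
   in-range numeral whose token sequence contains it. Containment is
   token-level (whole component words, contiguous), never substring
   level — "six" does not match inside "sixty". The correction is a
   single pass over raw values, not iterated. A corrected value ≤ 0
   raises an error naming the value: on well-formed inputs the
   contained occurrences are a subset of the container counts, so a
   non-positive result signals malformed input.

The optional `fetch_ngrams` adapter queries the public n-gram service
live (stdlib urllib, JSON cache on disk, Arabic-numeral digit queries
skip the correction since each digit string is one token). It is a
convenience for online use; nothing else depends on it and its tests
are fully mocked.

## Statistical analyses

All regressions are OLS with intercept on log10 frequency
(statsmodels), two-sided t-distribution p-values, no multiple-testing
correction. Implemented analyses:

- log-log magnitude regression (the power-law slope);
- divisibility regression: log10 magnitude plus indicator variables
  for divisibility by 10, 5, 3, 2, 7 — both the full simultaneous
  model and a sequential-entry (hierarchical) mode, since the two
  reporting conventions give different coefficients for correlated
  indicators (div10 implies div5 and div2);
- multiplicity regression: prime exponents of 2, 3, 5, 7 instead of
  indicators, optionally retaining div10 (default: retained), with
  `compare_aic` declaring improvement only below the working
  threshold ΔAIC < −10;
- an optional word-length covariate (characters of the canonical
  spelling including dashes and spaces);
- paired contrasts on log10 differences pooled across languages, with
  canned sets: {24 vs 26, 36 vs 34}, {84 vs 86, 96 vs 94},
  {10n+1 vs 10n+2} and {10n+1 vs 10n+3} (n = 1..9; six languages
  give df = 53). Zero-variance difference vectors raise an explicit
  degenerate-contrast error;
- cross-language Pearson correlations of log10 profiles on the
  intersection of value ranges (French truncates to 97);
- the "about n" vs "exactly n" phrase contrast: each context is
  normalized to sum to one over n (zero cells dropped with a
  warning) and paired t-tests compare the per-number log10
  differences for the round class {10n, 10n+5} and the near-decade
  class {10n±1}. The sum-to-one normalization is one reading of
  "following normalization"; it makes the two contexts comparable as
  distributions over numbers.

## Synthetic data

The generators in `synthetic_data` stand in for live corpus queries
and carry known ground truth:

- `simulate_frequencies` draws `f_n = prediction · 10^ε`,
  ε ~ N(0, σ²), i.e. lognormal multiplicative noise. This matches the
  MSE-on-log10 fitting criterion, making the fit the maximum-
  likelihood estimator under the generator. Default σ = 0.1.
- Default ground truth: cumulative model with `f1 = 800` ppm,
  `cost_add = 3e-4`, `cost_mult = 3e-5`, κ = 0.25, w = 0.15 — chosen
  by fitting the model once to the canonical empirical shape
  (a 1/n² ppm profile with decade peaks roughly an order of magnitude
  high) and rounding to one significant digit. With these values the
  synthetic tables show a log-log slope near −2 and the
  divisibility-by-10 signature appears only after the approximation
  stage, mirroring the qualitative pattern in real corpus tables.
- `simulate_raw_ngram_table` is the constructed inverse of the
  containment correction: each numeral's raw total is its corrected
  frequency plus the *raw* totals of every numeral containing it
  (recursion over the containment DAG — with nested chains like
  dix ⊂ dix-sept ⊂ soixante-dix-sept the inverse of a single-pass
  raw-value subtraction must add raw, not corrected, container
  totals). Totals are split across spelling variants in seeded
  proportions from [0.3, 0.7]; merging restores them exactly, so the
  round trip is exact by construction.
- `make_phrase_fixture` plants a specified log10 "about"-excess on
  the round class over a smooth 1/n baseline with small seeded noise
  (σ = 0.02, enough to keep paired t-tests non-degenerate). The
  sum-to-one normalization in the contrast dilutes the recovered
  class difference below the planted value by
  `log10(1 + s·(10^effect − 1))`, `s` the class's mass share —
  boosting one class's shares necessarily depresses the rest.

What the generators do *not* emulate: year-by-year corpus dynamics,
cross-language lexical idiosyncrasies (synthetic "languages" differ
only by noise seed), genre composition, and any systematic deviation
of real usage from the grammar-plus-approximation model. Passing
tests therefore demonstrate that the machinery recovers planted
structure under the model's own assumptions, not that the model is
true of any corpus.

## Problem sizes and numerical choices

The test suite and the acceptance script run the oracle comparison at
50 parameter draws × n ≤ 12 (tree enumeration beyond 12 grows
combinatorially), conservation at 100 random draws, recovery at
5–10 optimizer seeds per variant with 2 jittered restarts each, and
the permutation floor at N = 99 shuffles — sizes chosen so the whole
pipeline re-runs from scratch in a few minutes on one CPU while
keeping every check at its stated tolerance. The permutation null in
actual analyses defaults to N = 1000.

## Known limitations

- Numbers above 99 (and multi-word contexts like "two hundred") are
  out of scope throughout.
- The shortest-path loss surface has kinks (a max of smooth pieces);
  Nelder–Mead handles it in practice but gradient methods would not.
- The naive closed form is undefined when any anchor frequency is
  missing or non-positive.
- `enumerate_expressions` is exponential in n and guarded at n ≤ 12.
- The approximation stage's processing order matters at the percent
  level for the top decades (see above); increasing order is the
  defined semantics.
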