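# Methods

## Model and procedure

`dmpenrich` tests whether a probe set is enriched for overlap with each
reference sample's regulatory intervals relative to an annotation-matched
random background. The null being rejected, per sample, is "the test probes
overlap this sample's hotspots no more often than random array probes with
the same gene-model and CpG-island composition".

**Overlap definition.** A probe is a point: its 1-based manifest coordinate
`pos` converts to the 0-based position `pos − 1`, and it overlaps a 0-based
half-open interval `[start, end)` iff `start ≤ pos − 1 < end`. Tracks are
sorted and merged (overlapping or abutting intervals coalesce) before
indexing, so a probe contributes at most one overlap per sample — the store
records presence/absence, not counts. Chromosome names must use the `chrN`
dialect; bare names are rejected rather than silently coerced, because a
mixed-dialect store would mask real overlaps as zeros.

**Background bins.** Probes are stratified by 7 gene categories × 3 CpG
categories = 21 bins. The raw island annotation's shores and shelves
(N_Shore, S_Shore, N_Shelf, S_Shelf) merge into one `Shore_Shelf` stratum so
each bin keeps a usable pool; empty gene annotation maps to IGR and empty
island annotation to open sea. On the real 450k manifest every bin holds
over a thousand probes; for small synthetic manifests the minimum-pool check
is a (configurable) warning, not an error. Real manifests list multiple
semicolon-separated gene groups per probe; the reader collapses them with a
pluggable reducer, by default the first listed group (deterministic and
order-stable).

**Input handling.** Probe-ID and BED inputs are auto-detected per line;
mixing formats in one file is an error. BED records resolve to probes by
exact coordinate match (`(chrom, pos − 1, pos)`). Off-array probes are
excluded and reported, not fatal. The proximity filter visits probes in a
random order and keeps a probe only if it lies ≥ 1,000 bp (configurable)
from every probe already kept on that chromosome — "within 1 kb" excludes,
exactly 1 kb survives. The filter applies to the test set only; backgrounds
are matched on annotation, not spacing. The recommended size bounds
(20–1,000 analyzable probes) are enforced in strict mode and downgraded to a
warning in lenient mode, since they encode statistical advice rather than a
precondition of the computation.

**Background sampling.** Each of the `n_sets` (default 1,000) background
sets draws, per bin, exactly as many probes as the test set holds in that
bin, uniformly without replacement from the bin's pool excluding the test
probes themselves (so the null cannot contain the signal); draws are
independent across sets, and a probe may recur in different sets. Uniform
subsets are realized as the `c` smallest of i.i.d. uniform keys per set,
which is exactly uniform over `C(P, c)` subsets and vectorizes over the
1,000 sets.

**Test statistic.** With `k` the test-set overlap count, `n` the test-set
size, and background counts `b_1..b_S`, the success probability is the
pooled background proportion `p0 = Σ b_s / (S·n)`. The p-value is the
one-sided upper tail `P(X ≥ k)` for `X ~ Bin(n, p0)`, evaluated in log
space: `log pmf(i) = lnΓ(n+1) − lnΓ(i+1) − lnΓ(n−i+1) + i·ln p0 +
(n−i)·ln(1−p0)` combined by log-sum-exp over `i = k..n`. This is exact to
floating precision (checked against an exact rational oracle to 1e−10
relative over all `k, n ≤ 60`) and never underflows for `p0 > 0`. The
Z-score is `(k − mean(b)) / sd(b)` with the sample (ddof = 1) standard
deviation; a degenerate background (sd = 0) yields 0 when `k` equals the
common value and a signed-infinity sentinel otherwise. Edge cases: `p0 = 0`
is floored at half a pseudo-count, `1/(2·S·n)`, so enrichment over an empty
background is reportable; `p0 = 1` forces p = 1.

The pooled-`p0` parameterization is one reading of an under-specified
design; it uses all background draws, reduces the estimator's noise to
negligible levels (s.e. ≈ √(p0(1−p0)/(S·n))), and is isolated behind a
single function should an alternative (e.g. per-set empirical tail) be
preferred.

**Multiple testing and tiers.** p-values are corrected across the samples
selected for the run — one panel, one family, matching how per-panel plots
are read. Benjamini–Yekutieli (step-up with the harmonic inflation
`c(m) = Σ 1/i`) is the operative correction because DHS landscapes of
related cell types are strongly dependent; Benjamini–Hochberg is co-reported
diagnostically, and BY ≥ BH holds elementwise. Tiers are assigned from the
BY q-value alone: red `q < 0.01`, pink `0.01 ≤ q < 0.05`, blue otherwise.
The plot shows −log10 of the *uncorrected* binomial p (matching the table's
Pvalue column) with points colored by BY tier and dashed lines at the raw-p
boundaries implied by the family's q = 0.05 / 0.01 step-up thresholds.

## Storage

Bitstrings live in a single-file SQLite store: a `store_info` table with a
format-version tag, a global probe-order table, per-dataset sample-metadata
rows, and one `bits_<dataset>` table mapping probe id → bitstring over that
dataset's samples. Loading verifies the version tag and runs SQLite's
integrity check so truncation surfaces as an error rather than silent
corruption; appending a panel only adds tables/rows and is rejected if the
probe universe differs. Any single-file keyed store would satisfy the same
round-trip and append contracts; SQLite was chosen for concurrent-read
robustness and zero dependencies.

## Synthetic studies

The fixture generator emulates only the structure the method consumes.
Probes are placed uniformly (≥ 2 bp apart, by sampling odd coordinates
without replacement) on a toy genome — default 3 chromosomes × 10 Mb with
5,000 probes, small enough for quadratic brute-force oracles yet large
enough that every bin pool covers the matched-sampling demand — with bin
labels multinomial (or exact-quota) over the 21 bins. Each of the default
20 samples covers each probe independently with probability π0 = 0.1 (a
planted sample covers a designated subset with π1 = 0.8 instead), emitting
an interval of random 50–500 bp width containing the probe at a random
offset; intervals are then merged. Ground truth (realized coverage, planted
sample and probes) is written from the same random draw that generated the
data, never re-estimated.

What the fixtures do **not** model: spatial correlation of coverage between
nearby probes (the 1-kb filter removes its relevance at test scale),
bin-dependent coverage rates (real DHSs concentrate at islands/promoters),
probe-type chemistry, and real DNase signal structure. Passing tests
therefore demonstrate correctness of the machinery and calibration under
independence, not performance on consortium data. One consequence of the
interval widening is a small "collateral" coverage of probes that happen to
sit near a drawn probe; at the default probe density this inflates realized
coverage by well under one percentage point and is shared by test and
background sets alike.

All randomness flows through one explicitly seeded generator family
(numpy's PCG64 via `default_rng`), whose identity is recorded in run logs
and truth records; a fixed seed reproduces every output byte-for-byte.

## Calibration at protocol scale

The null false-positive benchmark follows the published protocol shape —
random probe sets of sizes {5, 10, 15, 20, 30, 40, 50, 100} — scaled to the
synthetic panel (504 sets × 20 samples = 10,080 sample tests, versus
8,000 × 299 = 2,392,000 in the original; the bookkeeping pass reproduces
that total against a 299-sample stub panel). A caveat worth stating
explicitly: with only m = 20 samples the BY rank-1 rejection threshold is
0.01/(20·H₂₀) ≈ 1.4e−4 per test, large enough that over ~10⁴ honest null
tests the *expected* number of q < 0.01 calls is of order 0.5 — at m = 299
the threshold (≈ 5e−6) is small enough that binomial discreteness suppresses
such calls almost entirely, which is the regime the original zero-count
result lives in. The scaled-down benchmark is therefore a calibration check
(BY counts must not exceed BH, q < 0.05 rates must stay at the per-mille
level), not a guaranteed zero; individual seeds can and occasionally do
produce one or two genuine extreme tail draws.

## Numerical and design notes

- Tail summation is O(n − k) per test with n ≤ 1,000; no truncation is
  applied, and the log-sum-exp result is clipped at ln 1 to absorb rounding.
- BH/BY q-values come from `statsmodels.multipletests`; tests verify them
  against a direct step-up implementation of the definitions.
- TSV floats use shortest-round-trip (`repr`) serialization, so re-parsing
  reproduces the fitted values exactly; rows sort by tissue then cell,
  alphabetically.
- Determinism contract: `(inputs, parameters, seed)` fully determine every
  output byte, including the background draw, the proximity filter's visit
  order, and the TSV.
- Known limitations: one genome assembly per store (no liftover); no
  hypergeometric alternative (the binomial's speed is the point); depletion
  is visible as negative Z but not separately tested; backgrounds are not
  matched on covariates beyond the 21 bins (e.g. CpG density or probe
  chemistry).
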