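# Methods

## Model and procedure

`mdnorm` compares two single-chromosome Hi-C contact maps held at a common
bin resolution *X*. Each map is a sparse upper-triangular set of
interaction frequencies IF over bin pairs. The joint analysis is
distance-centric: a bin pair at matrix indices (i, j) has unit-length
distance D = j − i, so each value of D indexes one off-diagonal of the
matrix, along which interaction frequencies are roughly exchangeable.

For every pair present in both maps the MD representation carries
M = log2(IF2/IF1), D, and A = (IF1 + IF2)/2. The procedure is:

1. **Join.** By default only pairs with both IFs positive are used
   (`drop_any_zero`): a zero cannot be distinguished from missing data.
   `keep_partial_zeros` carries one-sided pairs for bookkeeping with M
   undefined; such records never enter fitting or testing and pass through
   normalization unmodified.
2. **Trend fit.** Loess of M on D: at each query distance the
   ⌈span·n⌉ nearest points by |D − d| are fit with a local polynomial
   (degree 1 by default) under tricube weights
   w = (1 − (|D−d|/h)³)³, h being the largest neighbor distance. All
   records sharing a distance enter individually; since the weight depends
   only on D, the weighted least squares collapses onto per-distance counts
   and M-sums, making each query O(number of distinct distances). The fit
   is evaluated at every observed distance; no interpolation is ever
   needed because D is integral.
3. **Joint normalization.** IF1 is multiplied and IF2 divided by
   2^{f(D)/2}. Per pair this conserves log2 IF1 + log2 IF2 (the geometric
   mean) exactly in exact arithmetic; the implementation verifies the
   residual below 1e−9. Either normalized IF falling below one drops the
   whole pair — a pair with one unusable side is unusable for a ratio
   statistic, and dropping the pair keeps the table well-formed.
4. **Testing.** Z = (M − M̄)/σ_M with M̄, σ_M estimated from the
   chromosome's M values *after* removing pairs with A < A_min; removed
   pairs get Z = 0 and status `filtered` (explicitly untested, never p = 1).
   Two-sided standard-normal p-values; Benjamini–Hochberg applied
   independently within each distance stratum by default, or per
   chromosome; Holm/Bonferroni/none available. Calls are p_adj < α.

The assumptions, in order of importance: most pairs are unchanged between
the datasets (otherwise the loess fit absorbs biology into f); after
normalization M is approximately normal with a distance-stable variance;
tests are approximately independent within a distance stratum (BH is used
in its standard form).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `span` | 0.75 | fraction of points per local window. 0.75 is the classical loess default and sensible for small tables; for dense chromosome-scale tables (10⁴–10⁵ points) cross-validated selection (`span_candidates`, `select_span`, CLI `--span auto` over 0.1/0.2/0.4/0.75) is preferred, since large spans buy negligible variance reduction at a real bias cost. |
| `degree` | 1 | local polynomial degree. Degree 1 is robust in the sparse large-D tail; degree 2 available. |
| `A_min` | 15 | minimum average expression to test a pair (counts). Low-A ratios are supported by few reads; their M is noisy and their Z would be anticonservative. The threshold is deliberately user-facing. |
| `alpha` | 0.05 | significance level on adjusted p-values. |
| `adjust_scope` | per_distance | each off-diagonal is a family; IFs at a common distance are comparable, making stratified FDR the natural default. |
| `min_stratum_size` | 0 (off) | optional merging of strata with fewer tested records into the nearest larger-D stratum before BH; off by default (strict per-distance). |

## Synthetic data: what it emulates and what it does not

The generator draws, for each upper-triangular pair at distance D,
negative-binomial counts with mean μ(D) = c·(1+D)^(−α) (floored at 1e−6)
and size θ, independently per dataset; dataset 2's mean is multiplied by
`depth_ratio · bias_fn(D)`, whose log2 is the ground-truth trend that the
normalization should remove. Entries are independently zeroed with
probability π. An optional checkerboard (alternating blocks of size
`block_size`, same-compartment means scaled by 1 + strength, opposite by
1 − strength) provides A/B-like structure for compartment analyses.

Defaults (one chromosome, "chrS"): n_bins = 250 at 1 Mb (a human
chromosome-1-scale map), c = 2·10⁵, α = 1, θ = 60, π = 0.05,
depth_ratio = 1, no bias, no blocks. The depth and dispersion were chosen
to emulate deeply sequenced replicate pairs of the kind used for
controlled-difference benchmarking: with Var(M) ≈ (2/ln²2)(1/θ + 1/μ),
these values give a replicate-level σ_M ≈ 0.27 that is nearly constant
across distances — the regime in which detecting a fold-change-2
difference (|M| = 1) under stratified FDR is hard but possible, and in
which M is approximately normal at every distance, matching the method's
stated operating assumptions.

What the generator does *not* model: TADs and loops, restriction-fragment
and GC/mappability biases, copy-number structure, trans contacts, and the
long-range correlation of real Hi-C noise. Passing tests on this data
therefore demonstrate the statistical machinery (bias removal,
calibration, power, compartment preservation) under the method's
assumptions — not performance on any real dataset.

Bias presets (`default_bias_library`): `flat` (f ≡ 0), `global_shift(k)`
(f ≡ k, a pure depth imbalance), `linear_in_logD(a, b)`
(f = a + b·ln(1+D), a smooth monotone technology bias), and
`sinusoidal(amp, period)` (an oscillating local irregularity).

## Numerical choices

- σ_M uses the sample (n−1) normalization; at the n involved (10³–10⁵)
  the population/sample distinction is far below every other error term,
  but the choice is pinned here.
- The test is two-sided: gains and losses of interaction are equally
  interesting.
- Loess tie and degeneracy handling: points exactly at the bandwidth edge
  receive zero weight, so tie-breaking among equidistant neighbors cannot
  change the fit; a zero bandwidth (all selected points at the query
  distance) degenerates to the local mean, as does a singular local design;
  a table whose records all share one distance is an error.
- Span selection shuffles record indices with a seeded generator and is
  deterministic given the seed; ties in CV error go to the earlier
  candidate in the list.
- BH is computed with the textbook step-up arithmetic (p·n/rank, reverse
  cumulative minimum, clipped at 1) rather than via a library call, so the
  adjusted values equal the step-up formula to the last bit; library
  implementations group the division differently and differ in the last
  ulp.
- MCC is the direct formula with the 0-when-degenerate convention.
- Pearson correlations of compartment profiles are clamped to exactly ±1
  when within 1e−12, so identical profiles score exactly 1.
- Injected benchmark IFs are kept as floats (averaging produces halves);
  the side multiplied by the fold change is chosen uniformly at random per
  entry to avoid a directional bias in the benchmark.
- Written float IFs carry 12 significant digits (round trips agree within
  1e−9 relative); integer tables round-trip exactly.

## Design choices where the design was open

- Diagonal (D = 0) records are retained by default; an off-diagonal-only
  analysis can be had by filtering D ≥ 1 beforehand.
- Duplicate (bin1, bin2) keys in an input file are a hard error rather than
  being summed: summing silently hides upstream binning bugs.
- The two estimator classes follow scikit-learn conventions (constructor
  params, `fit`/`transform`/`predict`, trailing-underscore fitted state)
  but operate on domain tables rather than feature matrices; they do not
  compose with `sklearn.Pipeline`.
- Per-distance strata with very few tests can yield coarse BH families;
  the optional merging rule exists for that case but strict per-distance
  correction is the default behavior.
- The compartment pipeline (observed/expected, correlation, leading
  eigenvector, sign = A/B) is the standard construction; bins with zero
  marginals are masked, not imputed, and eigenvector sign is aligned
  before profiles are compared.

## Problem sizes used by the automated analyses

The shipped analyses run at n_bins = 250 (join/benchmark/conservation,
~3·10⁴ pairs), n_bins = 500 (trend recovery and null calibration,
~1.1·10⁵ pairs), and n_bins = 200 with 20-bin blocks for compartment
preservation. These sizes give Monte-Carlo error comfortably below the
assertion margins while keeping a full run in seconds.

## Known limitations

- Pairwise only: no multi-replicate or multi-condition designs.
- Cis only: trans (inter-chromosomal) contacts have no distance and are
  out of scope.
- The normal approximation for Z degrades for shallow data (low μ), where
  the count ratio is heavy-tailed; raise `A_min` accordingly.
- Very sparse high-resolution matrices (few non-zero pairs per distance)
  limit the loess fit; the method is most reliable at resolutions where
  most distances carry many non-zero pairs.
- A true biological difference affecting a large fraction of pairs at one
  distance would be partially absorbed into f(D).
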