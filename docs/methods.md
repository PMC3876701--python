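# Methods

## Library model

A sequenced library is a sparse multiset: the list of observed unique
sequences (equal length L; DNA inserts of L = 21 throughout the pipeline)
and a non-negative integer copy-number vector aligned with it. Zero counts
are representable — an observed absence is information — but are excluded
from the unique-sequence count. The theoretical diversity N (4^L or 20^L)
is metadata only; no operation requires dense indexing over the full
sequence space, so a library with millions of reads is handled in memory
regardless of N.

## Sampling operator

`sample` draws `round(f*m)` element instances uniformly without
replacement from the m instances of the library (banker's rounding for
the draw size; the choice only matters when f*m is exactly half-integral).
The resulting count vector is multivariate hypergeometric. Draws use
numpy's `multivariate_hypergeometric` with the marginals decomposition,
whose cost scales with the number of unique sequences rather than with m;
10,000 draws over 5,000 sequences take seconds. Binomial thinning is *not*
an acceptable substitute: it violates read-count conservation, and
conservation is what couples the elements of the vector.

Two structural properties are asserted on every draw: the sampled total
equals the draw size, and no element exceeds its source count (sampling
cannot create sequences). Fixing the seed makes any draw reproducible;
different seeds give independent draws.

`enumerate_outcomes` is the independent exact oracle: it enumerates every
integer vector B with 0 <= B_i <= n_i and sum(B) equal to the draw size,
with probability prod C(n_i, B_i) / C(m, draw). It is exact integer
combinatorics (no scipy), guarded to small multisets (default total <= 30),
and exists so that the simulation path can be validated against it by
goodness-of-fit rather than the two routes sharing code. For multisets too
large to enumerate jointly, per-element marginals are validated against
the univariate hypergeometric law instead.

## Confidence bands

`confidence_interval` applies the sampling operator k times and brackets
each sequence's count. Two estimators are exposed:

* **minmax** (default, k = 10,000): the minimum and maximum count seen in
  k draws. This is the estimator used for the censorship tables. Its
  effective coverage depends on k: for a fresh draw, the expected number
  of elements falling outside the band is about 2·N_c/(k+1), where N_c is
  the number of elements whose marginal is quasi-continuous (count sd well
  above 1). Whole-vector containment of a fresh draw therefore requires
  k >> 2·N_c/0.01; with k = 5,000 and 1,000 ramp elements the
  whole-vector containment rate is only ~0.7, and this is a property of
  the estimator, not an implementation artifact. Per-element coverage is
  ~1 − 2/(k+1), which is what the censorship false-positive budget uses.
* **quantile**: symmetric empirical quantiles at a stated level, with
  integer outward rounding. Provided because minmax conflates its nominal
  "99.9%" label with an order statistic whose coverage drifts with k.

Bands are always built from the pre-filtering library at the *measured*
fraction f = sum(after)/sum(before).

## Censorship detection

Given aligned before/after libraries and a band built at the measured f,
each sequence is classified: `undetermined_low_copy` when the
before-count is below 10 (at such depths a complete disappearance is
compatible with random sampling, so the bias is undefined and fixed at 1);
`within_band`; `censored_below` with B = after/(f·before) when the count
falls under loC; `above_band` (apparent enrichment) flagged for
diagnostics with B kept at 1, since the bias model quantifies only the
loss direction. The ranked report sorts by ascending B (strongest
censorship first), breaking ties by descending before-count then sequence,
and includes the peptide translation and fold-loss 1/B.

The estimator B = after/(f·before) is consistent but binomially noisy:
its relative standard deviation is sqrt((1-p)/(p·n)) with p ≈ f·B, so at
B = 0.01 and n = 1,000 the relative sd is ~33%. Tests of magnitude
recovery therefore bound the median relative error (30%) plus a
per-element 4-sigma binomial envelope, rather than demanding a fixed
relative accuracy from every element.

## Quality model and filtering

Phred+33 decoding (offset configurable for legacy +64 data); per-base
accuracy 1 − 10^(−Q/10); cumulative read accuracy is the product of
per-base accuracies over the 33-nt window — matching the worked algebra
(0.95^33 ≈ 0.18; 27 perfect bases with five Q=13 bases give 0.77) — not a
sum of raw Q values. Filtering styles: minimum-Phred (style A), cumulative
accuracy (style B), and their conjunction (style C), all evaluated on the
33-nt window only. The "^1n" convention (discard reads containing a
Phred = 0 base) is implemented as min Q >= 1, which coincides for integer
scores. Filtering monotonicity (a stricter cutoff yields an element-wise
sub-multiset) follows directly and is property-tested.

Adapter handling: a read is `perfect` only when the upstream constant
region occurs exactly and the 12-nt GGGS-encoding tail matches exactly at
the expected offset. Damaged adapters are recognized within a small edit
distance (edlib) purely for accounting — such reads carry elevated error
rates and are never rescued. The default adapter sequences are
placeholders (any 12-nt tail must translate to GGGS; alternatives are
accepted via configuration) because the true vector sequences are
experiment-specific.

## Synthetic data generator

The generator emulates the features the analysis is sensitive to:

* **copy-number law** — "ramp" (1..n_unique; the 1,000-element ramp totals
  500,500 reads), log-uniform between chosen bounds (real libraries span
  six or more orders of magnitude), or explicit counts;
* **quality** — all positions at `base_quality` (default 40) except
  planted degradations at `low_quality_q` (default 2, below any cutoff in
  use);
* **censorship** — a censored sequence loses each read independently with
  probability 1 − B through degraded quality at 3-4 fixed window
  positions, mirroring the observation that censored reads carry
  low-quality scores clustered at a few specific nucleotides;
* **background** — `degraded_read_rate` gives any read one randomly
  placed sub-cutoff position (default 0; set to 0.1 to reproduce the
  typical ~10% read loss between a permissive and a Phred-13 filter), and
  `flawed_adapter_rate` corrupts one upstream-adapter base.

Under min-Phred filtering every degraded read fails and every clean read
passes, so a sequence with planted bias B survives per-read with
probability B·(1 − d): the planted B is exactly the bias the detector
should recover. Because reads fail independently, the per-sequence
surviving count is Binomial(n_i, p_i); `planted_survival_counts` draws
from that law directly, which is distributionally identical to writing
FASTQ, ingesting and filtering, and is used for deep-library tests where
materializing millions of read records would dominate runtime. A test
cross-checks the two routes on the same specification.

What the generator does *not* model: PCR and growth biases, indels,
position-dependent quality decay along the read, or any mechanistic cause
of censorship inside the sequencer — planted censorship is a stand-in
with matching observable consequences. Passing the planted-recovery tests
therefore demonstrates the statistical machinery, not the biology of real
censored reads.

## Problem sizes and numerical choices

Default test and demo scales — toy 4-element multiset, 1,000-element ramp,
5,050-sequence planted-censorship library with ~7 million total reads via
the binomial route, k = 10,000 band draws — were chosen so the full chain
exercises realistic regimes while the whole suite runs in well under a
minute of Monte-Carlo time. Chi-square goodness-of-fit tests run at
alpha = 0.001 with 100,000 draws; total-variation checks use 50,000 draws.
All stochastic tests fix seeds, chosen by convention (0, 1, small
integers) before the tests were first run. Degenerate inputs are defined,
not special-cased: f = 0 yields the zero vector, f = 1 the identity,
zero-count elements always sample to zero, and an empty library is a
valid multiset everywhere except where a mean over reads is undefined.
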