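# Methods

## Model

`bmprev` estimates the size of a chronic-disease population by the
benchmark-multiplier method. The *benchmark* N̂ₓ is the absolute count of a
specific, well-enumerated subgroup — here persons who received a
disease-modifying therapy (DMT) within the index year, from a
reimbursement registry. The *multiplier* π̂ is that subgroup's share of the
whole disease population, estimated from a dataset of size *n* taken to
reflect the target population. The naive estimator N̂ₓ/π̂ is biased upward
because π̂ is estimated; the bias-corrected form subtracts a term of order
1/n:

    total = N̂ₓ/π̂ − (1/n) · N̂ₓ · (1/π̂ − 1)

Rates are reported per 100,000 persons at risk. The method assumes (i) the
benchmark enumerates its subgroup exhaustively (after augmentation, below),
(ii) the multiplier dataset is representative of the target population, and
(iii) the subgroup definitions coincide exactly across the two sources.

Algebraically the corrected estimate equals N̂ₓ·[(1/π̂)(1 − 1/n) + 1/n],
which is strictly positive for every valid input (n ≥ 1, π̂ ∈ (0, 1]); a
defensive floor at zero exists in the code but cannot bind. At π̂ = 1 the
estimate equals N̂ₓ exactly, so π̂ = 1 is accepted while π̂ = 0 is rejected.
Estimates are kept unrounded internally; rounding to whole persons or to
multiples of 50 happens only in reports, because the resampling engine
needs raw replicates.

## Benchmark augmentation

When the benchmark source covers only part of its subgroup (e.g. a
reimbursement registry with a ~65% market share), it is complemented with
pseudo-records before estimation. A reference source that sees the whole
subgroup carries a boolean flag marking which of its records fall inside
the benchmark's covered universe. For each cell of a user-chosen
cross-classification (default: region), coverage = flagged/total among
reference records, and the benchmark cell is scaled to
`round(observed / coverage)` by replicating its own records round-robin in
`person_id` order (remainder to the lowest ids). This is deterministic —
no random number generator — and idempotent: re-running with coverage
recomputed on the output finds coverage 1 and changes nothing.
Pseudo-records are marked `pseudo=True` and keep derived, unique ids. A
cell with benchmark records but no reference records falls back to the
global coverage with a warning; an estimated coverage of zero in a
nonempty cell is an error, since no finite scaling exists.

## Uncertainty propagation

Both N̂ₓ and π̂ are treated as uncertain. Each is assigned a uniform
sampling distribution centred on its point value with a relative half-width
δ (default 0.05 for both, a deliberately conservative band wider than the
observed between-source disagreements of roughly 1–2%). Per replicate,
values are drawn, the bias-corrected estimate is computed separately per
5-year disease-duration stratum with the global n, and stratum estimates
are summed; the default run repeats this 100,000 times. The reported
interval is the empirical percentile interval of the replicate totals with
linear interpolation between order statistics (the simplest defensible
reading of a resampled distribution; the same quantile convention is used
everywhere, including interquartile ranges in dataset comparisons).

Two sharing modes govern how draws relate across strata:

* **independent** (default): every (stratum, parameter) pair draws its own
  deviations per replicate. Across K similar strata the relative 95%
  half-width of the total then shrinks like 1/√K. With δ = 0.05 and the
  ~5 effective duration strata of the use case this yields a half-width of
  ~3.5% of the midpoint, which is what the published interval shows; a
  shared draw cannot produce an interval that narrow at δ = 0.05, which is
  why independent is the default even though the original analysis does
  not state the choice explicitly.
* **shared**: one unit deviation u ∈ [−1, 1] per parameter per replicate is
  applied to every stratum's centre via c·(1 + δu). This models fully
  correlated parameter uncertainty; with identical strata each replicate
  total is exactly K times a single-stratum evaluation.

The multiplier sample size n is held fixed across strata and replicates at
the full multiplier-dataset size; stratum-specific n values are not
identifiable from the available summaries. A single global π̂ centre is
applied per stratum by default, though strata can carry their own centres.

Randomness contract: one root seed per run; each (stratum index, parameter)
pair draws from a substream spawned as
`SeedSequence(seed, spawn_key=(stratum_index, parameter_index))`
(shared-mode deviations use a disjoint spawn-key namespace). Adding or
removing a stratum therefore never perturbs the other strata's draws, and
identical configuration + seed reproduces the replicate vector
bit-for-bit.

## Synthetic data

Because real patient-level sources of this kind are not shareable, the
package ships a generator that creates a ground-truth population of known
size and derives the three linked sources the pipeline needs: a simple
random sample (multiplier role), the treated subgroup thinned by a known
coverage (benchmark role), and the full treated subgroup with a membership
flag (reference role). Defaults mirror the national MS use case: true
total 15,300; treated share 0.621; multiplier sample 1,567; benchmark
coverage 0.65; marginals for sex (73.6% female), age bands
(55.5/34.5/10.0% for 19–49/50–64/65+), disease course (72.2/16.8/11.0%
RRMS/SPMS/PPMS), treated-therapy mix (24.5/59.8/15.7% renormalised to the
treated), and a seven-region distribution. Disease duration is log-normal
with μ = ln 8.1 and σ = ln(14.2/3.8)/(2·0.6745) ≈ 0.977: the median
matches the published 8.1 years, and σ is taken from the full
quartile-ratio spread because the two one-sided quartile fits disagree
(0.83 from the upper, 1.12 from the lower quartile) — the simulated IQR
therefore brackets the stated 3.8–14.2 rather than matching each endpoint.

What the generator does *not* emulate: record linkage errors and duplicate
persons across sources, misclassification of disease course, longitudinal
changes in treatment status, age/region-dependent treatment probabilities,
and children (the use case covers adults). Passing tests therefore show
that the estimation machinery recovers a known truth under clean sampling
mechanisms, not that any real registry satisfies the method's
representativeness assumptions — that judgement remains with the analyst
and the expert-appraisal step, for which the package only emits the
reports.

## Numerical and design choices

* Percentiles/quartiles: linear interpolation throughout; the degenerate
  δ = 0 configuration collapses every percentile to the point estimate.
* Display rounding: interval endpoints optionally rounded to the nearest
  50 (half away from zero); raw endpoints are always reported alongside.
* Subgroup extraction: records missing a field the predicate needs are
  excluded from both numerator and denominator of π̂ and counted in a
  reported exclusion tally (transparency over imputation).
* Age/sex-specific rates: the estimated total is allocated to
  (age band, sex) cells by configurable proportions, defaulting to the
  multiplier dataset's empirical age×sex distribution
  (`empirical_allocation`), and divided by cell populations. How any given
  published cell-level figure was allocated is generally not recoverable,
  so this stays a configurable default.
* Pipeline runs validate inputs first and write no partial outputs; every
  stage error is reported with the stage name, and the run log records the
  seed, all resolved parameters, per-stratum supports and the min/mean/max
  of the drawn totals for audit.

## Problem sizes in the tests

The test suite runs the full 100,000-replicate configuration for the
headline interval checks (< 1 s vectorised), 60,000 replicates for the
√K-shrinkage law, six independent 20,000-replicate brute-force oracle runs
per δ for the engine-vs-oracle comparison, and 50 synthetic generations at
the full use-case scale (15,300 persons each, 2,000 replicates per fit)
for parameter recovery. The whole suite completes in well under a minute.

## Known limitations

* The uniform ±δ bands are judgement-based inputs, not estimated
  variances; the interval is a sensitivity band, not a sampling-theory
  confidence interval.
* Coverage estimation for augmentation assumes the reference source sees
  the subgroup completely and that the membership flag is error-free.
* Per-cell rounding in augmentation can shift totals by ±0.5 records per
  cell; with many small cells this can accumulate.
* The expert-appraisal step of the surrounding workflow is a human
  process; the package produces the material to be appraised and nothing
  more.
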