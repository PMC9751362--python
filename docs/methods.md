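# Methods

This note records the statistical model, the synthetic-data generator, the
numerical choices and the design decisions behind `touchdid`, in the order
the pipeline runs.

## 1. Exclusion cascade and lexicon

Streams arrive as records with a timestamp (minute resolution, one fixed
zone — default `Asia/Tokyo`, since the emulated corpus is Japanese), a
content key for deduplication, URL and marker flags, an attitude label
(`desire` / `avoidance` / `none`) and, for attitude records, an optional
pre-annotated target word. Natural-language target extraction
(morphological analysis, dependency parsing) is explicitly outside this
package: a pluggable extractor hook on `classify_targets` lets a real NLP
front end be attached.

Deduplication keeps the **earliest** record per content key — the point of
the rule is to count each distinct content once, and earliest-kept is the
deterministic realisation of that. Out-of-lexicon words are rejected, not
auto-categorised (the lexicon is a curated object); blocklisted "noisy"
targets (e.g. `mahjong_tile`, where the surface word does not denote a
physical touch target) are rejected before lookup. Body parts, animals and
people are animate; objects and geometric features inanimate; temperature
words carry an explicit per-word animacy, mirroring how such words need
context to classify.

## 2. Pseudo-baseline and tweet proportions

The monthly outcome is `Y = attitude count / pseudo-baseline`. The
pseudo-baseline samples one 30-second window per 3-hour block (8 per day),
uniformly placed **with wrap-around inside the block**, so every instant is
covered with probability exactly 30/10800 and the estimator is unbiased for
that fraction of marker posts; a non-wrapping window would shade the block
edges and bias the count by ~0.3%. Windows are redrawn per month from a
child seed, so any month is independently reproducible.

Aggregating days `d ≡ s (mod 3)` (s = 1, 2, 3) yields three proportion
samples per month; day 31 falls in class 1 and no rebalancing is done —
the literal every-third-day rule. The three samples enter the GLMs as
replicate observations: that is the only reading that uses all computed
samples. A zero *baseline* sum raises an error (the denominator must be
positive); zero *target* counts yield proportion 0, handled by the model
layer (§4).

Because numerator and denominator share the platform-volume factor, the
proportion is invariant in expectation to uniform volume rescaling — the
property that motivates the pseudo-baseline.

## 3. Panel design

Seven rolling 18-month groups starting each August 2013-2019; the 2019
window is the treatment group. Month index m = 1..18; months 1-6 are
pre-treatment; waves are m = 7-11, 12-16, 17-18; event time k = m − 7 with
reference k = −1 (January of year two). An 18-month window has 12 post
months, so k runs −6..11; a nominal upper summation bound of 18 is a
month-count, not a k value.

Calendar months shared by overlapping windows appear once per group, with
identical values when a single observed stream is aggregated — the design
requires it, and the group fixed effect absorbs level differences. The
inferential consequence is discussed in §7.

## 4. Gamma / inverse-link GLMs

Proportions and cosine similarities are positive, continuous,
right-skewed, with roughly constant coefficient of variation — hence a
Gamma family with variance `phi mu^2` and the canonical inverse link
`g(mu) = 1/mu`. Fitting is maximum likelihood via IRLS (statsmodels
backend), tolerance 1e-8, at most 100 iterations; for the canonical link
the coefficient MLE does not depend on the Gamma shape, which is how the
test suite's independent oracle (direct Newton maximisation of
`sum(log eta − y*eta)`, a concave problem) can check IRLS to 1e-6.
Dispersion is the Pearson estimate; Wald inference uses the expected
information. A constant response is a degenerate boundary case (zero
dispersion) and is fitted exactly with zero deviance rather than iterated.

All three specifications — overall DID, wave-specific DID, event study —
use this family. The estimators include **common period main effects**
(`Post`, wave dummies, month-of-window dummies) alongside the treatment
interactions and control-group fixed effects. Without them the interaction
would reduce to the treatment group's own post-vs-pre contrast and the
control groups would not enter the point estimate at all; the period main
effects are what make the estimate a double difference that cancels shared
seasonality and long-term trend. `time_effects=False` reproduces the
barer specification for comparison.

Sign convention: the inverse link reverses signs between the linear
predictor and the response. Rather than guessing which scale a reader
wants, every interaction is reported on both: the linear coefficient with
Wald z/p/CI, and the average response-scale effect (absolute and relative)
over the rows where the interaction is active, with CI endpoints mapped
through the monotone link — so a response-scale interval excludes zero
exactly when the coefficient interval does, and the sign-reversal identity
`sign(effect) = −sign(coef)` holds on every fit.

Zeros: Gamma support excludes 0. Default policy shifts zero responses by
half the smallest positive response with a logged warning; `drop` and
`error` are available. Standard errors are model-based Wald by default (no
clustering), with a cluster-robust option (group × month) off by default.
No multiple-testing correction is applied across event-study months; the
per-month 5% tests are reported as such.

## 5. Synthetic-data generator

The generator emulates an eight-year corpus at desk scale. Monthly record
totals are Poisson (negative-binomial switch available for overdispersion
robustness) around `base_volume × trend × seasonal factor`:

- `base_volume` default 100,000 records/month — a desk-scale stand-in;
  only ratios matter downstream.
- `trend` is the total fractional change over six years, applied
  exponentially per month, default −0.238 to mimic the long-term decline
  in touch-desire proportions; it multiplies both volume and attitude
  rates.
- `seasonal_factors` (12 values, geometric-mean normalised) multiply both
  volume and attitude rates. Volume seasonality cancels in the proportion
  (by construction of the pseudo-baseline); rate seasonality is what makes
  proportions seasonal, with the default profile putting February ~11%
  below January.
- attitude rates default to desire 0.020 / avoidance 0.006 (roughly the
  observed desire:avoidance imbalance); 25% of attitude posts carry an
  extractable target, of which 30% are noisy (blocklisted); contamination
  defaults are 5% exact duplicates and 10% URL posts.
- post-outbreak effects are multiplicative on the attitude rate from
  February 2020: `effect_overall` and per-wave `effect_waves`, and the
  target-word distribution switches from `target_distribution_pre` to
  `target_distribution_post`.
- the marker token is an independent Bernoulli flag (default prevalence
  0.9, emulating a near-ubiquitous character); its absolute prevalence is
  a free parameter since only ratios matter.

Two paths share this model. `generate_stream` simulates records
(duplicates copy an earlier same-month record's content and flags, so
dedup keeps exactly the originals). `generate_panel` /
`simulate_monthly_cells` draw the per-month, per-sample counts directly
from the **exact** count law implied by the stream path — sequential
binomial thinning of the monthly total, and window-sampled baselines that
are Binomial in the number of covered minute ticks, itself
Binomial(8 × days, 1/2). The agreement is therefore distributional, not
merely in expectation, and is verified by two-sample Kolmogorov-Smirnov
tests across seeds with and without contamination.

What the generator does **not** emulate: real text (targets are symbolic
tokens), day-of-week effects (the analysis is monthly), user-level
correlation beyond exact duplicates, drift in the marker prevalence, or
platform events (API changes, viral cascades). Passing tests demonstrate
that the estimators recover effects under the stated generative model;
they cannot certify behaviour under real-data pathologies outside it.

## 6. Calibration studies

Operating characteristics (effect recovery, CI coverage, pre-trend
rejection, wave localisation) are measured under a **model-consistent
calibration regime**: flat seasonal factors, zero trend, no contamination,
cell counts large enough that zero proportions are vanishingly rare, and —
importantly — panel cells drawn independently per group-month
(`independent_cells=True`). This is the standard way to verify an
estimator implementation: simulate from the world the model assumes, and
check that nominal properties hold. The seasonal/trend and contamination
machinery is exercised separately (generator tests, stream-vs-fast-path
equivalence, end-to-end pipeline with all defaults active).

The quality-stage calibration uses a 40-word Zipf vocabulary, 5,000 counts
per side, ±0.03 absolute shifts on four words, B = 10,000 bootstrap
replicates; the per-word one-tailed Bonferroni level is 0.05/30 (the 15+15
selected words — selection precedes testing). The one-tailed direction
follows the sign of each observed delta, and resampling conditions on the
observed totals (multinomial), the natural bootstrap for closed
vocabularies. Control-period counts are pooled across the six control
groups — pooling maximises the control sample and is symmetric across
groups.

## 7. Known limitations

- **Overlap correlation.** The rolling design reuses calendar months
  across up to three groups; with a single observed stream those rows are
  identical, and model-based Wald SEs (which assume independent rows)
  understate uncertainty — measured here as wave-coefficient coverage
  dropping a few points below nominal on overlap-correlated panels. This
  is intrinsic to the design, not to this implementation; the
  cluster-robust option mitigates within-month duplication but not
  cross-group reuse. The calibration studies therefore use independent
  cells (§6).
- **Variance-function approximation.** Proportions are ratios of counts
  (variance ≈ `mu^2 (1/E[T] + 1/E[B])`), not exactly constant-CV Gamma;
  with roughly equal cell means the approximation is benign, which the
  coverage studies confirm, but strongly unbalanced designs would strain
  it.
- Small post-period cells (the two-month third wave has 6 replicate
  observations per group) make Wald intervals slightly anticonservative.
- The bootstrap treats word counts as multinomial given totals; burstiness
  of individual words within a period is not modelled.
- Event-study months are tested at 5% each without multiplicity
  correction, so one pre-period false positive among the five pre-event
  contrasts is within expectation.
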