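# Methods

This note records the model, the numerical choices and the known limits
of the package, in the spirit of a methods appendix.

## Model and procedure

The object of analysis is the pairwise similarity structure of spatial
EEG patterns.  For participant *p*, sentences *i, j* and time sample *t*,

    r_ijt = Pearson correlation across channels of pattern(i, t) and pattern(j, t).

Pearson (not cosine) is used: each channel vector is centered before
normalization, so a channel-constant offset or a positive gain applied to
one epoch leaves its similarities unchanged.  Zero-variance patterns make
the correlation undefined; such values are stored as NaN missing markers,
never as 0, and propagate as sample-wise pair dropout.

Per participant, per time sample, the similarity values over pairs are
regressed on an intercept and three pair-level predictors (identity,
Lin semantic similarity, normalized edit similarity), all in [0, 1].
The four predicted condition signals are affine reads of the betas with
the predictor configurations (WS, Sem, Form) =
(1,1,1), (0,1,0), (0,0,1) and (0,0,0); the identity
`WordSpecific − Unrelated = β_WS + β_Sem + β_Form` holds at machine
precision and is asserted in tests.  Fitting is independent per
participant; group inference happens only on the condition signals.
The Word-Specific configuration sets semantic and form to 1, not to their
empirical means, because identical words sit at the maximum of all three
predictors.

Semantic similarity needs a taxonomy with corpus counts.  Because the
mapping of a real stimulus list onto a curated taxonomy (and the synset
choice for polysemous words) is an experimental decision, not a package
decision, the semantic source is pluggable: a TSV edge list
(child, parent, own_count) plus word map, or a precomputed symmetric
word-by-word similarity matrix.  Information content uses the natural
logarithm; Lin similarity is invariant to the base.  Word identity is
exact string equality after NFC normalization and lowercasing — accents
are **not** stripped, since Spanish orthography makes them contrastive.
Edit distance uses unit costs; the normalized similarity is
`1 − 2d/(|a|+|b|+d)`, which is 1 exactly on identical strings (including
the degenerate empty–empty case, which the identity clause covers).

## Statistics

* **Chance level.** The median over time of the across-condition average
  of the grand-average signal; a configured override is available.
* **Window detection.** One-sample t-series against chance,
  Benjamini–Yekutieli adjusted (the harmonic-number penalty, valid under
  arbitrary dependence); maximal runs of adjusted p ≤ α become windows,
  and their envelope (earliest onset to latest offset) the analysis
  window.
* **Cluster tests.** Cluster-forming threshold t = 2.04 by default (the
  two-tailed α = .05 critical value at df = 30); clusters are contiguous
  suprathreshold runs (4-connected cells in 2-D), mass = summed t.  The
  null is the distribution of the maximum cluster mass under
  per-participant condition swaps, which for paired contrasts is a sign
  flip of the difference series; permuted t-series are computed in closed
  form from the flipped sums, so even 10^5 permutations are cheap.  The
  direction is one-sided positive by default (the scientific hypotheses
  are "more similar than baseline"); two-sided mode exists behind a flag.
  P-values use the +1 correction and are never 0.  Cross-temporal
  clusters are Bonferroni-multiplied by the number of condition tests
  (default 4).
* **Latencies.** The latency of an effect is the time of the maximum t
  inside the largest-mass cluster, ties broken toward the earlier sample.
  Jack-knife comparison: for each leave-one-participant-out subsample the
  latency is re-extracted; the n paired latency differences enter a
  sign-flip permutation test (two-tailed, on the mean).  The
  t-statistic on jack-knife scores is reported in two variants: divided
  by (n − 1) — the classical correction for subsample-based scores, the
  default for new analyses — and uncorrected, which reproduces the
  historical practice.  The permutation p does not depend on the
  correction.  Iterations where an effect has no suprathreshold cluster
  are flagged unstable and dropped pairwise; latency comparisons are only
  meaningful when both effects are significant in the full-sample cluster
  test.
* **Power arithmetic.** The a-priori minimal sample size iterates n
  upward, evaluating two-tailed paired-t power from the noncentral t with
  noncentrality d·√n.

## Numerical choices

* Per-sample OLS is solved with vectorized least squares over all time
  samples sharing a pair set; samples with missing pairs are grouped by
  identical missingness masks.  A sample is flagged missing when fewer
  than 5 pairs survive or the design is rank-deficient (e.g. all
  surviving pairs share one word_specific value).  statsmodels OLS serves
  as the cross-check oracle in the test suite.
* Cross-temporal matrices are streamed in pair batches; normal equations
  are accumulated so the full pair × 240 × 240 stack is never resident.
  Cells with missing correlations are re-solved by downdating the
  accumulated normal equations with the offending pairs' design rows.
* Downsampling is polyphase resampling with a zero-phase anti-alias
  filter (scipy `resample_poly`); sample count = floor(duration · rate),
  so −800..0 ms at 300 Hz gives 240 samples.  A decimation-only mode
  (integer factors, kept samples untouched) exists for exactness tests.
* Epochs are stored half-open, [−800, 0) ms at 1 kHz = 800 samples;
  window cropping is inclusive of both endpoints on the stored grid.
* Every stochastic routine requires a seed or Generator; given one, all
  outputs are bit-reproducible.  Pipeline reports carry the config hash,
  and persisted intermediates round-trip exactly (17-significant-digit
  TSV, round-trip float parsing) so resumed and fresh runs agree
  bit-for-bit.

## The synthetic generator

The generator emulates exactly the structure the regression assumes:
each word owns a unit-norm channel pattern; words in a taxonomy branch
share a semantic component, words with a common stem share a form
component; each effect mixes its shared component into the word pattern
with a convex pattern-share amplitude inside a latency window, under a
raised-cosine envelope (so the peak-t latency is well defined at the
window centre); white Gaussian noise is added per channel and sample.
Defaults: 47 words × 2 sentences, 34 channels, 1 kHz; windows
semantic −672..−657 ms, form −650..−644 ms, word-specific −650..−614 ms
(amplitudes 0.5/0.5/1.0); noise sd 1.0 and signal gain 2.0, which puts
the peak same-word pattern correlation near 0.1 — the order of magnitude
of published EEG similarity effects.

One subtlety is deliberate: per-participant topography variation is a
random orthogonal rotation of channel space *restricted to the subspace
orthogonal to the channel-mean direction*.  Pearson pattern correlation
centers across channels, so unrestricted rotations would distort the
planted similarity structure; mean-preserving rotations leave it exactly
invariant while still giving every participant different topographies.

What the generator does **not** emulate: 1/f (pink) spectral structure
(a pink-noise option exists but is off by default so oracles stay
analytic), volume-conduction channel correlations, trial-to-trial
latency jitter, artifact-induced missingness patterns, and any
biophysical forward model.  Passing recovery tests therefore demonstrate
the correctness of the estimators under the assumed generative model,
not robustness to every property of real EEG.

## Problem sizes in the test suite

Recovery and calibration tests run at deliberately chosen reduced sizes:
the latency-ordering study simulates the default recipe on the
−730..−511 ms analysis window (220 samples at 1 kHz), which contains all
three planted effects, with 1,000 permutations per test across 50
replicates; type-I calibration uses 200 null replicates of 20
participants × 120 samples at 1,000 permutations.  These sizes keep the
suite fast while leaving the estimators, which scale linearly in samples
and permutations, untouched.

## Known limitations

* No mixed-effects alternative to the two-stage (per-participant fit,
  group test) summary-statistics approach.
* No regularized or robust regression variants.
* Cross-temporal matrices are stored in one fixed pair orientation
  (sentence-id order); symmetrization across orientations is not applied.
* The decoding (classifier-based) variant of temporal generalization is
  out of scope; this is the correlation/RSA variant only.
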