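# rrsa — regression-based representational similarity analysis for EEG

`rrsa` implements a complete analysis chain for asking *what* the brain
has pre-activated about an upcoming word — its meaning, its orthographic
form, or the specific word itself — from multichannel EEG recorded while
participants read highly constraining sentence frames.  It is written for
cognitive-neuroscience labs running time-resolved multivariate pattern
analyses: the inputs are cleaned epoch tensors (trials × channels × time)
plus a table of which word each sentence predicts, and the outputs are
decomposed similarity time courses with full cluster-permutation and
latency statistics.

## The method

**Pairwise similarity.** For every unordered pair of sentences *(i, j)*
and every time sample *t*, the spatial patterns (channel vectors) of the
two epochs are correlated with Pearson's *r*, giving one similarity time
series per pair — C(n, 2) series for *n* sentences (4,371 for the
canonical 94-sentence design).

**Regression decomposition (rRSA).** Each pair carries three predictors
about its two *expected* words: identity (dummy-coded `word_specific`),
Lin semantic similarity in a concept taxonomy
(`2·IC(lcs) / (IC(a) + IC(b))`, `IC = −log p` from corpus counts), and
normalized edit similarity (`1 − 2d/(|a|+|b|+d)` with Levenshtein
distance *d*).  Per participant and per time sample, OLS fits

```
r  ≈  β₀ + β_WS·word_specific + β_Sem·semantic + β_Form·form + ε
```

and four predicted condition signals are read off the betas:
Unrelated = β₀, Semantic = β₀+β_Sem, Form = β₀+β_Form, and
Word-Specific = β₀+β_WS+β_Sem+β_Form (identical words are maximally
similar on all three predictors).

**Cross-temporal similarity (rCTS).** The temporal-generalization variant
correlates sentence *i*'s pattern at time *k* with sentence *j*'s pattern
at every time *l*, after anti-aliased downsampling (800 samples at
1 kHz → 240 at 300 Hz, i.e. 240×240 matrices), and decomposes the
matrices cell-wise with the same regression — a diagonal-only effect
means the neural code is transient.

**Statistics.** Analysis windows come from a Benjamini–Yekutieli
corrected one-sample *t*-series of the grand average against the chance
level (the median over time of the across-condition average).  Condition
contrasts use cluster-mass permutation tests (contiguous *t* > 2.04 runs,
max-cluster null from per-participant condition swaps), effect latencies
the leave-one-participant-out jack-knife with a sign-flip permutation
test on latency differences (reported both with and without the classical
(n−1) jack-knife correction of the *t* statistic), and cross-temporal
clusters 4-connected 2-D labelling with Bonferroni correction.

A synthetic-data module plants word-unique, semantically shared and
form-shared spatial patterns in configurable latency windows, so the
entire pipeline is testable against known ground truth without any data
download.

## Worked example

`examples/03_cluster_and_latency_stats.py` simulates 24 participants with
a planted semantic → form → word-specific cascade and runs the full
statistical chain:

```
semantic       largest cluster   -670.. -660 ms, mass   122.4, max t 22.01, p = 0.0010
form           largest cluster   -648.. -645 ms, mass    46.5, max t 19.68, p = 0.0010
word_specific  largest cluster   -649.. -619 ms, mass   316.6, max t 25.85, p = 0.0010
semantic (-664 ms) precedes form (-647 ms) by 17 ms, permutation p = 0.0010
form (-647 ms) precedes word_specific (-632 ms) by 15 ms, permutation p = 0.0010
```

Times are ms relative to the expected word's onset: every effect is
detected against the Unrelated baseline (cluster *p* = 0.001 at 1,000
permutations), and the jack-knife latencies recover the planted ordering —
meaning first, form next, the specific word last.  The other scripts in
`examples/` walk through predictor construction, single-participant
decomposition, cross-temporal generalization and the end-to-end pipeline.

A thin CLI wraps the same calls for shell use:

```sh
rrsa simulate --n-words 47 --n-participants 24 --out data
rrsa run --config analysis.yaml
```

Every report carries the config hash and seed; re-running an identical
configuration reproduces the report bit-for-bit, and deleting a
downstream output regenerates only that stage.

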