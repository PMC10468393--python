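# Methods

This note documents the generative model, the decoding pipeline, the
analysis procedures, the parameter choices that matter, and what the
synthetic tests do and do not establish.

## Synthetic data generator

The simulator emulates the statistics that an attempted-speech decoding
pipeline must handle, with no biophysics:

* **Latent articulatory trajectory.** A sentence is converted to a phoneme
  sequence (first-listed pronunciation per word, `<sil>` after every
  word). Each phoneme holds a 15-dimensional articulatory feature vector —
  consonants: one-hot place (bilabial, labiodental, dental, alveolar,
  postalveolar, velar/palatal, glottal), manner flags (nasal, plosive,
  fricative, approximant; affricates set plosive+fricative), a voicing
  bit; vowels: tongue height and backness in [0, 1] and a rounding bit.
  W carries half weight on both bilabial and velar slots because it is
  articulated with both lips and tongue body. Phoneme dwell times are
  log-normal (arithmetic mean 90 ms, log-s.d. 0.4 — right-skewed, as real
  segment durations are); the piecewise-constant feature track is smoothed
  with a 60 ms moving average as a coarticulation proxy. The delay epoch
  before the go cue holds the zero vector.
* **Rates and features.** `rate = softplus(b + W a(t) + day_offset +
  drift·t·u)`. softplus keeps rates nonnegative while staying near-linear
  at working rates. Baselines `b` are clipped Gaussians (mean 20 Hz, s.d.
  6 Hz — multiunit threshold-crossing scale); tuning weights are zero-mean
  Gaussians with s.d. 10 Hz per feature unit. TX counts are Poisson over
  20 ms bins; SBP is `gain·rate` plus Gaussian noise (s.d. 2), so the two
  feature types are correlated, as in real arrays. Attempted-silent mode
  multiplies the rate by 0.7.
* **Non-stationarities.** Additive per-day rate offsets (s.d. 2 Hz, day 0
  is the reference), optional random relabeling of a channel subset on
  later days (`permute_frac`), and within-day linear drift along a fixed
  random population direction (default 0.05 Hz/min; experiments that probe
  adaptation plant 0.5 Hz/min). A helper converts the i.i.d. day offsets
  into a cumulative random walk for gradual-drift analyses.

What the generator does **not** emulate: spike waveforms, electrode
cross-talk, heavy-tailed rate fluctuations, behaviorally varying speaking
rate, error trials, or any nonlinear encoding beyond softplus. Passing
tests therefore establish that the pipeline's machinery is correct and
that it recovers planted structure — not that it would reach the same
error rates on human recordings.

## Corpus and lexicon

The bundled lexicon is a 50-word assistive vocabulary in CMUdict format
(stress digits stripped on load; alternate pronunciations retained for
decoding, first variant used for training targets; out-of-vocabulary words
are a hard error). A small probabilistic phrase grammar generates
caregiver-style sentences over these words; language-model text, decoder
training sentences and test sentences are all drawn from it, with
train/test splits disjoint by sentence string. For vocabulary sweeps,
pseudo-words are appended: half are near-homophones of real words (one
phoneme edited) — the kind of vocabulary growth that actually causes
confusions — and half random consonant-vowel strings.

## Feature pipeline

Decoder path: TX and SBP are concatenated (bins × 2·electrodes), smoothed
with a causal 2-bin boxcar (the acausal 80 ms-s.d. Gaussian kernel is used
only for display PSTHs — the decoder must not look ahead), z-scored with
frozen training-set statistics (s.d. floor 1e-3 for silent electrodes),
and stacked 4 bins per step to form the 80 ms decoder input. Rolling
adaptation replaces frozen z-scoring with causal exponentially weighted
mean/variance per column (half-life 60 s of observed bins, state
initialized from training statistics and persisting across trial
boundaries); its normalization of bin *t* uses only bins before *t*.

## Decoder

A day-specific affine input transform (one per recording day, initialized
at identity) feeds a shared GRU stack and a softmax over 41 tokens.
Defaults are deliberately desk-scale — 2 layers × 96 units, trained 30
epochs with Adam (lr 4e-3, cosine decay to 10%, gradient-norm clip 5,
day-pure batches of 32) — a 5 × 512 preset exists but is not used by the
tests. The CTC loss and its gradient are computed by the log-space
forward–backward recursion over the blank-augmented label lattice;
training targets whose minimum CTC length exceeds the available steps are
skipped with a warning (rare long sentences drawn with short dwell times).
Forward, backward-through-time and input gradients are hand-written NumPy;
correctness is pinned by finite-difference tests and by brute-force
alignment enumeration on small instances.

## Language model and word decoding

The trigram uses interpolated absolute discounting with a single discount
D = 0.75 — the simplest fully-specified estimator: each conditional is the
discounted maximum-likelihood term plus `γ(context)` times the next-lower
order, ending in an interpolation with the uniform distribution, so every
in-vocabulary word has positive probability and every observed context
sums to one. Restricting to a sub-vocabulary renormalizes conditionals
over the retained words on demand. ARPA export writes the interpolated
probabilities with the discount gammas as backoff weights.

Word decoding is CTC prefix beam search over a lexicon trie with separate
blank/non-blank path probabilities per (word history, phoneme prefix)
hypothesis. A word completes when `<sil>` is consumed at a
pronunciation-final trie node — `<sil>` terminates every word, exactly as
in the training targets; no optional inter-word silence is modeled — and
the language-model log-probability joins the score there (shallow
fusion). Scores decompose as `acoustic_weight·log P_CTC + lm_weight·log
P_LM + insertion_bonus·n_words` with defaults (1, 1, 0); ties break
lexicographically. With an unbounded beam the search is exact: its scores
match an exhaustive oracle that enumerates word sequences and computes the
full CTC marginal per pronunciation expansion. The no-LM baseline maps
greedy-decoded phoneme segments (split at `<sil>`) to the
nearest-pronunciation word by edit distance.

PER and WER are unit-cost Levenshtein distance over reference length
(`<sil>` counts as a phoneme token); batch values are total edits over
total reference length, not means of per-sentence rates.

## Analyses

* **Naive Bayes** classification uses Gaussian likelihoods on windowed
  per-electrode mean rates (1 s from the go cue; 100 ms centered windows
  for the time-resolved curve), leave-one-out cross-validation (the
  highest-data-use scheme at these trial counts), a variance floor, and
  percentile bootstrap (1,000 resamples) for confidence intervals.
* **ANOVA maps** test each electrode's 800 ms-binned rates across
  conditions per bin at α = 1e-5 with no multiplicity correction (the
  fixed-threshold convention for these displays); the number of bins
  tested is recorded alongside. **FVAF** is SS_between/SS_total of the
  windowed rates, reported per bin with the per-electrode maximum.
* **Saliency vectors** maximize the decoder's center-step probability of a
  phoneme over a unit-norm constant input repeated for 6 steps, by
  projected gradient ascent (60 iterations, step 0.5, best of seeded
  restarts); a gradient-at-baseline estimator is available for sensitivity
  checks. The blank token is rejected — it has no articulatory meaning.
* **RSA** compares cosine-similarity matrices (neural saliency vs
  articulatory features) by Pearson correlation over strictly-upper
  triangle entries; significance is a joint row/column permutation null
  with `p = (1 + #{null ≥ obs}) / (n + 1)`. **Cross-validated Procrustes**
  projects neural vectors onto their top principal components (default 8),
  fits an orthogonal rotation plus global scale to zero-padded 2-D
  articulatory coordinates on all-but-one phoneme, and places the held-out
  phoneme; disparity is the mean squared residual. The **vowel plane** is
  the least-squares map from 2-D vowel coordinates into neural space;
  ordering checks use formant-style axes (F1-like = 1−height, F2-like
  folds rounding into backness), since rounding covaries with backness and
  is read into the second formant in real vowel spaces.

## Experiment design choices

* **Electrode sweep** uses nested subsets within a seed (count-16 ⊂
  count-32) to reduce subset-sampling variance, retrains the decoder per
  count, and fits `log WER = a + b·log2(count)`; the per-doubling factor
  is `2^b`. The sweep covers 4–32 electrodes: with this simulator's
  signal-to-noise, performance saturates above ~32 electrodes at the
  50-word vocabulary, so larger counts would only measure a floor.
* **Vocabulary sweep** re-decodes fixed posteriorgrams with restricted
  language models (the true 50 words always retained, the remainder by
  unigram frequency).
* **Training-size sweep**: with zero evaluation-day sentences, the new
  day's input layer copies the most recent prior day's (the minimal
  zero-shot mechanism; flagged in the sweep manifest).
* **Day-layer ablation** compares three decoders on a 2-day dataset whose
  second day has all channels relabeled: day-specific input layers, a
  shared input layer (day labels hidden), and a single-day reference. A
  caveat worth stating: in this simulator the shared-layer decoder
  degrades far less than one might expect, because day identity is
  inferable from the features themselves and the articulatory latent space
  (15-dim) is much smaller than the feature dimension, so even a single
  linear map can invert several days' codes at once. The corresponding
  acceptance assertion documents this as an open discrepancy rather than
  forcing the effect with a crippled decoder.
* **Rolling-adaptation check** plants 0.5 Hz/min drift in a 260-sentence
  session (a realistic single-day session length) and measures the
  per-trial mean slope along the dominant drift direction after the
  adaptation state's five-half-life warm-up, comparing frozen z-scoring
  against rolling adaptation.

## Problem sizes used by the test suite

End-to-end checks run the default study (300 train / 50 test sentences, 64
electrodes, 30 epochs) at five seeds; sweeps use 150 train sentences and
12 epochs at three seeds; the RSA chain uses 200 sentences and 20 epochs.
These sizes keep the full suite within minutes on one CPU while leaving
wide margins to the thresholds tested.

## Numerical choices and degenerate inputs

Log-space arithmetic throughout CTC, beam search and the LM; probability
floors 1e-300 before logs; z-score s.d. floor 1e-3; naive-Bayes variance
floor 1e-6 relative to feature scale; FVAF of an all-constant window
defined as 0; PSTH confidence intervals collapse to the point estimate for
a single trial; empty references raise rather than return 0. Every random
quantity draws from a named substream of one global seed
(`pipeline.child_seed`), so a single integer reproduces any run.

## Known limitations

The simulator's linear-softplus encoding makes the decoding task easier
than real recordings (error rates here are lower than any plausible real
system); the sentence grammar is far simpler than conversational English,
so language-model gains are optimistic; the day-layer mechanism's benefit
is understated for the reason given above; and saliency extraction on a
saturated decoder can stall on probability plateaus (restarts mitigate
this). Raw 30 kHz voltage processing, real-time closed-loop operation and
neural-LM rescoring are out of scope.
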