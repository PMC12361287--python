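# Methods

This note documents the statistical procedures implemented in `surpread`,
the choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Surprisal extraction

Word surprisal is `−ln P(word | context)` in nats. When a word spans several
tokens, the token log probabilities are summed before negation, so the word's
surprisal is exactly its chain-rule contribution to the sequence log
probability; splitting words into finer tokens that preserve the chain rule
leaves totals unchanged (tested).

**Sliding window.** A model with context window `W` scores token `i` on its
full left context while `i ≤ W`. On the first token that would exceed the
window, the context start advances by `⌊W/2⌋`, cascading as needed. Every
token after the first window therefore keeps at least `⌊W/2⌋` tokens of
context. Tokens are scored exactly once; the overlap region is context only,
never re-scored.

**Built-in n-gram.** Additive (add-k) smoothing,
`P(w|c) = (count(c,w) + k)/(count(c,·) + k·|V|)`, default `k = 1`. Add-k
admits exact enumeration oracles, which the tests exploit; the contract
accepts any other smoother. Sentences are padded on the left with `n−1`
boundary symbols; no end-of-sentence event is modelled, so a "sequence
probability" is the probability of the words given the sentence
segmentation. Contexts shorter than `n−1` are implicitly boundary-padded.
The vocabulary includes an unknown-word symbol by default (`unk=False`
restricts `V` to the training types; out-of-vocabulary queries then raise).
External models are imported as TSV streams of
`(token, word_index, logprob_nat, context_len_used)`; positive or non-finite
log probabilities and non-monotone alignments are rejected.

## Corpus handling

A corpus is one row per participant × word with FFD/GD/TRT in milliseconds,
word length in characters, Zipf frequency (log10 per billion words), and
punctuation/sentence-initial/skip flags. Invariants enforced on read:
FFD ≤ GD ≤ TRT on fixated words, skip ⟺ missing-or-zero gaze duration,
Zipf ∈ [0, 9].

**Exclusions** remove, in a fixed order (punctuation → sentence-initial →
out-of-vocabulary → skipped), the response rows conventionally dropped from
reading-time analyses. The punctuation class is any character outside
letters and digits (regex `[^\w]|_`), including apostrophes and hyphens.
The order affects only the per-rule counts in the report, never the retained
set; exclusion is idempotent. A zero and a missing gaze duration both mean
"skipped"; this skip definition is applied uniformly to all three measures.

**Spillover.** The previous word's length, frequency and surprisal are taken
from the text-stream predecessor *before* exclusion filtering: a word
excluded as a response still serves as context for the next word. The first
word of a text stream has no predecessor and yields no response row.

## Cross-validated ΔLogLik

Reading times are modelled in raw milliseconds with Gaussian error (a log-ms
option exists via the `log_response` flag); fixed effects only.
Baseline predictors: length, Zipf frequency, within-sentence position,
previous word's length and frequency, plus an intercept. The full model adds
surprisal and previous-word surprisal (2 extra df). Rows are shuffled into
`k = 10` near-equal folds by a seeded permutation; per fold, both models are
fitted by OLS on the other nine folds and the held-out log-likelihood uses
the training coefficients *and* the training MLE variance `RSS/n`, keeping
each fold's evaluation a pure function of the training fit. Predictors are
left on their natural scales (ΔLogLik is scale-invariant; coefficients stay
interpretable). Fold assignment ignores participant/item grouping, matching
plain tenfold cross-validation.

**Fold p-values.** Three constructions are exposed:

* `fold_exact` (default): the likelihood-ratio test of the nested pair
  computed within each held-out fold. For nested Gaussian linear models the
  LR statistic is a monotone function of the F statistic, so the exact
  finite-sample null is used. Folds are disjoint, hence the p-values are
  independent and uniform under the null — the premise Fisher's combination
  requires. Measured null rejection of the combined test at α = 0.05:
  0.05 (it is computed by the test suite and the acceptance script).
* `heldout`: `2 × (held-out ΔLL)` referred to χ²₂, clamped to `p = 1` for
  negative improvements. Under the null the statistic is not χ²
  distributed — most folds land at `p = 1` and the combined test is extremely
  conservative (measured rejection ≈ 0). Provided for comparability.
* `train`: the classical LRT on the nine training folds. Fold statistics
  share 90% of their data, so Fisher combination over them is strongly
  anticonservative (measured rejection ≈ 0.2). Provided for comparability.

ΔLogLik per word is reported per fold, averaged over folds, and scaled per
1,000 words with `SE = SD(folds)/√k`.

**Scaling meta-regression.** Gains (per 1,000 words) are regressed on model
size in units of 100 M parameters with corpus and measure main effects and
size × corpus, size × family interactions (factors with a single level are
dropped automatically). A negative size slope is the inverse-scaling
pattern: bigger models explaining reading times worse.

## Penalized-spline engine and the linearity test

Smooths are cubic B-splines on *uniform* knots with a second-order
difference penalty (P-splines). Uniform knots make the penalty null space
correspond exactly to constant + linear functions, which the engine exploits
by reparameterizing every smooth into (i) an explicit unpenalized linear
column and (ii) a penalized block whitened to an identity penalty. Tensor
products are row-wise Kronecker products of marginal bases with one
difference penalty per margin; their joint null space (bilinear functions
`1, x, z, xz`) is likewise split out. Consequences: an infinitely penalized
smooth *is* the linear (or bilinear) fit to machine precision, and the
nonlinear model nests the linear one exactly.

Smoothing parameters minimize a profiled REML criterion
`(n−M)·log(RSS_p) + log|XᵀX + S_λ| − log|S_λ|₊` (`M` = unpenalized columns),
or GCV on request, via Nelder–Mead on log-λ with warm starts from a
full-data fit in cross-validation. Defaults: basis dimension 10 for
univariate smooths, 5 per tensor margin (the conventional default for
tensor interactions; it keeps `n ≫ p` at item counts near 2,000 and makes
replicated simulation studies cheap). Degenerate inputs (too few distinct
covariate values, `n` not exceeding the basis dimension, non-positive-
definite normal equations at extreme λ) raise informative errors; a tiny
escalating ridge guards the final solve.

**Item-level analysis.** All strictly positive gaze durations on a word are
averaged over participants; words never fixated are absent. The three
models — baseline `te(freq, len) + te(prev_freq, prev_len)`; linear
baseline + `s_lin(surprisal) + s_lin(prev_surprisal)`; nonlinear baseline +
`s(surprisal) + s(prev_surprisal)` — share identical folds. The baseline
carries tensor smooths for *both* the current and previous word so the
linear/nonlinear contrast isolates the surprisal terms alone. Surprisal
smooths span at least [0, 20] nats so prediction curves on the conventional
0–20 grid need no extrapolation; reference covariates for curves are the
training means.

**Permutation test.** The statistic is the mean over folds of the per-item
difference in held-out improvements (nonlinear − linear). N = 1,000 random
sign flips of the paired differences give a two-sided p with the +1
correction, so `p ∈ [1/(N+1), 1]`; differences are sorted before flipping,
making the Monte-Carlo draw invariant to fold order (signs are i.i.d., so
the distribution is unchanged). For `k = 10` the Monte-Carlo p agrees with
the exact 2¹⁰ enumeration within binomial error (tested).

### Known limitation: type-I inflation of the linearity protocol

The sign-flip test assumes the fold-level paired differences are
exchangeable and symmetric under the null. They are not quite: CV folds
share 90% of their training rows, and per-dataset smoothing-selection quirks
(a smooth that settles on a little real-looking wiggle) shift *all* folds'
differences together. On strictly linear synthetic data the measured
rejection rate at α = 0.05 is ≈ 0.10–0.15 at moderate item noise and
≈ 0.20 when items are averaged over many participants (very low noise) —
inflated relative to the nominal level. The same inflation, at the same
magnitude, appears when the identical protocol is run with an independent
GAM implementation, so it is a property of the procedure, not of this
engine. Practical reading: a linearity-test p just below 0.05 is weak
evidence against linearity; power for genuinely curved links is excellent
(rejection 1.0 for quadratic links at 2,000 items in the test suite).

## Synthetic data generator

The generator emulates the structure of word-level eye-tracking corpora:

* **Lexicon:** `V` word types (default 250) with rank-frequency ∝ rank^(−s)
  (default `s = 1`), Zipf values `log10(rel · 1e9)`, and lengths drawn from a
  rank-dependent Poisson so frequent words are shorter on average.
* **Text:** a first-order Markov word model whose conditional rows are drawn
  once from a Dirichlet with Zipfian mean (concentration 50) and then
  frozen, so the true surprisal of every sampled word is exactly
  `−ln P(w | prev)` — the same model scores its own output bit-for-bit.
  Three shapes mirror common corpus designs: 200 isolated sentences of 5–30
  words (context resets each sentence), 12 paragraphs of 161–213 words
  (context flows within a paragraph), or one book-length stream (≥ 50,000
  words; long enough to force sliding-window scoring).
* **Reading model:** gaze duration is additive —
  `GD = 200 + 3·g(s) + 1.5·g(s_prev) + 6·len − 8·zipf − 0.3·pos + u_p + ε`,
  with `g` the identity (linear link) or a power `s^γ`, participant
  intercepts `u_p ~ N(0, 20²)` and noise `ε ~ N(0, 30²)` ms by default;
  negative draws are resampled at zero (count logged). Skips follow a
  logistic model (intercept −2, −0.35/char, +0.3/Zipf; ≈ 30% skips). FFD
  equals GD with probability 0.6 (single first-pass fixation) and otherwise
  a U(0.4, 0.9) share of it; TRT adds an Exp(120 ms) rereading increment
  with probability 0.25, so FFD ≤ GD ≤ TRT always holds. All effect sizes
  are in the range reported for natural reading (a few ms per nat of
  surprisal, strong length/frequency effects).

**What passing tests show — and don't.** The generator produces Gaussian,
homoscedastic reading times with exactly linear (or exactly power-law)
links, exact Zipf frequencies and a memoryless text source. Real corpora
have skewed duration distributions, oculomotor dependencies between
neighbouring words, participant-by-item interactions and frequency
measurement error. Green tests therefore establish that the *pipeline*
recovers what it is pointed at under its own assumptions — effect recovery
to machine precision at zero noise, calibrated null behaviour of the
ΔLogLik test, detection of genuine nonlinearity — not that those assumptions
hold for any particular real dataset.

## Numerical conventions

Natural logs everywhere; conversions to bits belong to presentation.
Fold shuffles, the generator, and the permutation test each take explicit
seeds, and every seed is recorded in the outputs; identical configs
reproduce byte-identical files (digest-checked manifests). Problem sizes in
the shipped studies — 5,000 response rows for detection, 200 × 1,000-row
null corpora for calibration, 150 × 2,000-item corpora for the linearity
studies — were chosen as the smallest sizes at which the asymptotic
approximations involved are comfortably accurate.
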