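# surpread

**Psychometric evaluation of language-model surprisal against eye-movement
reading times.**

Readers slow down on words that are unpredictable in context. The standard
index of this difficulty is *surprisal*, `s(w_i) = −ln P(w_i | w_1 … w_{i−1})`,
the negative natural log of a word's conditional probability under a language
model. `surpread` implements the full evaluation chain that reading
researchers use to ask two questions of any autoregressive language model:

1. **Psychometric predictive power** — how much held-out log-likelihood does
   surprisal add to a reading-time regression beyond standard controls?
2. **Linking function** — is the effect of surprisal on reading time linear,
   or super-/sublinear?

It is a library for people who work with word-level eye-tracking tables
(first fixation duration, gaze duration, total reading time — the format
distributed by corpora such as RaCCooNS, MECO and GECO) and with per-token
log probabilities from any language model: the built-in add-k n-gram, or an
external transformer scored elsewhere and imported through a simple TSV
contract.

## What it computes

**Surprisal extraction.** Tokens are scored left-to-right; when a tokenizer
splits a word, the token log probabilities are summed, so word surprisal is
the word's exact chain-rule contribution (in nats). Texts longer than a
model's context window `W` are scored with a sliding window that advances in
steps of `⌊W/2⌋`, so every word keeps at least half a window of context.

**Cross-validated ΔLogLik.** For each eye-movement measure, a Gaussian
baseline regression (word length, Zipf frequency, sentence position, and the
previous word's length and frequency) is compared to the same model plus
surprisal of the current and previous word. Under tenfold cross-validation,

```
ΔLogLik per word = (1/k) Σ_folds [ ℓ_full(test fold) − ℓ_baseline(test fold) ] / n_test
```

with coefficients and error variance taken from the training folds. Fold
p-values come from an exact Gaussian likelihood-ratio (F) test within each
held-out fold and are combined across folds with Fisher's method,
`X = −2 Σ ln p_i ~ χ²_{2k}`. A meta-regression of the gains on model size
(per 100 M parameters, with corpus/measure main effects and size×corpus,
size×family interactions) quantifies scaling trends.

**Linearity of the linking function.** On participant-averaged gaze
durations, three penalized-spline additive models share a tenfold split: a
baseline with tensor-product smooths of frequency × length (current and
previous word), a model adding *linear* surprisal terms, and one adding
*smooth* surprisal terms. A paired sign-flip permutation test (N = 1,000) on
the fold-level held-out improvements asks whether the smooth model genuinely
beats the linear one. The spline engine (cubic B-splines, second-order
difference penalties, tensor products, REML/GCV smoothing selection) is
built in; an infinitely penalized smooth collapses exactly to the linear fit.

**Synthetic corpora with known truth.** A generator produces Zipfian
lexicons, text from a frozen Markov word model (true surprisal exact by
construction), and FFD/GD/TRT responses with configurable linear or
power-law surprisal effects, spillover, logistic skipping, participant
variability and Gaussian noise — so every stage is testable end-to-end
without any external data.

## Worked example

```python
import surpread as sp

config = sp.SyntheticConfig(
    structure=sp.TextStructure(kind="sentences", n_sentences=250),
    participants=4, seed=1234,
)
records, truth, _, _ = sp.make_corpus(config)
table, _ = sp.apply_exclusions(sp.attach_spillover(records, truth))
table = table.iloc[:5000]

for measure in ("ffd", "gd", "trt"):
    res = sp.cv_delta_loglik(table, sp.RegressionSpec(response=measure),
                             k=10, seed=77)
    print(f"{measure.upper():>4s}: ΔLogLik/1000 words = {res.per_1000:6.2f} "
          f"(SE {1000 * res.se:.2f}), Fisher p = {res.fisher_p:.2e}")
```

prints

```
 FFD: ΔLogLik/1000 words =   1.86 (SE 0.83), Fisher p = 3.43e-02
  GD: ΔLogLik/1000 words =   5.72 (SE 0.61), Fisher p = 3.44e-07
 TRT: ΔLogLik/1000 words =   0.03 (SE 0.19), Fisher p = 9.63e-01
```

Gaze duration gains 5.72 log-likelihood points per 1,000 words from the
surprisal terms — strong, reliable predictive power (the generator injects
the effect into first-pass reading). FFD inherits an attenuated effect, and
TRT drowns it in rereading noise: the per-measure pattern is itself a
finding. The `examples/` directory has one narrative script per capability
(surprisal scoring, corpus simulation, ΔLogLik evaluation, linearity
testing, the end-to-end pipeline).

A thin CLI mirrors the stages:

```bash
surpread simulate --seed 3 --out-corpus corpus.tsv --out-truth truth.tsv
surpread evaluate --corpus corpus.tsv --surprisal truth.tsv --measure gd --out eval.json
surpread run-all --config run.yaml
```

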