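"""Train an add-k n-gram, score a sentence, and aggregate to word surprisal.

Surprisal is the negative natural log of a word's conditional probability
given its preceding words — the standard index of processing difficulty
in reading research.  Long texts that exceed a model's context window are
scored with a sliding window that always keeps at least half a window of
left context.
"""

import numpy as np

import surpread as sp

training = [
    "de kat zit op de mat",
    "de hond ligt op de mat",
    "de kat en de hond slapen",
    "op de mat ligt een kat",
]
model = sp.train_ngram(training, order=3, add_k=0.5, max_context=8)
print(f"trained order-{model.order} model, vocabulary of {len(model.vocab)} types")

sentence = "de kat ligt op de mat".split()
scores = sp.score_sequence(model, sentence, bos_context=True)
per_word = sp.word_surprisal(scores, word_of_token=list(range(len(sentence))))
for w, s in zip(sentence, per_word["surprisal"]):
    print(f"  {w:>6s}  surprisal = {s:5.2f} nats")
print("high values mark words the model found unpredictable in context\n")

# a stream longer than the window: the window slides in half-window steps
long_stream = (sentence * 10)[:40]
scores = sp.score_sequence(model, long_stream, window=8)
print(f"scored {len(long_stream)} tokens with window 8;")
print(f"minimum context after the first window: "
      f"{scores.context_len_used[8:].min()} tokens (never below window/2 = 4)")
total = -scores.total_logprob()
print(f"total sequence surprisal: {total:.2f} nats "
      f"(= sum of the per-token values, chain rule)")
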