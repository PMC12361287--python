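"""Count-based n-gram language model with additive (add-k) smoothing.

The model satisfies the autoregressive language-model contract used by
the scoring machinery in :mod:`surpread.surprisal`: a ``vocab`` of
tokens, a ``max_context`` window size, and a ``logprob(context, next)``
method returning natural-log conditional probabilities that normalize
over the vocabulary for any fixed context.

Conditional probabilities are
``P(w | c) = (count(c, w) + k) / (count(c, ·) + k·|V|)``.
Sentences are padded on the left with ``order − 1`` boundary symbols;
no end-of-sentence event is modelled, so a sequence probability is the
probability of the words given the sentence segmentation.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Protocol, Sequence, runtime_checkable

import math

BOS = "<s>"
UNK = "<unk>"


@runtime_checkable
class LanguageModel(Protocol):
    """Contract every surprisal source must satisfy."""

    vocab: tuple
    max_context: int

    def logprob(self, context: Sequence, next_token) -> float: ...


class NGramModel:
    """Add-k smoothed n-gram model over whitespace tokens.

    Parameters
    ----------
    order
        n of the n-gram (1 = unigram).
    add_k
        Additive smoothing constant, > 0.
    max_context
        Longest context (in tokens) the model accepts; only the last
        ``order − 1`` tokens influence the prediction.  Contexts shorter
        than ``order − 1`` are implicitly left-padded with the sentence
        boundary symbol.
    unk
        Include an unknown-token symbol in the vocabulary (default).
        Without it the vocabulary is exactly the training types and
        out-of-vocabulary tokens raise ``KeyError``.
    """

    def __init__(self, order: int, add_k: float = 1.0, max_context: int = 512,
                 unk: bool = True):
        if order < 1:
            raise ValueError(f"order must be >= 1, got {order}")
        if add_k <= 0:
            raise ValueError(f"add_k must be > 0, got {add_k}")
        if max_context < 2:
            raise ValueError("max_context must be >= 2")
        self.order = order
        self.add_k = float(add_k)
        self.max_context = int(max_context)
        self.unk = bool(unk)
        self.counts: dict[tuple, Counter] = defaultdict(Counter)
        self.context_totals: Counter = Counter()
        self.vocab: tuple = ()
        self._vocab_set: set = set()

    # -- training -----------------------------------------------------
    def fit(self, lines: Iterable[str]) -> "NGramModel":
        """Accumulate counts from an iterable of sentences (one per line,
        whitespace tokenized)."""
        n_sent = 0
        types: set[str] = set()
        pad = (BOS,) * (self.order - 1)
        for line in lines:
            tokens = line.split()
            if not tokens:
                continue
            n_sent += 1
            types.update(tokens)
            padded = pad + tuple(tokens)
            for i in range(self.order - 1, len(padded)):
                ctx = padded[i - self.order + 1 : i]
                self.counts[ctx][padded[i]] += 1
                self.context_totals[ctx] += 1
        if n_sent == 0:
            raise ValueError("empty training corpus")
        self._vocab_set = types | {UNK} if self.unk else types
        self.vocab = tuple(sorted(self._vocab_set))
        return self

    # -- scoring ------------------------------------------------------
    def _normalize(self, token):
        if token in self._vocab_set:
            return token
        if not self.unk:
            raise KeyError(f"token {token!r} not in vocabulary")
        return UNK

    def _context_key(self, context: Sequence) -> tuple:
        need = self.order - 1
        if need == 0:
            return ()
        ctx = tuple(BOS if t == BOS else self._normalize(t) for t in context[-need:])
        if len(ctx) < need:
            ctx = (BOS,) * (need - len(ctx)) + ctx
        return ctx

    def prob(self, context: Sequence, next_token) -> float:
        """Smoothed conditional probability P(next | context)."""
        if not self.vocab:
            raise RuntimeError("model is untrained; call fit() first")
        if len(context) > self.max_context:
            raise ValueError(
                f"context length {len(context)} exceeds max_context {self.max_context}"
            )
        ctx = self._context_key(context)
        w = self._normalize(next_token)
        V = len(self.vocab)
        c = self.counts[ctx][w] if ctx in self.counts else 0
        tot = self.context_totals[ctx]
        return (c + self.add_k) / (tot + self.add_k * V)

    def logprob(self, context: Sequence, next_token) -> float:
        return math.log(self.prob(context, next_token))


def train_ngram(
    lines: Iterable[str], order: int, add_k: float = 1.0, max_context: int = 512,
    unk: bool = True,
) -> NGramModel:
    """Train an add-k n-gram model on a text stream (one sentence per line)."""
    return NGramModel(order=order, add_k=add_k, max_context=max_context,
                      unk=unk).fit(lines)
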