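"""Per-word surprisal from any autoregressive language model.

Surprisal is the negative natural logarithm of a word's conditional
probability given its preceding context, in nats.  When a tokenizer
splits a word into several tokens, the tokens' log probabilities are
summed, so word surprisal is exactly the chain-rule contribution of the
whole word.

Long texts that exceed a model's context window are scored with a
sliding window: tokens are conditioned on the full left context while it
fits, and on the first token that would exceed the window the start of
the context advances in steps of half the window, so that every later
token keeps at least half a window of context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ngram import BOS, LanguageModel


@dataclass
class TokenScores:
    """Per-token natural-log probabilities with alignment to words."""

    tokens: list
    logprobs: np.ndarray  # shape (n_tokens,), values <= 0
    context_len_used: np.ndarray  # ints
    word_of_token: np.ndarray | None = None  # monotone word indices

    def __post_init__(self):
        self.logprobs = np.asarray(self.logprobs, dtype=float)
        self.context_len_used = np.asarray(self.context_len_used, dtype=int)
        if self.word_of_token is not None:
            self.word_of_token = np.asarray(self.word_of_token, dtype=int)

    def total_logprob(self) -> float:
        return float(self.logprobs.sum())


def score_sequence(
    model: LanguageModel,
    tokens: Sequence,
    window: int | None = None,
    bos_context: bool = False,
) -> TokenScores:
    """Score a token sequence, sliding the context window as needed.

    Token ``i`` (1-based) is conditioned on its full left context while
    the window holds ``i`` tokens (context plus the token itself).  On
    the first token exceeding the window, the window start advances by
    ``⌊W/2⌋``, cascading as needed; every token after the first full
    window is thus conditioned on at least ``⌊W/2⌋`` tokens.

    Parameters
    ----------
    model
        Any object satisfying the language-model contract.
    tokens
        Non-empty token sequence.
    window
        Context window W; defaults to ``model.max_context``.
    bos_context
        If True, the model sees a sentence-boundary symbol to the left
        of the first window (sequence-initial conditioning); the symbol
        occupies no window slot and is not scored.
    """
    if len(tokens) == 0:
        raise ValueError("empty token sequence")
    W = int(window if window is not None else model.max_context)
    if W < 2:
        raise ValueError("window must be >= 2")
    tokens = list(tokens)
    logprobs = np.empty(len(tokens))
    ctx_len = np.empty(len(tokens), dtype=int)
    start = 0
    for i in range(len(tokens)):
        while i - start + 1 > W:
            start += W // 2
        context = tokens[start:i]
        if bos_context and start == 0:
            context = [BOS] + context
        logprobs[i] = model.logprob(context, tokens[i])
        ctx_len[i] = i - start
    return TokenScores(tokens=tokens, logprobs=logprobs, context_len_used=ctx_len)


def score_sentences(
    model: LanguageModel, sentences: Sequence[Sequence], window: int | None = None
) -> TokenScores:
    """Score independent sentences (context resets at each boundary).

    Each sentence is conditioned from its own start, with the model's
    boundary padding supplying sequence-initial context.  Results are
    concatenated in order.
    """
    parts = [score_sequence(model, s, window=window, bos_context=True) for s in sentences]
    return TokenScores(
        tokens=[t for p in parts for t in p.tokens],
        logprobs=np.concatenate([p.logprobs for p in parts]),
        context_len_used=np.concatenate([p.context_len_used for p in parts]),
    )


def word_surprisal(
    token_logprobs: np.ndarray | TokenScores,
    word_of_token: Sequence[int] | None = None,
    context_len_used: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Aggregate token log probabilities to word surprisal (nats).

    Per word: ``surprisal = −Σ log P(token)`` over the word's tokens.

    Parameters
    ----------
    token_logprobs
        Array of per-token natural-log probabilities, or a
        :class:`TokenScores` carrying its own alignment.
    word_of_token
        Word index of each token; must be monotone non-decreasing with
        no gaps, every token assigned.

    Returns
    -------
    pandas.DataFrame
        Columns ``word_index``, ``surprisal``, ``n_tokens``,
        ``context_len_used`` (minimum over the word's tokens).
    """
    if isinstance(token_logprobs, TokenScores):
        scores = token_logprobs
        lp = scores.logprobs
        if word_of_token is None:
            word_of_token = scores.word_of_token
        if context_len_used is None:
            context_len_used = scores.context_len_used
    else:
        lp = np.asarray(token_logprobs, dtype=float)
    if word_of_token is None:
        raise ValueError("token without word assignment: no word_of_token given")
    w = np.asarray(word_of_token)
    if len(w) != len(lp):
        raise ValueError("token without word assignment: alignment length mismatch")
    if np.any(w < 0):
        raise ValueError("token without word assignment: negative word index")
    if np.any(np.diff(w) < 0) or np.any(np.diff(w) > 1) or (len(w) and w[0] != 0):
        raise ValueError("word_of_token must be monotone non-decreasing without gaps")
    cl = (
        np.asarray(context_len_used, dtype=int)
        if context_len_used is not None
        else np.zeros(len(lp), dtype=int)
    )
    df = pd.DataFrame({"word_index": w, "logprob": lp, "ctx": cl})
    out = df.groupby("word_index", sort=True).agg(
        surprisal=("logprob", lambda s: -s.sum()),
        n_tokens=("logprob", "size"),
        context_len_used=("ctx", "min"),
    )
    return out.reset_index()


def import_external_logprobs(path, sep: str = "\t") -> TokenScores:
    """Read per-token log probabilities produced by an external model.

    Expected columns: ``token``, ``word_index``, ``logprob_nat``,
    ``context_len_used``.  Word indices must be 0-based, monotone
    non-decreasing and gap-free; log probabilities must be finite and
    ≤ 0.
    """
    df = pd.read_csv(path, sep=sep, dtype={"token": str})
    required = ["token", "word_index", "logprob_nat", "context_len_used"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"column '{col}' not found in {path}")
    for i, col in enumerate(["word_index", "logprob_nat", "context_len_used"]):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2  # header is line 1
            raise ValueError(f"malformed row at line {line}: non-numeric '{col}'")
        df[col] = vals
    lp = df["logprob_nat"].to_numpy(float)
    if np.any(lp > 0):
        line = int(np.flatnonzero(lp > 0)[0]) + 2
        raise ValueError(f"positive log probability at line {line}")
    if np.any(~np.isfinite(lp)):
        line = int(np.flatnonzero(~np.isfinite(lp))[0]) + 2
        raise ValueError(f"non-finite log probability at line {line}")
    w = df["word_index"].to_numpy(int)
    if np.any(np.diff(w) < 0) or np.any(np.diff(w) > 1):
        raise ValueError("word_index must be monotone non-decreasing without gaps")
    return TokenScores(
        tokens=df["token"].tolist(),
        logprobs=lp,
        context_len_used=df["context_len_used"].to_numpy(int),
        word_of_token=w - w[0] if len(w) else w,
    )


def surprisal_table_for_words(
    words: pd.DataFrame, per_word: pd.DataFrame
) -> pd.DataFrame:
    """Key a per-word surprisal frame by corpus word identity.

    ``words`` must have one row per distinct word in text-stream order
    with ``text_id, sentence_id, word_pos`` columns; ``per_word`` is the
    output of :func:`word_surprisal` in the same order.
    """
    if len(words) != len(per_word):
        raise ValueError(
            f"word count mismatch: {len(words)} corpus words, "
            f"{len(per_word)} surprisal rows"
        )
    out = words[["text_id", "sentence_id", "word_pos"]].reset_index(drop=True).copy()
    out[["surprisal", "n_tokens", "context_len_used"]] = per_word[
        ["surprisal", "n_tokens", "context_len_used"]
    ].reset_index(drop=True)
    return out
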