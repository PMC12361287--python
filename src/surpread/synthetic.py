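"""Synthetic reading corpora with exactly known ground truth.

The generator produces everything the pipeline consumes, with the true
data-generating quantities recorded alongside:

* a Zipfian lexicon (rank-frequency law, frequency-dependent lengths);
* text sampled from a fixed first-order Markov word model whose
  conditional distributions are drawn once (Dirichlet with a Zipfian
  mean) and then frozen — so the true surprisal of every generated word
  is exactly the negative log of its generating probability;
* per-participant reading measures (FFD/GD/TRT) with configurable
  linear or power-law surprisal effects, spillover from the previous
  word, a logistic skipping model, participant intercepts and Gaussian
  noise.

Texts come in three shapes mirroring common eye-tracking corpora:
isolated sentences, paragraphs, or a single book-length stream (the
latter long enough to force sliding-window scoring downstream).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ngram import BOS

_LETTERS = np.array(list(string.ascii_lowercase))


# ---------------------------------------------------------------- lexicon


@dataclass
class SyntheticLexicon:
    """Zipfian vocabulary: rank, relative frequency, Zipf value, length."""

    table: pd.DataFrame  # columns: word_form, rank, rel_freq, zipf_freq, length_chars

    @property
    def words(self) -> np.ndarray:
        return self.table["word_form"].to_numpy()


def make_lexicon(V: int, zipf_exponent: float = 1.0, seed: int = 0) -> SyntheticLexicon:
    """Build a V-word lexicon with rank-frequency ∝ rank^(−s).

    Zipf values are log10(relative frequency × 1e9); lengths are drawn
    from a rank-dependent distribution so frequent words are shorter on
    average.  Deterministic per seed.
    """
    if V < 2:
        raise ValueError("need a vocabulary of at least 2 words")
    if zipf_exponent <= 0:
        raise ValueError("zipf_exponent must be > 0")
    rng = np.random.default_rng(seed)
    rank = np.arange(1, V + 1)
    rel = rank.astype(float) ** (-zipf_exponent)
    rel /= rel.sum()
    zipf = np.log10(rel * 1e9)

    mean_len = 1.5 + 1.6 * np.log1p(rank) / np.log(10)
    length = 1 + rng.poisson(np.maximum(mean_len - 1, 0.1))
    length = np.clip(length, 1, 14)

    forms, seen = [], set()
    for L in length:
        for _ in range(100):
            w = "".join(rng.choice(_LETTERS, size=L))
            if w not in seen:
                break
            w = w + "".join(rng.choice(_LETTERS, size=1))
        seen.add(w)
        forms.append(w)

    return SyntheticLexicon(
        pd.DataFrame(
            {
                "word_form": forms,
                "rank": rank,
                "rel_freq": rel,
                "zipf_freq": zipf,
                "length_chars": [len(f) for f in forms],
            }
        )
    )


# ----------------------------------------------------------- generator LM


class GeneratorLM:
    """First-order Markov word model with frozen random conditionals.

    Each context's next-word distribution is drawn once from a Dirichlet
    whose mean follows the lexicon's Zipfian frequencies, then fixed.
    Satisfies the autoregressive language-model contract, so the scoring
    machinery can re-derive the generator's own true surprisal exactly.
    """

    def __init__(self, lexicon: SyntheticLexicon, concentration: float = 50.0,
                 seed: int = 0, max_context: int = 512):
        rng = np.random.default_rng(seed)
        self.vocab = tuple(lexicon.words)
        self.max_context = int(max_context)
        self._index = {w: i for i, w in enumerate(self.vocab)}
        alpha = concentration * lexicon.table["rel_freq"].to_numpy()
        alpha = np.maximum(alpha, 1e-3)
        V = len(self.vocab)
        # rows: context words 0..V-1 plus the boundary context at row V
        self.probs = rng.dirichlet(alpha, size=V + 1)
        self._cum = np.cumsum(self.probs, axis=1)
        self._cum[:, -1] = 1.0

    def _row(self, context) -> int:
        if len(context) == 0 or context[-1] == BOS:
            return len(self.vocab)
        return self._index[context[-1]]

    def logprob(self, context, next_token) -> float:
        if len(context) > self.max_context:
            raise ValueError("context exceeds max_context")
        return float(np.log(self.probs[self._row(context), self._index[next_token]]))

    def sample_next(self, context, rng: np.random.Generator) -> tuple[str, float]:
        """Draw the next word; returns (word, true surprisal in nats)."""
        row = self._row(context)
        j = int(np.searchsorted(self._cum[row], rng.random(), side="right"))
        j = min(j, len(self.vocab) - 1)
        return self.vocab[j], float(-np.log(self.probs[row, j]))

    def stationary_distribution(self) -> np.ndarray:
        P = self.probs[:-1]  # word-context rows only
        pi = np.full(P.shape[0], 1.0 / P.shape[0])
        for _ in range(500):
            nxt = pi @ P
            if np.abs(nxt - pi).max() < 1e-13:
                break
            pi = nxt
        return pi / pi.sum()

    def entropy_rate(self) -> float:
        """Expected surprisal (nats/word) under the stationary context law."""
        pi = self.stationary_distribution()
        H_rows = -np.sum(self.probs[:-1] * np.log(self.probs[:-1]), axis=1)
        return float(pi @ H_rows)


# ------------------------------------------------------------- structure


@dataclass
class TextStructure:
    """Shape of the generated text.

    ``sentences``: independent sentences (context resets at each one).
    ``paragraphs``: independent paragraphs; context flows across the
    sentences inside a paragraph.  ``book``: one continuous stream.
    """

    kind: str = "sentences"
    n_sentences: int = 200
    sentence_len: tuple[int, int] = (5, 30)
    n_paragraphs: int = 12
    paragraph_len: tuple[int, int] = (161, 213)
    book_words: int = 50_000


@dataclass
class SyntheticConfig:
    """Full generative specification of a synthetic reading corpus."""

    structure: TextStructure = field(default_factory=TextStructure)
    vocab_size: int = 250
    zipf_exponent: float = 1.0
    concentration: float = 50.0
    participants: int = 1
    intercept_ms: float = 200.0
    beta_surprisal: float = 3.0  # ms per nat (per nat^gamma for power links)
    beta_prev_surprisal: float = 1.5
    beta_length: float = 6.0  # ms per character
    beta_zipf: float = -8.0  # ms per Zipf unit
    beta_pos: float = -0.3  # ms per within-sentence position
    participant_sd: float = 20.0
    link: str = "linear"  # or "power"
    gamma: float = 1.0  # exponent of the power link
    noise_sd_ms: float = 30.0
    skip_intercept: float = -2.0
    skip_length: float = -0.35
    skip_zipf: float = 0.3
    punct_rate: float = 0.1
    ffd_single_fix_prob: float = 0.6
    ffd_share: tuple[float, float] = (0.4, 0.9)
    reread_prob: float = 0.25
    reread_mean_ms: float = 120.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["structure"] = asdict(self.structure)
        return d


def _link(s: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    if config.link == "linear":
        return s
    if config.link == "power":
        return np.power(s, config.gamma)
    raise ValueError(f"unknown link: {config.link}")


# ----------------------------------------------------------- text sampling


def sample_text(
    lexicon: SyntheticLexicon,
    generator: GeneratorLM,
    structure: TextStructure | None = None,
    seed: int = 0,
    punct_rate: float = 0.1,
) -> pd.DataFrame:
    """Sample a word stream of the requested shape with true surprisal.

    Returns one row per word with text/sentence/position keys, lexical
    covariates, punctuation and sentence-initial flags, and the exact
    surprisal of the word under the generating model.
    """
    structure = structure or TextStructure()
    rng = np.random.default_rng(seed)
    lex = lexicon.table.set_index("word_form")

    if structure.kind == "sentences":
        streams = [
            rng.integers(structure.sentence_len[0], structure.sentence_len[1] + 1, size=1)
            for _ in range(structure.n_sentences)
        ]
        stream_lens = [int(s[0]) for s in streams]
        sent_bounds = [[L] for L in stream_lens]
    elif structure.kind == "paragraphs":
        stream_lens, sent_bounds = [], []
        for _ in range(structure.n_paragraphs):
            total = int(rng.integers(structure.paragraph_len[0], structure.paragraph_len[1] + 1))
            stream_lens.append(total)
            sent_bounds.append(_chop(total, structure.sentence_len, rng))
    elif structure.kind == "book":
        total = int(structure.book_words)
        stream_lens = [total]
        sent_bounds = [_chop(total, structure.sentence_len, rng)]
    else:
        raise ValueError(f"unknown structure kind: {structure.kind}")

    rows = []
    for text_id, (n_words, sent_lens) in enumerate(zip(stream_lens, sent_bounds)):
        prev = BOS
        words, surps = [], []
        for _ in range(n_words):
            w, s = generator.sample_next([prev], rng)
            words.append(w)
            surps.append(s)
            prev = w
        pos_in_sent, sent_ids, sent_final = [], [], []
        for sid, L in enumerate(sent_lens):
            pos_in_sent.extend(range(1, L + 1))
            sent_ids.extend([sid] * L)
            sent_final.extend([False] * (L - 1) + [True])
        punct = rng.random(n_words) < punct_rate
        punct |= np.asarray(sent_final)
        for i in range(n_words):
            rows.append(
                (
                    text_id,
                    sent_ids[i],
                    pos_in_sent[i],
                    words[i],
                    int(lex.at[words[i], "length_chars"]),
                    float(lex.at[words[i], "zipf_freq"]),
                    bool(punct[i]),
                    pos_in_sent[i] == 1,
                    surps[i],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "text_id",
            "sentence_id",
            "word_pos",
            "word_form",
            "length_chars",
            "zipf_freq",
            "has_punct",
            "is_sentence_initial",
            "true_surprisal",
        ],
    )


def _chop(total: int, bounds: tuple[int, int], rng: np.random.Generator) -> list[int]:
    """Split ``total`` words into sentence lengths within ``bounds``."""
    lo, hi = bounds
    out, left = [], total
    while left > 0:
        L = int(rng.integers(lo, hi + 1))
        if left - L < lo:
            L = left
        out.append(min(L, left))
        left -= out[-1]
    return out


# --------------------------------------------------------- reading model


def simulate_reading(text: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Simulate participant × word reading measures from a sampled text.

    Gaze duration follows the additive model
    ``GD = β0 + βs·g(s) + βps·g(s_prev) + βlen·len + βzipf·zipf
    + βpos·pos + u_participant + ε`` with ``g`` the identity (linear
    link) or a power function; skips follow a logistic model in length
    and frequency; FFD is a first-pass share of GD and TRT adds a
    non-negative rereading increment, so FFD ≤ GD ≤ TRT on every row.
    Negative durations are resampled (truncation at zero); the count is
    exposed as ``result.attrs["n_resampled"]``.
    """
    rng = np.random.default_rng(config.seed)
    n = len(text)
    s = text["true_surprisal"].to_numpy()
    prev_s = (
        text.groupby("text_id", sort=False)["true_surprisal"].shift(1).fillna(0.0).to_numpy()
    )
    base = (
        config.intercept_ms
        + config.beta_surprisal * _link(s, config)
        + config.beta_prev_surprisal * _link(prev_s, config)
        + config.beta_length * text["length_chars"].to_numpy()
        + config.beta_zipf * text["zipf_freq"].to_numpy()
        + config.beta_pos * text["word_pos"].to_numpy()
    )
    skip_logit = (
        config.skip_intercept
        + config.skip_length * text["length_chars"].to_numpy()
        + config.skip_zipf * text["zipf_freq"].to_numpy()
    )
    p_skip = 1.0 / (1.0 + np.exp(-skip_logit))

    frames = []
    n_resampled = 0
    for p in range(config.participants):
        u = rng.normal(0.0, config.participant_sd) if config.participant_sd > 0 else 0.0
        skipped = rng.random(n) < p_skip
        gd = base + u + (rng.normal(0.0, config.noise_sd_ms, n) if config.noise_sd_ms > 0 else 0.0)
        neg = gd <= 0
        while neg.any():
            n_resampled += int(neg.sum())
            gd[neg] = base[neg] + u + rng.normal(0.0, config.noise_sd_ms, int(neg.sum()))
            if config.noise_sd_ms == 0:
                raise ValueError("negative duration with zero noise; check effect sizes")
            neg = gd <= 0
        single = rng.random(n) < config.ffd_single_fix_prob
        share = rng.uniform(*config.ffd_share, n)
        ffd = np.where(single, gd, gd * share)
        reread = (rng.random(n) < config.reread_prob) * rng.exponential(
            config.reread_mean_ms, n
        )
        trt = gd + reread

        df = text[
            ["text_id", "sentence_id", "word_pos", "word_form", "length_chars",
             "zipf_freq", "has_punct", "is_sentence_initial"]
        ].copy()
        df.insert(0, "participant_id", f"p{p:03d}")
        df["ffd_ms"] = np.where(skipped, np.nan, ffd)
        df["gd_ms"] = np.where(skipped, np.nan, gd)
        df["trt_ms"] = np.where(skipped, np.nan, trt)
        df["skipped"] = skipped
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_resampled"] = n_resampled
    return out


def make_corpus(config: SyntheticConfig):
    """Generate lexicon, generator model, text and reading data in one call.

    Returns ``(records, truth, lexicon, generator)`` where ``truth`` is
    the per-word table with exact surprisal (column ``surprisal``)
    keyed by text/sentence/position.
    """
    lexicon = make_lexicon(config.vocab_size, config.zipf_exponent, seed=config.seed)
    generator = GeneratorLM(
        lexicon, concentration=config.concentration, seed=config.seed + 1
    )
    text = sample_text(
        lexicon, generator, config.structure, seed=config.seed + 2,
        punct_rate=config.punct_rate,
    )
    records = simulate_reading(text, config)
    truth = text[["text_id", "sentence_id", "word_pos", "true_surprisal"]].rename(
        columns={"true_surprisal": "surprisal"}
    )
    return records, truth, lexicon, generator
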