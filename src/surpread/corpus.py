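"""Word-level eye-tracking corpus tables: reading, validation, exclusion
filtering, spillover construction and item-level averaging.

A corpus is held as a :class:`pandas.DataFrame` with one row per
participant × word and the canonical columns listed in
:data:`WORD_COLUMNS`.  Reading times are in milliseconds; a skipped word
(no first-pass fixation) carries missing/zero gaze duration.  Word
frequency is on the Zipf scale (log10 occurrences per billion words).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical column names of a word-level corpus table
WORD_COLUMNS = [
    "participant_id",
    "text_id",
    "sentence_id",
    "word_pos",
    "word_form",
    "length_chars",
    "zipf_freq",
    "has_punct",
    "is_sentence_initial",
    "ffd_ms",
    "gd_ms",
    "trt_ms",
    "skipped",
]

#: columns that must be present in an input file (the rest are derivable)
REQUIRED_COLUMNS = [
    "participant_id",
    "text_id",
    "sentence_id",
    "word_pos",
    "word_form",
    "zipf_freq",
    "ffd_ms",
    "gd_ms",
    "trt_ms",
]

MEASURES = ("ffd_ms", "gd_ms", "trt_ms")

# Any character outside letters and digits counts as punctuation when
# attached to a word token, including apostrophes and hyphens.
_PUNCT_RE = re.compile(r"[^\w]|_", re.UNICODE)

#: ordering of text streams; spillover predecessors follow this order
STREAM_KEY = ["text_id", "sentence_id", "word_pos"]


class CorpusError(ValueError):
    """Raised for malformed or invariant-violating corpus input."""


def has_attached_punctuation(word_form: str) -> bool:
    """True if the token carries any non-alphanumeric character
    (apostrophes and hyphens included)."""
    return bool(_PUNCT_RE.search(str(word_form)))


def read_corpus(
    path,
    format_spec: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited word-level eye-tracking table.

    Parameters
    ----------
    path
        Delimited UTF-8 text file with a header row.
    format_spec
        Mapping from canonical column name (e.g. ``"gd_ms"``) to the
        column name used in the file.  Canonical names not listed are
        looked up verbatim.
    sep
        Field separator; inferred from the extension when ``None``
        (``.csv`` → comma, otherwise tab).

    Returns
    -------
    pandas.DataFrame
        One row per participant × word with all of :data:`WORD_COLUMNS`.
        ``has_punct`` and ``is_sentence_initial`` are derived when not
        supplied; ``skipped`` is derived from gaze duration.
    """
    format_spec = dict(format_spec or {})
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, dtype={format_spec.get("word_form", "word_form"): str})
    if raw.empty:
        raise CorpusError(f"empty corpus file: {path}")

    out = pd.DataFrame(index=raw.index)
    for canon in WORD_COLUMNS:
        src = format_spec.get(canon, canon)
        if src in raw.columns:
            out[canon] = raw[src]
        elif canon in REQUIRED_COLUMNS:
            raise CorpusError(f"column '{canon}' not found in {path}")

    for col in ("word_pos",):
        out[col] = pd.to_numeric(out[col], errors="raise").astype(int)
    for col in ("zipf_freq",) + MEASURES:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() & out[col].notna()
        if bad.any():
            raise CorpusError(
                f"non-numeric value in column '{col}' at row index {int(bad.idxmax())}"
            )
        out[col] = vals

    if "length_chars" not in out:
        out["length_chars"] = out["word_form"].map(
            lambda w: max(len(_PUNCT_RE.sub("", str(w))), 1)
        )
    out["length_chars"] = out["length_chars"].astype(int)
    if "has_punct" not in out:
        out["has_punct"] = out["word_form"].map(has_attached_punctuation)
    out["has_punct"] = out["has_punct"].astype(bool)
    if "is_sentence_initial" not in out:
        out["is_sentence_initial"] = out["word_pos"] == 1
    out["is_sentence_initial"] = out["is_sentence_initial"].astype(bool)
    if "skipped" not in out:
        out["skipped"] = out["gd_ms"].isna() | (out["gd_ms"] == 0)
    out["skipped"] = out["skipped"].astype(bool)

    validate_corpus(out)
    return out[WORD_COLUMNS]


def validate_corpus(table: pd.DataFrame) -> None:
    """Check the row-level invariants of a word-level table.

    Raises :class:`CorpusError` on the first violation found:
    measure nesting FFD ≤ GD ≤ TRT, the skip/gaze-duration equivalence,
    Zipf values inside [0, 9] and word positions ≥ 1.
    """
    fixated = ~table["skipped"]
    ffd, gd, trt = (table.loc[fixated, m].to_numpy(float) for m in MEASURES)
    both = ~np.isnan(ffd) & ~np.isnan(gd)
    if np.any(ffd[both] > gd[both] + 1e-9):
        i = table.index[fixated][both][ffd[both] > gd[both] + 1e-9][0]
        raise CorpusError(f"measure nesting violated (ffd > gd) at row {i}")
    both = ~np.isnan(gd) & ~np.isnan(trt)
    if np.any(gd[both] > trt[both] + 1e-9):
        i = table.index[fixated][both][gd[both] > trt[both] + 1e-9][0]
        raise CorpusError(f"measure nesting violated (gd > trt) at row {i}")

    gd_all = table["gd_ms"]
    implied_skip = gd_all.isna() | (gd_all == 0)
    if (table["skipped"] != implied_skip).any():
        i = table.index[table["skipped"] != implied_skip][0]
        raise CorpusError(f"skip flag inconsistent with gaze duration at row {i}")

    zipf = table["zipf_freq"].to_numpy(float)
    ok = np.isnan(zipf) | ((zipf >= 0) & (zipf <= 9))
    if not ok.all():
        raise CorpusError("zipf_freq outside [0, 9]")
    if (table["word_pos"] < 1).any():
        raise CorpusError("word_pos must be >= 1")
    if (table["is_sentence_initial"] != (table["word_pos"] == 1)).any():
        raise CorpusError("is_sentence_initial flag inconsistent with word_pos")


@dataclass
class ExclusionReport:
    """Row counts removed by each exclusion rule, in application order."""

    n_input: int = 0
    removed_punct: int = 0
    removed_sentence_initial: int = 0
    removed_oov: int = 0
    removed_skipped: int = 0
    n_retained: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def apply_exclusions(
    table: pd.DataFrame, vocab: set[str] | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove response rows excluded from the reading-time analyses.

    Rules, applied in order: (1) word attached to any punctuation mark,
    (2) sentence-initial word, (3) word form outside ``vocab`` when a
    vocabulary is given, (4) skipped word (no first-pass fixation).
    The retained set is order-independent; only the per-rule counts in
    the report depend on the order.
    """
    report = ExclusionReport(n_input=len(table))
    keep = pd.Series(True, index=table.index)

    rule = table["has_punct"] & keep
    report.removed_punct = int(rule.sum())
    keep &= ~rule

    rule = table["is_sentence_initial"] & keep
    report.removed_sentence_initial = int(rule.sum())
    keep &= ~rule

    if vocab is not None:
        rule = ~table["word_form"].isin(vocab) & keep
        report.removed_oov = int(rule.sum())
        keep &= ~rule

    rule = table["skipped"] & keep
    report.removed_skipped = int(rule.sum())
    keep &= ~rule

    report.n_retained = int(keep.sum())
    return table.loc[keep].copy(), report


def attach_spillover(table: pd.DataFrame, surprisal: pd.DataFrame) -> pd.DataFrame:
    """Join per-word surprisal and previous-word (spillover) predictors.

    ``surprisal`` must cover every word of every text stream — including
    words later excluded as responses, since an excluded word still
    serves as the predecessor context of the next word.  The join is
    therefore performed on the full word inventory before any response
    filtering; apply :func:`apply_exclusions` afterwards (or before, on
    the response side only).

    Parameters
    ----------
    table
        Word-level table (one row per participant × word).
    surprisal
        Table keyed by ``text_id, sentence_id, word_pos`` with a
        ``surprisal`` column in nats, one row per distinct word.

    Returns
    -------
    pandas.DataFrame
        ``table`` with ``surprisal``, ``prev_surprisal``, ``prev_length``
        and ``prev_zipf`` columns added.  The first word of each text
        stream has no predecessor and yields no response row.
    """
    key = STREAM_KEY
    sur = surprisal.drop_duplicates(subset=key).set_index(key)["surprisal"]

    # one row per distinct word, in text-stream order, pre-exclusion
    words = (
        table.drop_duplicates(subset=key)
        .sort_values(key, kind="mergesort")
        .loc[:, key + ["length_chars", "zipf_freq"]]
        .reset_index(drop=True)
    )
    idx = pd.MultiIndex.from_frame(words[key])
    missing = ~idx.isin(sur.index)
    if missing.any():
        t, s, w = words.loc[np.flatnonzero(missing)[0], key]
        raise CorpusError(
            f"no surprisal entry for word at text={t} sentence={s} pos={w}"
        )
    words["surprisal"] = sur.loc[idx].to_numpy()

    grp = words.groupby("text_id", sort=False)
    words["prev_surprisal"] = grp["surprisal"].shift(1)
    words["prev_length"] = grp["length_chars"].shift(1)
    words["prev_zipf"] = grp["zipf_freq"].shift(1)

    out = table.merge(
        words[key + ["surprisal", "prev_surprisal", "prev_length", "prev_zipf"]],
        on=key,
        how="left",
        validate="many_to_one",
    )
    out = out[out["prev_surprisal"].notna()].copy()
    out["prev_length"] = out["prev_length"].astype(int)
    return out


def average_item_gd(table: pd.DataFrame) -> pd.DataFrame:
    """Average non-zero gaze durations over participants, per word.

    Expects a table already filtered of punctuation-attached and
    sentence-initial words.  Words never fixated by any participant are
    absent from the output.  Covariate columns (length, Zipf frequency
    and, when present, surprisal and spillover predictors) are carried
    over; they are constant within a word.
    """
    fixated = table[table["gd_ms"].notna() & (table["gd_ms"] > 0)]
    key = STREAM_KEY + ["word_form"]
    carry = [
        c
        for c in ("length_chars", "zipf_freq", "word_pos", "surprisal",
                  "prev_surprisal", "prev_length", "prev_zipf")
        if c in table.columns and c not in key
    ]
    agg = fixated.groupby(key, sort=True).agg(
        mean_gd_ms=("gd_ms", "mean"), n_contributing=("gd_ms", "size"),
        **{c: (c, "first") for c in carry},
    )
    return agg.reset_index()


def write_corpus(table: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a word-level table as delimited text (same dialect as read)."""
    table.to_csv(path, sep=sep, index=False)
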