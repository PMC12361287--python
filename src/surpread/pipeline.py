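"""End-to-end orchestration: simulate → score → evaluate → linearity.

A single :class:`RunConfig` drives all stages; every stochastic step is
seeded from the config, all outputs are written as delimited text or
JSON, and a manifest records per-stage outputs with content digests so a
re-run of the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .corpus import (
    apply_exclusions,
    attach_spillover,
    average_item_gd,
    read_corpus,
    write_corpus,
)
from .evaluation import RegressionSpec, cv_delta_loglik
from .linearity import cv_linearity, linearity_model_terms, predict_slowdown_curve
from .gam import fit_gam
from .ngram import train_ngram
from .surprisal import score_sequence, surprisal_table_for_words, word_surprisal
from .synthetic import SyntheticConfig, TextStructure, make_corpus

log = logging.getLogger("surpread")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "surpread_run"
    corpus_path: str | None = None  # read this corpus instead of simulating
    column_map: dict = field(default_factory=dict)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    lm_source: str = "truth"  # "truth" | "ngram"
    ngram_order: int = 5
    ngram_add_k: float = 1.0
    ngram_train_path: str | None = None  # default: train on the generated text
    measures: tuple[str, ...] = ("ffd", "gd", "trt")
    k: int = 10
    fold_seed: int = 17
    perm_seed: int = 29
    n_perm: int = 1000
    p_source: str = "fold_exact"
    tensor_dim: tuple[int, int] = (5, 5)
    smooth_dim: int = 10

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.lm_source not in ("truth", "ngram"):
            raise ValueError(f"unknown lm_source: {self.lm_source}")
        bad = set(self.measures) - {"ffd", "gd", "trt"}
        if bad:
            raise ValueError(f"unknown measures: {sorted(bad)}")
        if self.lm_source == "truth" and self.corpus_path is not None:
            raise ValueError("lm_source='truth' requires a simulated corpus")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        if isinstance(syn, dict):
            struct = syn.pop("structure", {})
            if isinstance(struct, dict):
                struct = TextStructure(**struct)
            syn = SyntheticConfig(structure=struct, **syn)
        cfg = cls(synthetic=syn, **d)
        for tup_field in ("measures", "tensor_dim"):
            setattr(cfg, tup_field, tuple(getattr(cfg, tup_field)))
        return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _text_streams(words: pd.DataFrame) -> list[list[str]]:
    ordered = words.sort_values(["text_id", "sentence_id", "word_pos"], kind="mergesort")
    return [g["word_form"].tolist() for _, g in ordered.groupby("text_id", sort=True)]


def score_corpus_with_ngram(words: pd.DataFrame, model) -> pd.DataFrame:
    """Score every distinct word of a corpus with an n-gram model.

    Each text stream is scored continuously (sliding window if it
    exceeds the model's context window), with boundary padding supplying
    sequence-initial context.  Returns a surprisal table keyed by
    text/sentence/position.
    """
    key = ["text_id", "sentence_id", "word_pos"]
    distinct = words.drop_duplicates(subset=key).sort_values(key, kind="mergesort")
    per_word_frames = []
    for _, grp in distinct.groupby("text_id", sort=True):
        tokens = grp["word_form"].tolist()
        scores = score_sequence(model, tokens, bos_context=True)
        pw = word_surprisal(scores, word_of_token=np.arange(len(tokens)))
        pw[key] = grp[key].reset_index(drop=True)
        per_word_frames.append(pw)
    out = pd.concat(per_word_frames, ignore_index=True)
    return out[key + ["surprisal", "n_tokens", "context_len_used"]]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write outputs plus a manifest under
    ``config.out_dir``.  Returns the result bundle as a dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seeds": {
            "simulation": config.synthetic.seed,
            "folds": config.fold_seed,
            "permutation": config.perm_seed,
        },
        "stages": [],
    }
    bundle: dict = {}

    def record(stage: str, outputs: list[Path], counts: dict) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {p.name: _digest(p) for p in outputs},
                "row_counts": counts,
            }
        )
        log.info("stage %s: %s", stage, counts)

    # --- stage 1: simulate (or read) ---------------------------------
    try:
        if config.corpus_path is None:
            records, truth, lexicon, generator = make_corpus(config.synthetic)
            corpus_path = out / "corpus.tsv"
            truth_path = out / "truth.tsv"
            write_corpus(records, corpus_path)
            truth.to_csv(truth_path, sep="\t", index=False)
            record("simulate", [corpus_path, truth_path],
                   {"rows": len(records), "words": len(truth)})
        else:
            records = read_corpus(config.corpus_path, config.column_map)
            truth = None
            record("simulate", [], {"rows": len(records), "source": "file"})
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    # --- stage 2: score -----------------------------------------------
    try:
        if config.lm_source == "truth":
            surprisal = truth
            vocab = None
        else:
            if config.ngram_train_path:
                with open(config.ngram_train_path, encoding="utf-8") as fh:
                    model = train_ngram(fh, config.ngram_order, config.ngram_add_k)
            else:
                streams = _text_streams(records)
                model = train_ngram(
                    (" ".join(s) for s in streams), config.ngram_order, config.ngram_add_k
                )
            surprisal = score_corpus_with_ngram(records, model)
            vocab = set(model.vocab)
        sur_path = out / "surprisal.tsv"
        surprisal.to_csv(sur_path, sep="\t", index=False)
        record("score", [sur_path], {"words": len(surprisal)})
    except Exception as e:
        raise RuntimeError(f"stage 'score' failed: {e}") from e

    # --- stage 3: evaluate --------------------------------------------
    try:
        analysis = attach_spillover(records, surprisal)
        filtered, report = apply_exclusions(analysis, vocab=vocab)
        (out / "exclusion_report.json").write_text(report.to_json() + "\n")
        bundle["exclusions"] = report
        eval_results = {}
        for measure in config.measures:
            res = cv_delta_loglik(
                filtered,
                RegressionSpec(response=measure),
                k=config.k,
                seed=config.fold_seed,
                p_source=config.p_source,
                metadata={"measure": measure, "model": config.lm_source},
            )
            eval_results[measure] = res
            _write_json(res.to_dict(), out / f"eval_{measure}.json")
            pd.DataFrame([asdict(f) for f in res.folds]).to_csv(
                out / f"eval_{measure}_folds.tsv", sep="\t", index=False
            )
        bundle["eval"] = eval_results
        record(
            "evaluate",
            [out / f"eval_{m}.json" for m in config.measures]
            + [out / "exclusion_report.json"],
            {"analysis_rows": len(filtered)},
        )
    except Exception as e:
        raise RuntimeError(f"stage 'evaluate' failed: {e}") from e

    # --- stage 4: linearity -------------------------------------------
    try:
        # item analysis keeps skipped rows out via the non-zero-GD average,
        # but punctuation-attached and sentence-initial words are excluded
        resp = analysis[~analysis["has_punct"] & ~analysis["is_sentence_initial"]]
        items = average_item_gd(resp)
        lin = cv_linearity(
            items,
            k=config.k,
            seed=config.perm_seed,
            n_perm=config.n_perm,
            tensor_dim=config.tensor_dim,
            smooth_dim=config.smooth_dim,
        )
        bundle["linearity"] = lin
        _write_json(lin.to_dict(), out / "linearity.json")
        terms = linearity_model_terms(config.tensor_dim, config.smooth_dim)
        curves = []
        for label in ("linear", "nonlinear"):
            fit = fit_gam(items, "mean_gd_ms", terms[label])
            curves.append(predict_slowdown_curve(fit, label=label))
        curves_df = pd.concat(curves, ignore_index=True)
        curves_df.to_csv(out / "curves.tsv", sep="\t", index=False)
        bundle["curves"] = curves_df
        record("linearity", [out / "linearity.json", out / "curves.tsv"],
               {"items": len(items)})
    except Exception as e:
        raise RuntimeError(f"stage 'linearity' failed: {e}") from e

    _write_json(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
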