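"""Synthetic corpus generator: lexicon laws, ground-truth surprisal, reading model."""

import numpy as np
import pandas as pd
import pytest

import surpread as sp
from surpread.corpus import validate_corpus


class TestLexicon:
    def test_rank_one_has_max_zipf(self):
        lex = sp.make_lexicon(100, seed=1).table
        assert lex.loc[lex["rank"] == 1, "zipf_freq"].iloc[0] == lex["zipf_freq"].max()

    def test_zipf_formula(self):
        """zipf = log10(relative frequency × 1e9); rel 1e-3 → 6.0."""
        lex = sp.make_lexicon(300, seed=2).table
        assert np.allclose(lex["zipf_freq"], np.log10(lex["rel_freq"] * 1e9))
        assert np.interp(1e-3, lex["rel_freq"][::-1], lex["zipf_freq"][::-1]) == (
            pytest.approx(6.0, abs=0.02)
        )

    def test_zipf_law(self):
        lex = sp.make_lexicon(200, zipf_exponent=1.2, seed=3).table
        rel = lex["rel_freq"].to_numpy()
        assert np.allclose(rel, lex["rank"].to_numpy() ** -1.2 / np.sum(
            np.arange(1, 201) ** -1.2))

    def test_length_weakly_increases_with_rank(self):
        lex = sp.make_lexicon(400, seed=4).table
        top = lex[lex["rank"] <= 50]["length_chars"].mean()
        tail = lex[lex["rank"] > 350]["length_chars"].mean()
        assert top < tail

    def test_deterministic(self):
        a = sp.make_lexicon(50, seed=9).table
        b = sp.make_lexicon(50, seed=9).table
        pd.testing.assert_frame_equal(a, b)

    def test_too_small_vocab(self):
        with pytest.raises(ValueError):
            sp.make_lexicon(1)


class TestGeneratorTruth:
    def test_scoring_own_output_reproduces_truth_exactly(self, small_corpus):
        """word_surprisal(score_sequence(generator, words)) equals the
        recorded true surprisal bit-for-bit: the same model scores its
        own sample."""
        gen, truth = small_corpus["generator"], small_corpus["truth"]
        records = small_corpus["records"]
        key = ["text_id", "sentence_id", "word_pos"]
        words = records.drop_duplicates(subset=key).sort_values(key)
        for _, grp in list(words.groupby("text_id"))[:30]:
            toks = grp["word_form"].tolist()
            scores = sp.score_sequence(gen, toks, bos_context=True)
            per_word = sp.word_surprisal(scores, list(range(len(toks))))
            expected = truth.set_index(key).loc[
                list(grp[key].itertuples(index=False, name=None)), "surprisal"
            ].to_numpy()
            assert np.array_equal(per_word["surprisal"].to_numpy(), expected)

    def test_mean_surprisal_matches_entropy_rate(self):
        """Monte-Carlo mean surprisal within 3 SE of the analytic entropy
        rate of the frozen Markov generator."""
        lex = sp.make_lexicon(120, seed=5)
        gen = sp.GeneratorLM(lex, seed=6)
        text = sp.sample_text(
            lex, gen, sp.TextStructure(kind="book", book_words=6000), seed=7
        )
        surps = text["true_surprisal"].to_numpy()
        se = surps.std(ddof=1) / np.sqrt(len(surps))
        assert abs(surps.mean() - gen.entropy_rate()) < 3 * se

    def test_distributions_normalize(self):
        lex = sp.make_lexicon(40, seed=8)
        gen = sp.GeneratorLM(lex, seed=9)
        assert np.allclose(gen.probs.sum(axis=1), 1.0, atol=1e-12)


class TestSampleText:
    def test_sentence_structure_bounds(self):
        lex = sp.make_lexicon(80, seed=1)
        gen = sp.GeneratorLM(lex, seed=2)
        text = sp.sample_text(
            lex, gen,
            sp.TextStructure(kind="sentences", n_sentences=200, sentence_len=(5, 30)),
            seed=3,
        )
        lens = text.groupby("text_id").size()
        assert len(lens) == 200
        assert lens.between(5, 30).all()

    def test_book_structure_forces_window_shifts(self):
        """A book-length stream exceeds 4×W tokens for a small-window model,
        so sliding-window scoring must shift at least twice."""
        lex = sp.make_lexicon(60, seed=1)
        gen = sp.GeneratorLM(lex, seed=2, max_context=64)
        W = gen.max_context
        text = sp.sample_text(lex, gen, sp.TextStructure(kind="book", book_words=4 * W + 50),
                              seed=3)
        assert len(text) > 4 * W
        scores = sp.score_sequence(gen, text["word_form"].tolist(), window=W,
                                   bos_context=True)
        assert (np.diff(scores.context_len_used) < 0).sum() >= 2
        assert scores.context_len_used[W:].min() >= W // 2

    def test_paragraph_structure(self):
        lex = sp.make_lexicon(80, seed=1)
        gen = sp.GeneratorLM(lex, seed=2)
        text = sp.sample_text(lex, gen, sp.TextStructure(kind="paragraphs"), seed=4)
        lens = text.groupby("text_id").size()
        assert len(lens) == 12
        assert lens.between(161, 213).all()


class TestSimulateReading:
    def test_noiseless_coefficient_recovery(self):
        cfg = sp.SyntheticConfig(
            structure=sp.TextStructure(kind="sentences", n_sentences=60),
            noise_sd_ms=0.0, participant_sd=0.0, seed=21,
        )
        records, truth, _, _ = sp.make_corpus(cfg)
        analysis = sp.attach_spillover(records, truth)
        table, _ = sp.apply_exclusions(analysis)
        cols = ("surprisal", "prev_surprisal", "length_chars", "zipf_freq", "word_pos")
        X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(float) for c in cols])
        fit = sp.fit_gaussian_linear(X, table["gd_ms"].to_numpy(float))
        expected = [cfg.intercept_ms, cfg.beta_surprisal, cfg.beta_prev_surprisal,
                    cfg.beta_length, cfg.beta_zipf, cfg.beta_pos]
        assert np.allclose(fit.coef, expected, atol=1e-9)

    def test_skip_limit_no_skips(self):
        cfg = sp.SyntheticConfig(
            structure=sp.TextStructure(kind="sentences", n_sentences=20),
            skip_intercept=-50.0, seed=22,
        )
        records, *_ = sp.make_corpus(cfg)
        assert not records["skipped"].any()

    def test_measure_nesting_and_validity(self, small_corpus):
        records = small_corpus["records"]
        validate_corpus(records)
        fixated = records[~records["skipped"]]
        assert (fixated["ffd_ms"] <= fixated["gd_ms"] + 1e-9).all()
        assert (fixated["gd_ms"] <= fixated["trt_ms"] + 1e-9).all()

    def test_byte_identical_reproduction(self):
        cfg = sp.SyntheticConfig(
            structure=sp.TextStructure(kind="sentences", n_sentences=25),
            participants=2, seed=33,
        )
        r1, t1, _, _ = sp.make_corpus(cfg)
        r2, t2, _, _ = sp.make_corpus(cfg)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1, t2)
        assert r1.to_csv() == r2.to_csv()

    def test_effect_estimate_coverage(self):
        """OLS estimates of the surprisal effect cover the truth at roughly
        the nominal 95% rate (reduced replicate count)."""
        from scipy import stats as st

        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            cfg = sp.SyntheticConfig(
                structure=sp.TextStructure(kind="sentences", n_sentences=60),
                participants=2, participant_sd=0.0, seed=500 + rep,
            )
            records, truth, _, _ = sp.make_corpus(cfg)
            table, _ = sp.apply_exclusions(sp.attach_spillover(records, truth))
            cols = ("surprisal", "prev_surprisal", "length_chars", "zipf_freq", "word_pos")
            X = np.column_stack(
                [np.ones(len(table))] + [table[c].to_numpy(float) for c in cols]
            )
            y = table["gd_ms"].to_numpy(float)
            fit = sp.fit_gaussian_linear(X, y)
            # classical OLS CI for the surprisal coefficient
            n, p = X.shape
            resid = y - X @ fit.coef
            s2 = resid @ resid / (n - p)
            cov = s2 * np.linalg.inv(X.T @ X)
            half = st.t.ppf(0.975, n - p) * np.sqrt(cov[1, 1])
            hits += abs(fit.coef[1] - cfg.beta_surprisal) <= half
        lo, hi = st.binom.interval(0.999, n_rep, 0.95)
        assert lo <= hits <= hi
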