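"""Corpus reading, validation, exclusion filtering, spillover and item averaging."""

import numpy as np
import pandas as pd
import pytest

import surpread as sp
from surpread.corpus import CorpusError, has_attached_punctuation, validate_corpus


def write_tsv(path, df):
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def corpus_file(tmp_path, toy_word_table):
    return write_tsv(tmp_path / "corpus.tsv", toy_word_table)


class TestReadCorpus:
    def test_roundtrip_identity(self, corpus_file, toy_word_table):
        table = sp.read_corpus(corpus_file)
        assert len(table) == len(toy_word_table)
        assert list(table["word_form"]) == list(toy_word_table["word_form"])
        assert np.allclose(
            table["gd_ms"], toy_word_table["gd_ms"], equal_nan=True
        )

    def test_column_mapping(self, tmp_path, toy_word_table):
        renamed = toy_word_table.rename(columns={"gd_ms": "GAZE_DUR"})
        path = write_tsv(tmp_path / "c.tsv", renamed)
        table = sp.read_corpus(path, format_spec={"gd_ms": "GAZE_DUR"})
        assert np.allclose(table["gd_ms"], toy_word_table["gd_ms"], equal_nan=True)

    def test_missing_required_column(self, tmp_path, toy_word_table):
        path = write_tsv(tmp_path / "c.tsv", toy_word_table.drop(columns=["gd_ms"]))
        with pytest.raises(CorpusError, match="column 'gd_ms' not found"):
            sp.read_corpus(path)

    def test_nesting_violation_rejected(self, tmp_path, toy_word_table):
        bad = toy_word_table.copy()
        bad.loc[1, "gd_ms"] = 200.0
        bad.loc[1, "trt_ms"] = 150.0
        path = write_tsv(tmp_path / "c.tsv", bad)
        with pytest.raises(CorpusError, match="nesting"):
            sp.read_corpus(path)

    def test_non_numeric_measure_cell(self, tmp_path, toy_word_table):
        bad = toy_word_table.astype({"trt_ms": object})
        bad.loc[2, "trt_ms"] = "oops"
        path = write_tsv(tmp_path / "c.tsv", bad)
        with pytest.raises(CorpusError, match="row index 2"):
            sp.read_corpus(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("participant_id\ttext_id\n")
        with pytest.raises((CorpusError, pd.errors.EmptyDataError)):
            sp.read_corpus(path)

    def test_flags_derived_when_absent(self, tmp_path, toy_word_table):
        slim = toy_word_table.drop(
            columns=["has_punct", "is_sentence_initial", "skipped", "length_chars"]
        )
        table = sp.read_corpus(write_tsv(tmp_path / "c.tsv", slim))
        assert bool(table.loc[3, "has_punct"])  # "daar,"
        assert not bool(table.loc[1, "has_punct"])
        assert bool(table.loc[0, "is_sentence_initial"])
        assert bool(table.loc[5, "skipped"])
        # derived length strips the attached punctuation
        assert table.loc[3, "length_chars"] == 4

    @pytest.mark.parametrize(
        "form,expected",
        [("huis", False), ("huis,", True), ("'s", True), ("e-mail", True),
         ("woord.", True), ("aan", False)],
    )
    def test_punctuation_class(self, form, expected):
        assert has_attached_punctuation(form) is expected


class TestExclusions:
    def test_toy_counts(self, toy_word_table):
        filtered, report = sp.apply_exclusions(toy_word_table)
        assert report.removed_punct == 2
        assert report.removed_sentence_initial == 1
        assert report.removed_skipped == 1
        assert report.n_retained == len(filtered) == 6

    def test_counts_sum_to_input(self, toy_word_table, analysis_table):
        for table in (toy_word_table, analysis_table):
            _, r = sp.apply_exclusions(table)
            assert (
                r.removed_punct + r.removed_sentence_initial + r.removed_oov
                + r.removed_skipped + r.n_retained == r.n_input == len(table)
            )

    def test_idempotent(self, toy_word_table):
        once, _ = sp.apply_exclusions(toy_word_table)
        twice, r2 = sp.apply_exclusions(once)
        pd.testing.assert_frame_equal(once, twice)
        assert r2.n_retained == len(once)

    def test_full_vocab_removes_nothing(self, toy_word_table):
        vocab = set(toy_word_table["word_form"])
        _, report = sp.apply_exclusions(toy_word_table, vocab=vocab)
        assert report.removed_oov == 0

    def test_oov_rule(self, toy_word_table):
        vocab = set(toy_word_table["word_form"]) - {"staat"}
        filtered, report = sp.apply_exclusions(toy_word_table, vocab=vocab)
        assert report.removed_oov == 1
        assert "staat" not in set(filtered["word_form"])


class TestSpillover:
    def test_prev_taken_from_pre_filter_neighbour(self, small_corpus):
        """The excluded sentence-initial word still supplies prev_* to word 2."""
        analysis = sp.attach_spillover(small_corpus["records"], small_corpus["truth"])
        truth = small_corpus["truth"].set_index(["text_id", "sentence_id", "word_pos"])
        second = analysis[(analysis["word_pos"] == 2) & (analysis["sentence_id"] == 0)]
        for _, row in second.head(20).iterrows():
            prev = truth.loc[(row["text_id"], 0, 1), "surprisal"]
            assert row["prev_surprisal"] == pytest.approx(float(prev))

    def test_prev_surprisal_is_previous_words_surprisal(self, small_corpus):
        analysis = sp.attach_spillover(small_corpus["records"], small_corpus["truth"])
        one_part = analysis[analysis["participant_id"] == "p000"].sort_values(
            ["text_id", "sentence_id", "word_pos"]
        )
        for _, grp in list(one_part.groupby("text_id"))[:10]:
            s = grp["surprisal"].to_numpy()
            ps = grp["prev_surprisal"].to_numpy()
            assert np.allclose(ps[1:], s[:-1])

    def test_text_initial_words_absent(self, small_corpus):
        analysis = sp.attach_spillover(small_corpus["records"], small_corpus["truth"])
        # in the isolated-sentence structure, each text's first word has pos 1
        assert (analysis["word_pos"] > 1).all()

    def test_measures_unchanged(self, small_corpus):
        records, truth = small_corpus["records"], small_corpus["truth"]
        analysis = sp.attach_spillover(records, truth)
        key = ["participant_id", "text_id", "sentence_id", "word_pos"]
        merged = analysis.merge(records, on=key, suffixes=("", "_orig"))
        for m in ("ffd_ms", "gd_ms", "trt_ms"):
            assert np.allclose(merged[m], merged[f"{m}_orig"], equal_nan=True)

    def test_missing_surprisal_entry_errors(self, small_corpus):
        truth = small_corpus["truth"].iloc[1:]
        with pytest.raises(CorpusError, match="no surprisal entry"):
            sp.attach_spillover(small_corpus["records"], truth)


class TestItemAverage:
    def _word(self, pid, gd, skipped=False):
        return dict(
            participant_id=pid, text_id=0, sentence_id=0, word_pos=2,
            word_form="huis", length_chars=4, zipf_freq=5.0, has_punct=False,
            is_sentence_initial=False,
            ffd_ms=np.nan if skipped else gd, gd_ms=np.nan if skipped else gd,
            trt_ms=np.nan if skipped else gd, skipped=skipped,
        )

    def test_mean_of_nonzero_gds(self):
        table = pd.DataFrame(
            [self._word("a", 200.0), self._word("b", 0.0, skipped=True),
             self._word("c", 300.0)]
        )
        items = sp.average_item_gd(table)
        assert len(items) == 1
        assert items.loc[0, "mean_gd_ms"] == pytest.approx(250.0)
        assert items.loc[0, "n_contributing"] == 2

    def test_all_skipped_word_absent(self):
        table = pd.DataFrame([self._word("a", 0.0, skipped=True)])
        assert len(sp.average_item_gd(table)) == 0

    def test_single_participant_identity(self):
        table = pd.DataFrame([self._word("a", 180.0)])
        items = sp.average_item_gd(table)
        assert items.loc[0, "mean_gd_ms"] == pytest.approx(180.0)
        assert items.loc[0, "n_contributing"] == 1


def test_validate_rejects_skip_flag_mismatch(toy_word_table):
    bad = toy_word_table.copy()
    bad.loc[1, "skipped"] = True  # but gd is positive
    with pytest.raises(CorpusError, match="skip flag"):
        validate_corpus(bad)


def test_validate_rejects_zipf_out_of_range(toy_word_table):
    bad = toy_word_table.copy()
    bad.loc[1, "zipf_freq"] = 9.5
    with pytest.raises(CorpusError, match="zipf"):
        validate_corpus(bad)
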