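import numpy as np
import pandas as pd
import pytest

import surpread as sp


def make_item_table(seed, participants=6, n_sentences=145, link="linear",
                    gamma=1.0, beta_surprisal=3.0, noise_sd=30.0, n_items=None):
    """Item-level (participant-averaged GD) table from a fresh synthetic corpus."""
    cfg = sp.SyntheticConfig(
        structure=sp.TextStructure(kind="sentences", n_sentences=n_sentences),
        participants=participants,
        seed=seed,
        link=link,
        gamma=gamma,
        beta_surprisal=beta_surprisal,
        noise_sd_ms=noise_sd,
    )
    records, truth, _, _ = sp.make_corpus(cfg)
    analysis = sp.attach_spillover(records, truth)
    resp = analysis[~analysis["has_punct"] & ~analysis["is_sentence_initial"]]
    items = sp.average_item_gd(resp)
    return items.iloc[:n_items] if n_items else items


@pytest.fixture(scope="session")
def small_corpus():
    """A modest multi-participant sentence corpus with exact true surprisal."""
    cfg = sp.SyntheticConfig(
        structure=sp.TextStructure(kind="sentences", n_sentences=80),
        participants=3,
        seed=42,
    )
    records, truth, lexicon, generator = sp.make_corpus(cfg)
    return {"records": records, "truth": truth, "lexicon": lexicon,
            "generator": generator, "config": cfg}


@pytest.fixture(scope="session")
def analysis_table(small_corpus):
    analysis = sp.attach_spillover(small_corpus["records"], small_corpus["truth"])
    filtered, report = sp.apply_exclusions(analysis)
    return filtered


@pytest.fixture(scope="session")
def toy_word_table():
    """Hand-built 10-row word table: 2 punctuation-attached, 1 sentence-initial
    (not punctuated), 1 skip, 6 clean rows."""
    rows = []
    # word 0: sentence-initial; words 3 and 7: punctuation-attached;
    # word 5: skipped (no first-pass fixation); the remaining 6 are clean
    gd = [200, 210, 190, 250, 230, 0, 260, 240, 220, 205]
    forms = ["Het", "huis", "staat", "daar,", "en", "het", "is", "groot,", "heel", "mooi"]
    for i in range(10):
        rows.append(
            dict(
                participant_id="p0",
                text_id=0,
                sentence_id=0,
                word_pos=i + 1,
                word_form=forms[i],
                length_chars=len(forms[i].rstrip(",")),
                zipf_freq=4.5,
                has_punct="," in forms[i],
                is_sentence_initial=i == 0,
                ffd_ms=np.nan if gd[i] == 0 else gd[i] * 0.8,
                gd_ms=np.nan if gd[i] == 0 else float(gd[i]),
                trt_ms=np.nan if gd[i] == 0 else gd[i] * 1.2,
                skipped=gd[i] == 0,
            )
        )
    return pd.DataFrame(rows)
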