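"""Shared fixtures: packaged sample note/lexicon and a small synthetic
pipeline corpus (kept deliberately tiny so the suite stays fast)."""

from __future__ import annotations

from dataclasses import replace

import pytest

import focusrank
from focusrank.extraction import make_note
from focusrank.lexicon import load_lexicon
from focusrank.synthetic_data import PROFILES, GeneratorProfile


@pytest.fixture(scope="session")
def sample_lexicon():
    return load_lexicon(focusrank.sample_lexicon_path())


@pytest.fixture(scope="session")
def sample_note():
    text = focusrank.sample_note_path().read_text(encoding="utf-8")
    return make_note("sample", text)


@pytest.fixture(scope="session")
def small_profile() -> GeneratorProfile:
    """A scaled-down generator profile for fast pipeline tests."""
    return replace(
        PROFILES["table1"],
        name="small",
        n_notes=12,
        words_mean=120.0,
        words_sd=20.0,
        words_min=60,
        candidates_mean=30.0,
        candidates_sd=5.0,
        gold_mean=4.0,
        gold_sd=2.0,
        n_lexicon_terms=300,
        n_background_docs=30,
        background_words_mean=80.0,
        background_words_sd=10.0,
    )


@pytest.fixture(scope="session")
def small_corpus(small_profile):
    """(lexicon, notes, gold, truth) for the small profile, seed 7."""
    from focusrank.synthetic_data import generate_corpus, generate_lexicon

    lexicon = generate_lexicon(small_profile, seed=7)
    notes, gold, truth = generate_corpus(small_profile, lexicon, seed=7)
    return lexicon, notes, gold, truth
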