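"""Feature operations and fold-safe assembly."""

from __future__ import annotations

import math

import numpy as np
import pytest

from focusrank.extraction import CandidateTerm, extract_candidates, make_note
from focusrank.features import (
    BackgroundCorpus,
    EmbeddingTable,
    FeatureConfig,
    FeatureExtractor,
    FeatureResources,
    chv_features,
    default_pos_tagger,
    embedding_feature,
    frequency_features,
    length_features,
    lexical_feature,
    load_embeddings,
    pos_feature,
    position_feature,
    semantic_type_feature,
    write_embeddings,
)
from focusrank.lexicon import DEFAULT_SEMANTIC_TYPES, Lexicon, LexiconEntry


def _cand(term="pain", note_id="n1", first=0, tf=1, stype="other",
          in_chv=False, familiarity=None, label=None):
    occ = [(first + 3 * i, first + 3 * i + len(term.split())) for i in range(tf)]
    return CandidateTerm(
        note_id=note_id, canonical_term=term, occurrences=occ,
        semantic_type=stype, in_chv=in_chv, familiarity=familiarity, label=label,
    )


class TestFrequency:
    def _background(self, df: int, N: int) -> BackgroundCorpus:
        docs = [["pain"] if i < df else ["filler"] for i in range(N)]
        return BackgroundCorpus(docs)

    def test_idf_closed_form(self):
        bg = self._background(df=24, N=99)
        _, idf, _ = frequency_features(_cand("pain"), make_note("n1", "pain"), bg)
        assert idf == pytest.approx(math.log(100 / 25), abs=1e-12)

    def test_unseen_term_smoothed(self):
        bg = self._background(df=0, N=99)
        _, idf, _ = frequency_features(_cand("pain"), make_note("n1", "pain"), bg)
        assert idf == pytest.approx(math.log(100), abs=1e-12)

    def test_tfidf_product_and_monotonicity(self):
        note = make_note("n1", "pain pain pain")
        idfs = []
        for df in (0, 10, 50, 99):
            bg = self._background(df=df, N=99)
            tf, idf, tfidf = frequency_features(_cand("pain", tf=3), note, bg)
            assert tf == 3
            assert tfidf == pytest.approx(tf * idf, abs=1e-12)
            idfs.append(idf)
        assert idfs == sorted(idfs, reverse=True)

    def test_multiword_df_counts_contiguous_occurrence(self):
        docs = [["crohn", "diseas"], ["diseas", "crohn"], ["fill"]]
        bg = BackgroundCorpus(docs)
        assert bg.document_frequency(("crohn", "diseas")) == 1
        assert bg.document_frequency(("diseas",)) == 2


@pytest.mark.parametrize(
    ("term", "tl", "maxwl", "combined"),
    [
        ("diabetes mellitus", 2, 8, 16.0),
        ("pain", 1, 4, 4.0),
        ("autologous stem cell transplant", 4, 10, 40.0),
    ],
)
def test_length_features(term, tl, maxwl, combined):
    assert length_features(_cand(term)) == (tl, maxwl, combined)


class TestPosition:
    def test_endpoints(self):
        note = make_note("n1", " ".join(["w"] * 200))
        assert position_feature(_cand(first=0), note) == 0.0
        assert position_feature(_cand(first=100), note) == 0.5
        assert position_feature(_cand(first=199), note) == pytest.approx(0.995)

    def test_empty_note_rejected(self):
        with pytest.raises(ValueError):
            position_feature(_cand(), make_note("n1", ""))


class TestLexical:
    def test_threshold(self):
        vocab = {"metformin": 5, "rareword": 2}
        assert lexical_feature(_cand("metformin"), vocab) == "metformin"
        assert lexical_feature(_cand("rareword"), vocab) == "RARE"
        assert lexical_feature(_cand("unseen"), vocab) == "RARE"


class TestPOS:
    def test_head_word_is_final_token(self):
        assert pos_feature(_cand("thyroid ultrasound"), None) == default_pos_tagger("ultrasound")
        assert pos_feature(_cand("dialysis"), None) == default_pos_tagger("dialysis")

    def test_tagger_failure_maps_to_unk(self):
        def broken(word):
            raise RuntimeError("no tagger")

        assert pos_feature(_cand("pain"), None, tagger=broken) == "UNK"


class TestEmbedding:
    def _table(self):
        # anchor rows pin per-dimension bounds to [0, 1], making the
        # min-max rescaling the identity on this table
        return EmbeddingTable({
            "lo": np.array([0.0, 0.0]),
            "hi": np.array([1.0, 1.0]),
            "alpha": np.array([0.2, 0.4]),
            "beta": np.array([0.6, 0.8]),
        })

    def test_mean_of_member_vectors(self):
        vec = embedding_feature(_cand("alpha beta"), self._table())
        assert vec == pytest.approx([0.4, 0.6])

    def test_vocabulary_minimum_maps_to_zero(self):
        assert embedding_feature(_cand("lo"), self._table()) == pytest.approx([0.0, 0.0])

    def test_all_words_missing_gives_neutral(self):
        vec = embedding_feature(_cand("zz qq"), self._table())
        assert vec == pytest.approx([0.5, 0.5])

    def test_missing_words_skipped(self):
        vec = embedding_feature(_cand("alpha zz"), self._table())
        assert vec == pytest.approx([0.2, 0.4])

    def test_word2vec_text_roundtrip(self, tmp_path):
        table = self._table()
        path = tmp_path / "emb.txt"
        write_embeddings(table, path)
        again = load_embeddings(path)
        assert again.d == 2
        assert again.vectors["alpha"] == pytest.approx([0.2, 0.4])


class TestSemanticType:
    def test_one_hot(self):
        vec = semantic_type_feature(_cand(stype="Organic chemical"))
        assert vec.sum() == 1.0
        assert vec[list(DEFAULT_SEMANTIC_TYPES).index("Organic chemical")] == 1.0

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            semantic_type_feature(_cand(stype="Novelty"))


class TestCHV:
    @pytest.mark.parametrize(
        ("in_chv", "fam", "expected"),
        [
            (True, 0.95, [1, 0, 0, 0, 0, 1, 1]),
            (True, 0.2, [1, 0, 1, 0, 0, 0, 1]),   # half-open bins
            (True, None, [1, 0, 0, 0, 0, 0, 0]),
            (False, None, [0, 0, 0, 0, 0, 0, 0]),
            (True, 1.0, [1, 0, 0, 0, 0, 1, 1]),   # top bin closed at 1
        ],
    )
    def test_bins(self, in_chv, fam, expected):
        vec = chv_features(_cand(in_chv=in_chv, familiarity=fam))
        assert list(vec) == expected
        assert vec[1:6].sum() <= 1


class TestAssembly:
    @pytest.fixture()
    def tiny(self):
        lexicon = Lexicon.from_entries([
            LexiconEntry("crohn disease", "Disease or syndrome", True, 0.35),
            LexiconEntry("metformin", "Organic chemical", True, 0.4),
            LexiconEntry("pain", "other", True, 0.95),
        ])
        notes = {
            "n1": make_note("n1", "crohn disease then pain then metformin"),
            "n2": make_note("n2", "pain early crohn disease late metformin"),
        }
        cands = []
        for note in notes.values():
            got, _ = [], None
            extracted = extract_candidates(note, lexicon)
            for i, c in enumerate(extracted):
                c.label = 1 if c.canonical_term == "crohn disease" else 0
            cands.extend(extracted)
        bg = BackgroundCorpus([n.stems for n in notes.values()])
        table = EmbeddingTable({
            "crohn": np.array([0.0, 1.0]), "disease": np.array([1.0, 0.0]),
            "metformin": np.array([0.5, 0.5]), "pain": np.array([0.2, 0.8]),
        })
        resources = FeatureResources(background=bg, embeddings=table)
        return lexicon, notes, cands, resources

    def test_baseline_column_blocks(self, tiny):
        _, notes, cands, resources = tiny
        cfg = FeatureConfig.baseline_only()
        cfg.lexical_min_count = 1
        fx = FeatureExtractor(cfg, resources).fit(cands, notes)
        fm = fx.transform(cands, notes)
        numeric = ["tf", "idf", "tfidf", "TL", "maxWL", "TLxWL", "position"]
        assert fm.names[:7] == numeric
        assert sum(n.startswith("lex=") for n in fm.names) == 4  # 3 terms + RARE
        assert sum(n.startswith("pos=") for n in fm.names) == 7
        assert not any(n.startswith(("emb_", "sty=", "chv", "topic_")) for n in fm.names)

    def test_full_config_adds_blocks(self, tiny):
        _, notes, cands, resources = tiny
        cfg = FeatureConfig(embedding=True, semantic_type=True, chv=True, topic=False)
        fx = FeatureExtractor(cfg, resources).fit(cands, notes)
        fm = fx.transform(cands, notes)
        assert sum(n.startswith("emb_") for n in fm.names) == 2
        assert sum(n.startswith("sty=") for n in fm.names) == len(DEFAULT_SEMANTIC_TYPES)
        assert sum(n.startswith(("chv", "fam_")) for n in fm.names) == 7
        X = np.asarray(fm.X.todense())
        emb = X[:, [i for i, n in enumerate(fm.names) if n.startswith("emb_")]]
        assert ((emb >= 0) & (emb <= 1)).all()
        sty = X[:, [i for i, n in enumerate(fm.names) if n.startswith("sty=")]]
        assert np.allclose(sty.sum(axis=1), 1.0)
        fam = X[:, [i for i, n in enumerate(fm.names) if n.startswith("fam_bin")]]
        assert (fam.sum(axis=1) <= 1).all()

    def test_note_dependent_columns_only(self, tiny):
        """The same term in two notes differs only in position/frequency."""
        _, notes, cands, resources = tiny
        cfg = FeatureConfig(embedding=True, semantic_type=True, chv=True)
        fx = FeatureExtractor(cfg, resources).fit(cands, notes)
        fm = fx.transform(cands, notes)
        rows = {r: i for i, r in enumerate(fm.rows)}
        X = np.asarray(fm.X.todense())
        a = X[rows[("n1", "metformin")]]
        b = X[rows[("n2", "metformin")]]
        note_dependent = {"tf", "tfidf", "position"}
        for name, va, vb in zip(fm.names, a, b):
            if name not in note_dependent:
                assert va == vb, name

    def test_lexical_vocabulary_depends_only_on_training_fold(self, tiny):
        _, notes, cands, resources = tiny
        cfg = FeatureConfig.baseline_only()
        cfg.lexical_min_count = 2  # one fold alone falls below the threshold
        train_a = [c for c in cands if c.note_id == "n1"]
        train_b = [c for c in cands if c.note_id == "n2"]
        fp_a1 = FeatureExtractor(cfg, resources).fit(train_a, notes).fingerprint()
        fp_a2 = FeatureExtractor(cfg, resources).fit(train_a, notes).fingerprint()
        fp_ab = FeatureExtractor(cfg, resources).fit(train_a + train_b, notes).fingerprint()
        assert fp_a1 == fp_a2
        assert fp_a1 != fp_ab

    def test_missing_resource_rejected(self, tiny):
        _, notes, cands, _ = tiny
        cfg = FeatureConfig(embedding=True)
        fx = FeatureExtractor(cfg, FeatureResources(background=None, embeddings=None))
        with pytest.raises((ValueError, RuntimeError)):
            fx.fit(cands, notes)
            fx.transform(cands, notes)
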