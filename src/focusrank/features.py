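"""Per-candidate learning features and feature-matrix assembly.

Nine baseline features standard in keyphrase extraction — term frequency,
IDF, TF-IDF, term length in words, longest-word length, their combination,
normalised first-occurrence position, the (thresholded) lexical identity
and the head-word part of speech — plus domain blocks: averaged word
embeddings min-max rescaled to [0, 1], a one-hot semantic type, seven
binary consumer-vocabulary features, and topic-coherence features from the
topics module.

Categorical blocks (lexical identity, POS) are one-hot encoded with
category sets frozen on the training folds; the :class:`FeatureExtractor`
carries that fitted state so test notes can never leak categories into
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse

from .extraction import CandidateTerm, Note
from .lexicon import DEFAULT_SEMANTIC_TYPES, stem_word

__all__ = [
    "BackgroundCorpus",
    "EmbeddingTable",
    "FeatureConfig",
    "FeatureMatrix",
    "FeatureResources",
    "FeatureExtractor",
    "frequency_features",
    "length_features",
    "position_feature",
    "lexical_feature",
    "pos_feature",
    "embedding_feature",
    "semantic_type_feature",
    "chv_features",
    "assemble",
    "default_pos_tagger",
    "load_embeddings",
    "write_embeddings",
]

RARE = "RARE"
POS_TAGS = ("NN", "JJ", "VBG", "VBD", "RB", "CD", "UNK")


# ---------------------------------------------------------------------------
# resources


class BackgroundCorpus:
    """A reference note collection used for IDF and topic modelling.

    ``documents`` are stemmed token sequences. Document frequency of a
    (possibly multi-word) term is the number of documents containing its
    stemmed token sequence contiguously; n-grams up to ``max_n`` words are
    pre-indexed.
    """

    def __init__(self, documents: Sequence[Sequence[str]], max_n: int = 4):
        if not documents:
            raise ValueError("background corpus must contain >= 1 document")
        self.documents = [list(d) for d in documents]
        self.N = len(self.documents)
        self.max_n = max_n
        df: dict[tuple[str, ...], int] = {}
        for doc in self.documents:
            grams: set[tuple[str, ...]] = set()
            for n in range(1, max_n + 1):
                for i in range(len(doc) - n + 1):
                    grams.add(tuple(doc[i : i + n]))
            for g in grams:
                df[g] = df.get(g, 0) + 1
        self._df = df

    def document_frequency(self, term_key: Sequence[str]) -> int:
        return self._df.get(tuple(term_key), 0)


class EmbeddingTable:
    """Word vectors with per-dimension min-max bounds over the vocabulary."""

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise ValueError("empty embedding table")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
        self.d = dims.pop()
        self.vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        mat = np.stack(list(self.vectors.values()))
        self.mins = mat.min(axis=0)
        self.maxs = mat.max(axis=0)

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def get(self, word: str) -> Optional[np.ndarray]:
        v = self.vectors.get(word)
        if v is None:
            v = self.vectors.get(stem_word(word)) if word else None
        return v


def load_embeddings(path: str | Path) -> EmbeddingTable:
    """Read a word2vec-text-format table (header ``V d``, then rows)."""
    vectors: dict[str, np.ndarray] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        n, d = int(header[0]), int(header[1])
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise ValueError(f"{path}:{lineno}: expected {d + 1} fields")
            vectors[parts[0]] = np.array(parts[1:], dtype=float)
    if len(vectors) != n:
        raise ValueError(f"{path}: header declares {n} rows, found {len(vectors)}")
    return EmbeddingTable(vectors)


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.d}\n")
        for w, v in table.vectors.items():
            fh.write(w + " " + " ".join(f"{x:.6g}" for x in v) + "\n")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class FeatureConfig:
    """Which feature blocks to compute and their knobs."""

    baseline: bool = True
    embedding: bool = False
    semantic_type: bool = False
    chv: bool = False
    topic: bool = False
    lexical_min_count: int = 3
    combined_form: str = "product"          # TL/maxWL combination
    topic_combiner: str = "product"         # or "geomean"

    def __post_init__(self) -> None:
        if self.lexical_min_count < 1:
            raise ValueError("lexical_min_count must be >= 1")

    @classmethod
    def baseline_only(cls) -> "FeatureConfig":
        return cls()

    @classmethod
    def full(cls) -> "FeatureConfig":
        return cls(embedding=True, semantic_type=True, chv=True, topic=True)


@dataclass
class FeatureResources:
    """Shared inputs for feature computation (not fold-dependent)."""

    background: Optional[BackgroundCorpus] = None
    embeddings: Optional[EmbeddingTable] = None
    topic_models: Sequence = ()             # focusrank.topics.TopicModel
    pos_tagger: Optional[Callable[[str], str]] = None
    semantic_types: Sequence[str] = DEFAULT_SEMANTIC_TYPES
    theta_cache: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# individual feature operations


def frequency_features(
    candidate: CandidateTerm,
    note: Note,
    background: BackgroundCorpus,
) -> tuple[int, float, float]:
    """(tf, idf, tf-idf) with smoothed idf = ln((N+1)/(df+1))."""
    tf = candidate.tf
    key = tuple(stem_word(w) for w in candidate.canonical_term.split())
    df = background.document_frequency(key)
    idf = float(np.log((background.N + 1) / (df + 1)))
    return tf, idf, tf * idf


def length_features(
    candidate: CandidateTerm, combined_form: str = "product"
) -> tuple[int, int, float]:
    """(TL, maxWL, combined); longer terms and words are less familiar."""
    words = candidate.canonical_term.split()
    if not words:
        raise ValueError("empty candidate term")
    tl = len(words)
    maxwl = max(len(w) for w in words)
    if combined_form == "product":
        combined = float(tl * maxwl)
    else:
        raise ValueError(f"unknown combined_form {combined_form!r}")
    return tl, maxwl, combined


def position_feature(candidate: CandidateTerm, note: Note) -> float:
    """Words preceding the first occurrence over the note's word count."""
    if note.word_count == 0:
        raise ValueError("position_feature: empty note")
    return candidate.first_token_index / note.word_count


def lexical_feature(
    candidate: CandidateTerm,
    training_vocabulary: Mapping[str, int],
    min_count: int = 3,
) -> str:
    """The stemmed term string if frequent enough in training, else RARE.

    Thresholding suppresses misspellings and one-off strings; unseen terms
    at test time fall into the RARE bucket by construction.
    """
    key = " ".join(stem_word(w) for w in candidate.canonical_term.split())
    if training_vocabulary.get(key, 0) >= min_count:
        return key
    return RARE


def default_pos_tagger(word: str) -> str:
    """Suffix-heuristic POS tagging delegate over a small closed tagset."""
    if not word:
        return "UNK"
    if word[0].isdigit():
        return "CD"
    w = word.lower()
    if w.endswith("ing") and len(w) > 4:
        return "VBG"
    if w.endswith("ed") and len(w) > 3:
        return "VBD"
    if w.endswith("ly") and len(w) > 3:
        return "RB"
    if w.endswith(("ous", "ic", "al", "ary", "ive")) and len(w) > 4:
        return "JJ"
    return "NN"


def pos_feature(
    candidate: CandidateTerm,
    note: Note,
    tagger: Optional[Callable[[str], str]] = None,
) -> str:
    """POS tag of the head word (final token) of the term."""
    tagger = tagger or default_pos_tagger
    head = candidate.canonical_term.split()[-1]
    try:
        tag = tagger(head)
    except Exception:
        return "UNK"
    return tag if tag in POS_TAGS else "UNK"


def embedding_feature(
    candidate: CandidateTerm, table: EmbeddingTable
) -> np.ndarray:
    """Mean of member-word vectors, min-max rescaled to [0, 1].

    Words missing from the table are skipped; a term with no in-vocabulary
    word maps to the neutral all-0.5 vector.
    """
    vecs = []
    for w in candidate.canonical_term.lower().split():
        v = table.get(w)
        if v is not None:
            vecs.append(v)
    if not vecs:
        return np.full(table.d, 0.5)
    mean = np.mean(vecs, axis=0)
    span = table.maxs - table.mins
    out = np.where(span > 0, (mean - table.mins) / np.where(span > 0, span, 1.0), 0.5)
    return np.clip(out, 0.0, 1.0)


def semantic_type_feature(
    candidate: CandidateTerm,
    semantic_types: Sequence[str] = DEFAULT_SEMANTIC_TYPES,
) -> np.ndarray:
    """One-hot over the declared closed semantic-type set."""
    if candidate.semantic_type not in semantic_types:
        raise ValueError(f"unknown semantic type {candidate.semantic_type!r}")
    vec = np.zeros(len(semantic_types))
    vec[list(semantic_types).index(candidate.semantic_type)] = 1.0
    return vec


FAM_BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def familiarity_bin(familiarity: float) -> int:
    """0-based bin index for half-open bins [0,.2) .. [.8,1.0]."""
    if not 0.0 <= familiarity <= 1.0:
        raise ValueError("familiarity outside [0, 1]")
    return min(int(familiarity / 0.2), 4)


def chv_features(candidate: CandidateTerm) -> np.ndarray:
    """[in_chv, fam-bin1..5, has_score]: 7 binary consumer-vocabulary flags.

    Bins are half-open fifths of [0, 1] (the last closed at 1); a term
    without a familiarity score sets no bin and has_score = 0.
    """
    vec = np.zeros(7)
    vec[0] = 1.0 if candidate.in_chv else 0.0
    if candidate.familiarity is not None:
        vec[1 + familiarity_bin(candidate.familiarity)] = 1.0
        vec[6] = 1.0
    return vec


# ---------------------------------------------------------------------------
# assembly


@dataclass
class FeatureMatrix:
    """Sparse candidate-by-feature matrix with named columns."""

    X: sparse.csr_matrix
    names: list[str]
    rows: list[tuple[str, str]]  # (note_id, canonical_term)

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.names):
            raise ValueError("column count does not match feature names")
        if self.X.shape[0] != len(self.rows):
            raise ValueError("row count does not match row index")

    def to_tsv(self, path: str | Path) -> None:
        dense = np.asarray(self.X.todense())
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("note_id\tterm\t" + "\t".join(self.names) + "\n")
            for (nid, term), row in zip(self.rows, dense):
                fh.write(nid + "\t" + term + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


class FeatureExtractor:
    """Fold-safe featuriser: fit category sets on training, then transform.

    ``fit`` builds the lexical vocabulary (stemmed-term instance counts
    with the min-count threshold) from training candidates only; the POS
    tagset and semantic-type set are closed and declared up front, and
    embedding bounds come from the table's whole vocabulary, so none of
    them can leak test-fold information.
    """

    def __init__(self, config: FeatureConfig, resources: FeatureResources):
        self.config = config
        self.resources = resources
        self.lexical_categories: Optional[list[str]] = None
        self._vocab_counts: dict[str, int] = {}
        self.topic_bounds: Optional[list[tuple[float, float]]] = None

    def fit(
        self,
        train_candidates: Sequence[CandidateTerm],
        notes: Optional[Mapping[str, Note]] = None,
    ) -> "FeatureExtractor":
        counts: dict[str, int] = {}
        for c in train_candidates:
            key = " ".join(stem_word(w) for w in c.canonical_term.split())
            counts[key] = counts.get(key, 0) + 1
        self._vocab_counts = counts
        kept = sorted(k for k, v in counts.items() if v >= self.config.lexical_min_count)
        self.lexical_categories = kept + [RARE]
        if self.config.topic:
            if notes is None:
                raise ValueError("topic block enabled: fit() needs the training notes")
            # min-max bounds per topic column, fitted on training candidates,
            # so the (0,1) coherence values span a range a linear model can use
            self.topic_bounds = []
            for mi, model in enumerate(self.resources.topic_models):
                vals = [
                    self._raw_topic_value(mi, model, c, notes)
                    for c in train_candidates
                ]
                self.topic_bounds.append((min(vals), max(vals)))
        return self

    def _raw_topic_value(self, mi, model, candidate, notes) -> float:
        from .topics import topic_feature

        cache_key = (mi, candidate.note_id)
        theta = self.resources.theta_cache.get(cache_key)
        if theta is None:
            theta = model.infer(notes[candidate.note_id].stems)
            self.resources.theta_cache[cache_key] = theta
        return topic_feature(
            model, candidate, theta, combiner=self.config.topic_combiner
        )

    def fingerprint(self) -> tuple:
        """Hashable summary of all fitted category sets (leakage checks)."""
        return (
            tuple(self.lexical_categories or ()),
            POS_TAGS,
            tuple(self.resources.semantic_types),
        )

    # -- column schema ------------------------------------------------------

    def feature_names(self) -> list[str]:
        if self.lexical_categories is None:
            raise RuntimeError("FeatureExtractor not fitted")
        names: list[str] = []
        cfg, res = self.config, self.resources
        if cfg.baseline:
            names += ["tf", "idf", "tfidf", "TL", "maxWL", "TLxWL", "position"]
            names += [f"lex={c}" for c in self.lexical_categories]
            names += [f"pos={t}" for t in POS_TAGS]
        if cfg.embedding:
            if res.embeddings is None:
                raise ValueError("embedding block enabled but no table provided")
            names += [f"emb_{i}" for i in range(res.embeddings.d)]
        if cfg.semantic_type:
            names += [f"sty={t}" for t in res.semantic_types]
        if cfg.chv:
            names += ["chv", "fam_bin1", "fam_bin2", "fam_bin3", "fam_bin4",
                      "fam_bin5", "fam_has_score"]
        if cfg.topic:
            if not res.topic_models:
                raise ValueError("topic block enabled but no topic models provided")
            names += [f"topic_K{m.K}" for m in res.topic_models]
        return names

    # -- transform ----------------------------------------------------------

    def transform(
        self,
        candidates: Sequence[CandidateTerm],
        notes: Mapping[str, Note],
    ) -> FeatureMatrix:
        if self.lexical_categories is None:
            raise RuntimeError("FeatureExtractor not fitted")
        cfg, res = self.config, self.resources
        if cfg.baseline and res.background is None:
            raise ValueError("baseline block enabled but no background corpus")
        names = self.feature_names()
        col_of = {n: i for i, n in enumerate(names)}
        data: list[float] = []
        indices: list[int] = []
        indptr = [0]
        rows: list[tuple[str, str]] = []

        def put(col: int, val: float) -> None:
            if val != 0.0:
                data.append(val)
                indices.append(col)

        for c in candidates:
            note = notes[c.note_id]
            if cfg.baseline:
                tf, idf, tfidf = frequency_features(c, note, res.background)
                tl, maxwl, comb = length_features(c, cfg.combined_form)
                put(col_of["tf"], tf)
                put(col_of["idf"], idf)
                put(col_of["tfidf"], tfidf)
                put(col_of["TL"], tl)
                put(col_of["maxWL"], maxwl)
                put(col_of["TLxWL"], comb)
                put(col_of["position"], position_feature(c, note))
                lex = lexical_feature(c, self._vocab_counts, cfg.lexical_min_count)
                if lex not in set(self.lexical_categories):
                    lex = RARE
                put(col_of[f"lex={lex}"], 1.0)
                put(col_of[f"pos={pos_feature(c, note, res.pos_tagger)}"], 1.0)
            if cfg.embedding:
                vec = embedding_feature(c, res.embeddings)
                base = col_of["emb_0"]
                for i, v in enumerate(vec):
                    put(base + i, float(v))
            if cfg.semantic_type:
                sty = semantic_type_feature(c, res.semantic_types)
                base = col_of[f"sty={res.semantic_types[0]}"]
                for i, v in enumerate(sty):
                    put(base + i, float(v))
            if cfg.chv:
                vec = chv_features(c)
                base = col_of["chv"]
                for i, v in enumerate(vec):
                    put(base + i, float(v))
            if cfg.topic:
                for mi, model in enumerate(res.topic_models):
                    val = self._raw_topic_value(mi, model, c, notes)
                    if self.topic_bounds is not None:
                        lo, hi = self.topic_bounds[mi]
                        val = 0.5 if hi <= lo else min(max((val - lo) / (hi - lo), 0.0), 1.0)
                    put(col_of[f"topic_K{model.K}"], val)
            indptr.append(len(data))
            rows.append((c.note_id, c.canonical_term))

        X = sparse.csr_matrix(
            (np.array(data), np.array(indices, dtype=np.int32), np.array(indptr)),
            shape=(len(candidates), len(names)),
        )
        return FeatureMatrix(X=X, names=names, rows=rows)


def assemble(
    candidates: Sequence[CandidateTerm],
    config: FeatureConfig,
    resources: FeatureResources,
    notes: Mapping[str, Note],
    train_candidates: Optional[Sequence[CandidateTerm]] = None,
) -> FeatureMatrix:
    """One-shot assembly: fit on ``train_candidates`` (default: all), then
    transform ``candidates``."""
    fx = FeatureExtractor(config, resources)
    fx.fit(train_candidates if train_candidates is not None else candidates, notes)
    return fx.transform(candidates, notes)
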