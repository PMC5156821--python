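"""LDA topic models and topic-coherence features.

The model fitting itself is delegated to scikit-learn's
``LatentDirichletAllocation``; what this module owns is the coherence
computation between a candidate term and its note:

    P(w | e) = sum_i  P(w | topic_i) * P(topic_i | e)
    P(t | e) = prod_{w in t}  P(w | e)

so a term whose words sit in the note's dominant topics scores high. A
geometric-mean combiner is available to de-bias term length. Words outside
the model vocabulary are floored at a small epsilon, keeping the feature
strictly inside (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer

from .extraction import CandidateTerm
from .lexicon import stem_word

__all__ = [
    "TopicModel",
    "train_topic_model",
    "word_prob_given_doc",
    "topic_feature",
    "save_topic_model",
    "load_topic_model",
]

EPS = 1e-9


@dataclass
class TopicModel:
    """K topics over a fixed vocabulary, plus an inference routine.

    ``word_topic`` has one probability distribution per row (topic); the
    fitted sklearn model is retained so a new document's topic mixture can
    be inferred.
    """

    K: int
    vocabulary: list[str]
    word_topic: np.ndarray            # K x V, rows sum to 1
    seed: int
    _lda: LatentDirichletAllocation | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.word_topic.shape != (self.K, len(self.vocabulary)):
            raise ValueError("word_topic shape mismatch")
        rowsums = self.word_topic.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("word_topic rows must sum to 1")
        self._word_index = {w: i for i, w in enumerate(self.vocabulary)}

    def infer(self, tokens: Sequence[str]) -> np.ndarray:
        """Topic mixture theta of a new document (stemmed tokens)."""
        if self._lda is None:
            raise RuntimeError("model carries no inference routine")
        counts = np.zeros((1, len(self.vocabulary)))
        for t in tokens:
            j = self._word_index.get(t)
            if j is not None:
                counts[0, j] += 1
        theta = self._lda.transform(counts)[0]
        return theta / theta.sum()


def _doc_term_matrix(documents: Sequence[Sequence[str]]):
    vec = CountVectorizer(
        analyzer=lambda doc: doc, lowercase=False
    )
    X = vec.fit_transform(list(documents))
    return X, list(vec.get_feature_names_out())


def train_topic_model(background, K: int, seed: int) -> TopicModel:
    """Fit a K-topic LDA on the background corpus with a fixed seed."""
    documents = background.documents if hasattr(background, "documents") else background
    X, vocabulary = _doc_term_matrix(documents)
    if K > len(vocabulary):
        raise ValueError(f"K={K} exceeds vocabulary size {len(vocabulary)}")
    lda = LatentDirichletAllocation(
        n_components=K, random_state=seed, learning_method="batch", max_iter=20
    )
    lda.fit(X)
    word_topic = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModel(
        K=K, vocabulary=vocabulary, word_topic=word_topic, seed=seed, _lda=lda
    )


def word_prob_given_doc(
    model: TopicModel, word: str, theta: np.ndarray
) -> float:
    """P(w|e) as the theta-weighted mixture of per-topic word probabilities.

    Out-of-vocabulary words are floored at ``EPS``.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (model.K,):
        raise ValueError(f"theta length {theta.shape} does not match K={model.K}")
    j = model._word_index.get(word)
    if j is None:
        return EPS
    return float(max(model.word_topic[:, j] @ theta, EPS))


def topic_feature(
    model: TopicModel,
    candidate: CandidateTerm | Sequence[str],
    theta: np.ndarray,
    combiner: str = "product",
) -> float:
    """Topic coherence P(t|e) of a term with its note.

    Combines the member words' P(w|e) by product (words treated as
    independent) or geometric mean (``combiner="geomean"``).
    """
    if isinstance(candidate, CandidateTerm):
        words = [stem_word(w) for w in candidate.canonical_term.split()]
    else:
        words = list(candidate)
    if not words:
        raise ValueError("topic_feature: empty term")
    probs = [word_prob_given_doc(model, w, theta) for w in words]
    if combiner == "product":
        return float(np.prod(probs))
    if combiner == "geomean":
        return float(np.exp(np.mean(np.log(probs))))
    raise ValueError(f"unknown combiner {combiner!r}")


def save_topic_model(model: TopicModel, directory: str | Path) -> None:
    """Persist K, vocabulary and the dense word-topic matrix as text."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "vocabulary.txt").write_text("\n".join(model.vocabulary), encoding="utf-8")
    np.savetxt(d / "word_topic.tsv", model.word_topic, delimiter="\t")
    (d / "meta.json").write_text(
        json.dumps({"K": model.K, "seed": model.seed}), encoding="utf-8"
    )


def load_topic_model(directory: str | Path) -> TopicModel:
    """Load a saved model (no inference routine; matrix queries only)."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text(encoding="utf-8"))
    vocabulary = (d / "vocabulary.txt").read_text(encoding="utf-8").splitlines()
    word_topic = np.loadtxt(d / "word_topic.tsv", delimiter="\t", ndmin=2)
    return TopicModel(
        K=meta["K"], vocabulary=vocabulary, word_topic=word_topic, seed=meta["seed"]
    )
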