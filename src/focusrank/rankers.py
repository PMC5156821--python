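"""Pairwise rankSVM and the random-forest ranking baseline.

The rankSVM learns a linear scorer w·x by minimising

    1/2 ||w||^2 + (C/m) * sum_{(i,j) in P} max(0, 1 - w·(x_i - x_j))

over the set P of all within-note (important, nonimportant) candidate
pairs, m = |P| — a large-margin objective whose hinge term upper-bounds
the number of swapped pairs. The optimisation runs on pair difference
vectors through liblinear (hinge loss, no intercept); each difference is
included with both signs so a two-class problem with per-sample weight
C/(2m) reproduces the objective above exactly.

The baseline scores candidates with a random-forest classifier whose
per-tree outputs are leaf-node positive fractions, averaged over the B
trees; B is chosen by minimum out-of-bag error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC

from .extraction import CandidateTerm
from .features import FeatureMatrix

__all__ = [
    "TrainingPairSet",
    "RankSVMModel",
    "RFModel",
    "RankedList",
    "build_pairs",
    "ranksvm_objective",
    "train_ranksvm",
    "train_rf",
    "score_and_rank",
    "select_C",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class TrainingPairSet:
    """All within-note (positive index, negative index) pairs; m = count."""

    pairs: list[tuple[int, int]]

    @property
    def m(self) -> int:
        return len(self.pairs)


@dataclass
class RankSVMModel:
    w: np.ndarray
    C: float
    feature_names: list[str]
    objective: float
    seed: int = 0

    def scores(self, X) -> np.ndarray:
        return np.asarray(X @ self.w).ravel()


@dataclass
class RFModel:
    B: int
    forest: RandomForestClassifier
    feature_names: list[str]
    oob_errors: dict[int, float] = field(default_factory=dict)

    def scores(self, X) -> np.ndarray:
        return self.forest.predict_proba(X)[:, 1]


@dataclass
class RankedList:
    """Score-sorted terms of one note with a deterministic tie-break."""

    note_id: str
    ranking: list[tuple[str, float]]  # (term, score), scores non-increasing
    tie_break: str = "score desc, first_token_index asc, term asc"

    @property
    def terms(self) -> list[str]:
        return [t for t, _ in self.ranking]


def build_pairs(
    candidates: Sequence[CandidateTerm],
    labels: Optional[Sequence[int]] = None,
) -> TrainingPairSet:
    """Enumerate all (important, nonimportant) index pairs within notes.

    A note with no positives or no negatives simply contributes no pairs.
    """
    if labels is None:
        labels = [c.label for c in candidates]
    by_note: dict[str, list[int]] = {}
    for i, c in enumerate(candidates):
        by_note.setdefault(c.note_id, []).append(i)
    pairs: list[tuple[int, int]] = []
    for note_id in sorted(by_note):
        idx = by_note[note_id]
        pos = [i for i in idx if labels[i] == 1]
        neg = [i for i in idx if labels[i] == 0]
        pairs.extend((i, j) for i in pos for j in neg)
    return TrainingPairSet(pairs=pairs)


def _difference_matrix(X, pairs: TrainingPairSet):
    pos_idx = np.array([p[0] for p in pairs.pairs])
    neg_idx = np.array([p[1] for p in pairs.pairs])
    if sparse.issparse(X):
        return X[pos_idx] - X[neg_idx]
    return np.asarray(X)[pos_idx] - np.asarray(X)[neg_idx]


def ranksvm_objective(w: np.ndarray, X, pairs: TrainingPairSet, C: float) -> float:
    """Value of the pairwise large-margin objective at w."""
    D = _difference_matrix(X, pairs)
    margins = np.asarray(D @ w).ravel()
    hinge = np.maximum(0.0, 1.0 - margins).sum()
    return 0.5 * float(w @ w) + (C / pairs.m) * float(hinge)


def train_ranksvm(
    X,
    pairs: TrainingPairSet,
    C: float = 1.0,
    feature_names: Optional[Sequence[str]] = None,
    seed: int = 0,
    tol: float = 1e-8,
) -> RankSVMModel:
    """Fit the pairwise hinge objective on difference vectors.

    Raises if the pair set is empty or C is not positive.
    """
    if isinstance(X, FeatureMatrix):
        feature_names = feature_names or X.names
        X = X.X
    if pairs.m == 0:
        raise ValueError("no training pairs")
    if C <= 0:
        raise ValueError("C must be > 0")
    D = _difference_matrix(X, pairs)
    if sparse.issparse(D):
        Xfit = sparse.vstack([D, -D]).tocsr()
    else:
        Xfit = np.vstack([D, -D])
    y = np.concatenate([np.ones(pairs.m), -np.ones(pairs.m)])
    # sample weight C/(2m) via LinearSVC's C parameter: liblinear minimises
    # 1/2||w||^2 + C_svc * sum hinge, and the mirrored samples double the sum
    svc = LinearSVC(
        loss="hinge",
        C=C / (2.0 * pairs.m),
        fit_intercept=False,
        tol=tol,
        max_iter=200_000,
        random_state=seed,
    )
    svc.fit(Xfit, y)
    w = svc.coef_.ravel().copy()
    obj = ranksvm_objective(w, X, pairs, C)
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(X.shape[1])
    ]
    return RankSVMModel(w=w, C=C, feature_names=names, objective=obj, seed=seed)


def train_rf(
    X,
    labels: Sequence[int],
    B_grid: Sequence[int] = (100, 200, 300),
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> RFModel:
    """Random-forest scorer with B selected by out-of-bag error."""
    if isinstance(X, FeatureMatrix):
        feature_names = feature_names or X.names
        X = X.X
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("train_rf: labels contain a single class")
    if not B_grid:
        raise ValueError("empty B grid")
    oob_errors: dict[int, float] = {}
    best: tuple[float, int] | None = None
    for B in B_grid:
        forest = RandomForestClassifier(
            n_estimators=B, oob_score=True, random_state=seed, n_jobs=1
        )
        forest.fit(X, y)
        err = 1.0 - float(forest.oob_score_)
        oob_errors[B] = err
        if best is None or (err, B) < best:
            best = (err, B)
    B_star = best[1]
    forest = RandomForestClassifier(
        n_estimators=B_star, oob_score=True, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(X.shape[1])
    ]
    return RFModel(B=B_star, forest=forest, feature_names=names, oob_errors=oob_errors)


def score_and_rank(
    model: RankSVMModel | RFModel,
    candidates: Sequence[CandidateTerm],
    X,
    feature_names: Optional[Sequence[str]] = None,
) -> RankedList:
    """Score one note's candidates and sort deterministically.

    Sort key: score descending, then earlier first occurrence, then
    lexicographic term order — so permuting the input leaves the output
    unchanged.
    """
    if isinstance(X, FeatureMatrix):
        feature_names = feature_names or X.names
        X = X.X
    if feature_names is not None and list(feature_names) != list(model.feature_names):
        raise ValueError("feature schema does not match the trained model")
    if not candidates:
        raise ValueError("no candidates to rank")
    note_ids = {c.note_id for c in candidates}
    if len(note_ids) != 1:
        raise ValueError("score_and_rank expects the candidates of one note")
    scores = model.scores(X)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-scores[i], candidates[i].first_token_index,
                       candidates[i].canonical_term),
    )
    ranking = [(candidates[i].canonical_term, float(scores[i])) for i in order]
    return RankedList(note_id=note_ids.pop(), ranking=ranking)


def select_C(
    X,
    candidates: Sequence[CandidateTerm],
    grid: Sequence[float] = DEFAULT_C_GRID,
    folds: int = 3,
    seed: int = 0,
) -> float:
    """Inner-CV choice of C maximising mean per-note ranking AUC.

    Notes are partitioned into ``folds`` inner folds; for each C the
    rankSVM is trained on the inner-training pairs and evaluated on the
    held-out notes; ties go to the smallest C.
    """
    from .evaluation import auc_ranking, make_folds

    if not grid:
        raise ValueError("empty C grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if isinstance(X, FeatureMatrix):
        X = X.X
    labels = np.array([c.label for c in candidates])
    note_ids = sorted({c.note_id for c in candidates})
    fold_of = make_folds(note_ids, folds, seed)
    row_fold = np.array([fold_of[c.note_id] for c in candidates])
    results: dict[float, list[float]] = {float(c): [] for c in grid}
    for fold in range(folds):
        train_rows = np.where(row_fold != fold)[0]
        test_rows = np.where(row_fold == fold)[0]
        train_cands = [candidates[i] for i in train_rows]
        pairs = build_pairs(train_cands)
        if pairs.m == 0:
            continue
        Xtr = X[train_rows]
        for C in grid:
            model = train_ranksvm(Xtr, pairs, C=C, seed=seed)
            scores = model.scores(X[test_rows])
            # per-note AUC on the held-out notes
            by_note: dict[str, list[int]] = {}
            for k, i in enumerate(test_rows):
                by_note.setdefault(candidates[i].note_id, []).append(k)
            for nid, rows_k in by_note.items():
                lab = labels[test_rows[rows_k]]
                if lab.min() == lab.max():
                    continue
                results[float(C)].append(auc_ranking(scores[rows_k], lab))
    means = {C: (np.mean(v) if v else 0.0) for C, v in results.items()}
    best = max(sorted(means), key=lambda C: (means[C], -C))
    return float(best)


def save_ranksvm(model: RankSVMModel, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# C={model.C}\tobjective={model.objective}\tseed={model.seed}\n")
        for name, w in zip(model.feature_names, model.w):
            fh.write(f"{name}\t{float(w)!r}\n")


def load_ranksvm(path: str | Path) -> RankSVMModel:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    meta = dict(kv.split("=") for kv in lines[0][2:].split("\t"))
    names, ws = [], []
    for line in lines[1:]:
        name, w = line.rsplit("\t", 1)
        names.append(name)
        ws.append(float(w))
    return RankSVMModel(
        w=np.array(ws),
        C=float(meta["C"]),
        feature_names=names,
        objective=float(meta["objective"]),
        seed=int(meta["seed"]),
    )


def write_ranked_lists(ranked: Sequence[RankedList], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("note_id\trank\tterm\tscore\n")
        for rl in ranked:
            for rank, (term, score) in enumerate(rl.ranking, start=1):
                fh.write(f"{rl.note_id}\t{rank}\t{term}\t{score:.6g}\n")
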