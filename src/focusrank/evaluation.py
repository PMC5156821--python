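"""Evaluation protocol: relaxed string match, rank metrics, CV, t tests.

Two AUC variants are reported per note and macro-averaged:

* ``auc_ranking`` — over the candidates a system actually extracted;
  isolates ranking quality given extraction.
* ``auc_ke`` — additionally counts every gold term the extractor missed as
  a positive ranked strictly below all candidates; measures extraction and
  ranking jointly. With no score ties against the phantom positives it
  factorises as ``auc_ranking * found / (found + missed)``.

True positives at rank k use relaxed string match: a system term counts if
it exactly matches or subsumes (contains) a gold term, never the reverse —
a fragment of an important term is typically too general to be important.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .lexicon import normalize_term

__all__ = [
    "relaxed_match",
    "prf_at_k",
    "auc_ranking",
    "auc_ke",
    "paired_t_test",
    "evaluate_note",
    "EvalReport",
    "cross_validate",
    "make_folds",
]

METRIC_NAMES = ["P5", "R5", "F5", "P10", "R10", "F10", "auc_ranking", "auc_ke"]


def relaxed_match(system_term: str, gold_term: str) -> bool:
    """True iff the system term equals or subsumes the gold term.

    Both terms are normalised (lowercase, possessives stripped, Porter
    stems); the gold token sequence must occur contiguously inside the
    system sequence. Containment the other way round does not count.
    """
    sys_key = normalize_term(system_term)
    gold_key = normalize_term(gold_term)
    if not sys_key or not gold_key:
        return False
    if len(gold_key) > len(sys_key):
        return False
    for i in range(len(sys_key) - len(gold_key) + 1):
        if sys_key[i : i + len(gold_key)] == gold_key:
            return True
    return False


def prf_at_k(
    ranked_terms: Sequence[str],
    gold: Sequence[str],
    k: int,
) -> tuple[float, float, float]:
    """Precision/recall/F over the top-k ranked terms.

    Each system term in the top ``min(k, len(ranked))`` is a true positive
    if it relaxed-matches a gold term; every gold term can be credited at
    most once, so a duplicated system term cannot double-count. P divides
    by k, R by ``|gold|``. Raises on an empty gold set (the caller skips
    such notes).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    gold = list(gold)
    if not gold:
        raise ValueError("prf_at_k: empty gold set (note should be skipped)")
    credited: set[int] = set()
    tp = 0
    for term in ranked_terms[:k]:
        for gi, g in enumerate(gold):
            if gi not in credited and relaxed_match(term, g):
                credited.add(gi)
                tp += 1
                break
    p = tp / k
    r = tp / len(gold)
    f = 0.0 if (p + r) == 0 else 2 * p * r / (p + r)
    return p, r, f


def auc_ranking(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Per-note AUC over extracted candidates.

    Equals the fraction of (positive, negative) candidate pairs ranked
    concordantly, counting exact score ties as 1/2. Raises if the note has
    a single class (the caller skips and reports such notes).
    """
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("auc_ranking: single-class note")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auc_ke(
    scores: Sequence[float],
    labels: Sequence[int],
    n_missed_gold: int,
) -> float:
    """AUC counting extractor-missed gold terms as bottom-ranked positives.

    Each missed gold term is appended as a phantom positive scored strictly
    below every candidate, contributing zero concordance.
    """
    if n_missed_gold < 0:
        raise ValueError("n_missed_gold must be >= 0")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if n_missed_gold == 0:
        return auc_ranking(scores, labels)
    if labels.sum() == 0:
        raise ValueError("auc_ke: no scored positives (all gold terms missed)")
    floor = scores.min() - 1.0
    ext_scores = np.concatenate([scores, np.full(n_missed_gold, floor)])
    ext_labels = np.concatenate([labels, np.ones(n_missed_gold, dtype=labels.dtype)])
    if ext_labels.min() == ext_labels.max():
        raise ValueError("auc_ke: no negative candidates")
    return float(roc_auc_score(ext_labels, ext_scores))


def paired_t_test(
    metric_a: Sequence[float],
    metric_b: Sequence[float],
) -> tuple[float, bool]:
    """Two-sided paired t test on per-note metric differences.

    Returns ``(p_value, degenerate)`` where ``degenerate`` flags a
    zero-variance difference vector: identical systems give p = 1.0,
    a constant nonzero difference gives p = 0.0 with the flag set.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_t_test: need two equal-length vectors, n >= 2")
    d = a - b
    if np.allclose(d.std(), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 1.0, True
        return 0.0, True
    res = stats.ttest_rel(a, b)
    return float(res.pvalue), False


def evaluate_note(
    ranked_terms: Sequence[str],
    scores: Sequence[float],
    labels: Sequence[int],
    gold: Sequence[str],
    n_missed_gold: int,
) -> dict[str, float]:
    """All per-note metrics; NaN where a metric is undefined for the note."""
    out: dict[str, float] = {}
    if gold:
        for k in (5, 10):
            p, r, f = prf_at_k(ranked_terms, gold, k)
            out[f"P{k}"], out[f"R{k}"], out[f"F{k}"] = p, r, f
    else:
        for name in ("P5", "R5", "F5", "P10", "R10", "F10"):
            out[name] = float("nan")
    try:
        out["auc_ranking"] = auc_ranking(scores, labels)
    except ValueError:
        out["auc_ranking"] = float("nan")
    try:
        out["auc_ke"] = auc_ke(scores, labels, n_missed_gold)
    except ValueError:
        out["auc_ke"] = float("nan")
    return out


@dataclass
class EvalReport:
    """Cross-validation report: per-note metric table and macro means."""

    system: str
    per_note: pd.DataFrame           # index note_id, columns METRIC_NAMES
    fold_assignment: dict[str, int]  # note_id -> fold
    skipped: dict[str, list[str]] = field(default_factory=dict)

    @property
    def macro(self) -> pd.Series:
        return self.per_note.mean(skipna=True)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "system": self.system,
            "macro": {k: float(v) for k, v in self.macro.items()},
            "per_note": json.loads(self.per_note.to_json(orient="index")),
            "fold_assignment": self.fold_assignment,
            "skipped": self.skipped,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    def to_tsv(self, path: str | Path) -> None:
        self.per_note.to_csv(path, sep="\t", index_label="note_id")

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        per_note = pd.DataFrame.from_dict(payload["per_note"], orient="index")
        per_note = per_note.loc[sorted(per_note.index), METRIC_NAMES]
        return cls(
            system=payload["system"],
            per_note=per_note,
            fold_assignment={k: int(v) for k, v in payload["fold_assignment"].items()},
            skipped=payload.get("skipped", {}),
        )


def make_folds(note_ids: Sequence[str], folds: int, seed: int) -> dict[str, int]:
    """Deterministic partition of note ids into CV folds."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ids = sorted(note_ids)
    if folds > len(ids):
        raise ValueError(f"folds={folds} exceeds note count {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return {ids[j]: int(i % folds) for i, j in enumerate(perm)}


def cross_validate(
    corpus,
    feature_config,
    ranker_spec: str = "ranksvm",
    folds: int = 10,
    seed: int = 0,
    *,
    C: float = 1.0,
    C_grid: Optional[Sequence[float]] = None,
    B_grid: Sequence[int] = (100, 200, 300),
    system_name: Optional[str] = None,
) -> EvalReport:
    """K-fold cross-validated evaluation of a ranker on a labelled corpus.

    ``corpus`` is an :class:`~focusrank.experiment.LabeledCorpus` (notes,
    labelled candidates, gold sets, per-note miss counts, shared
    resources). All training-fold-derived resources — the lexical
    vocabulary, one-hot category sets and, when ``C_grid`` is given, the
    rankSVM C — are rebuilt inside each fold. Metrics are macro-averaged
    over all evaluated notes.
    """
    from .experiment import run_fold  # deferred: experiment imports us

    fold_of = make_folds(list(corpus.candidates_by_note), folds, seed)
    rows: dict[str, dict[str, float]] = {}
    skipped: dict[str, list[str]] = {}
    for fold in range(folds):
        test_ids = sorted(nid for nid, f in fold_of.items() if f == fold)
        train_ids = sorted(nid for nid, f in fold_of.items() if f != fold)
        fold_rows, fold_skipped = run_fold(
            corpus,
            feature_config,
            ranker_spec,
            train_ids,
            test_ids,
            seed=seed + fold,
            C=C,
            C_grid=C_grid,
            B_grid=B_grid,
        )
        rows.update(fold_rows)
        for k, v in fold_skipped.items():
            skipped.setdefault(k, []).extend(v)
    per_note = pd.DataFrame.from_dict(rows, orient="index").loc[
        sorted(rows), METRIC_NAMES
    ]
    return EvalReport(
        system=system_name or ranker_spec,
        per_note=per_note,
        fold_assignment=fold_of,
        skipped=skipped,
    )
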