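"""End-to-end experiment loop: simulate -> extract -> featurize -> train ->
rank -> evaluate, with deterministic artifacts.

The :class:`LabeledCorpus` is the central in-memory object: tokenised
notes, relaxed-match-labelled candidates, gold sets, per-note extraction
miss counts, and the shared feature resources (background corpus,
embedding table, topic models). :func:`run_fold` does one train/test split
of a cross-validation; :func:`run_experiment` drives the whole loop from a
config and writes artifacts.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    EvalReport,
    METRIC_NAMES,
    cross_validate,
    evaluate_note,
    paired_t_test,
)
from .extraction import (
    CandidateTerm,
    Note,
    extract_candidates,
    label_candidates,
    load_gold,
    load_notes,
    write_candidates,
)
from .features import (
    FeatureConfig,
    FeatureExtractor,
    FeatureResources,
    load_embeddings,
)
from .lexicon import Lexicon, load_lexicon
from .rankers import (
    build_pairs,
    save_ranksvm,
    score_and_rank,
    select_C,
    train_ranksvm,
    train_rf,
    write_ranked_lists,
)

__all__ = [
    "LabeledCorpus",
    "ExperimentConfig",
    "build_labeled_corpus",
    "prepare_resources",
    "run_fold",
    "run_experiment",
    "compare_systems",
]


@dataclass
class LabeledCorpus:
    notes: dict[str, Note]
    candidates_by_note: dict[str, list[CandidateTerm]]
    gold: dict[str, set[str]]
    n_missed: dict[str, int]
    resources: FeatureResources

    def all_candidates(self, note_ids: Optional[Sequence[str]] = None) -> list[CandidateTerm]:
        ids = sorted(self.candidates_by_note) if note_ids is None else list(note_ids)
        out: list[CandidateTerm] = []
        for nid in ids:
            out.extend(self.candidates_by_note[nid])
        return out


def build_labeled_corpus(
    notes: Sequence[Note],
    gold: dict[str, set[str]],
    lexicon: Lexicon,
    resources: FeatureResources,
) -> LabeledCorpus:
    """Extract and relaxed-match-label candidates for every note."""
    cands: dict[str, list[CandidateTerm]] = {}
    n_missed: dict[str, int] = {}
    for note in notes:
        raw = extract_candidates(note, lexicon)
        labeled, missed = label_candidates(raw, gold.get(note.note_id, set()))
        cands[note.note_id] = labeled
        n_missed[note.note_id] = missed
    return LabeledCorpus(
        notes={n.note_id: n for n in notes},
        candidates_by_note=cands,
        gold={nid: set(gold.get(nid, set())) for nid in cands},
        n_missed=n_missed,
        resources=resources,
    )


def prepare_resources(
    background=None,
    embeddings=None,
    topic_Ks: Sequence[int] = (),
    seed: int = 0,
    semantic_types: Optional[Sequence[str]] = None,
) -> FeatureResources:
    """Train topic models on the background corpus and bundle resources."""
    from .topics import train_topic_model

    models = [train_topic_model(background, K, seed=seed + K) for K in topic_Ks]
    kwargs = {}
    if semantic_types is not None:
        kwargs["semantic_types"] = tuple(semantic_types)
    return FeatureResources(
        background=background, embeddings=embeddings, topic_models=models, **kwargs
    )


def run_fold(
    corpus: LabeledCorpus,
    feature_config: FeatureConfig,
    ranker_spec: str,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    seed: int = 0,
    C: float = 1.0,
    C_grid: Optional[Sequence[float]] = None,
    B_grid: Sequence[int] = (100, 200, 300),
):
    """Train on the training notes, rank and score the held-out notes.

    Returns ``(rows, skipped)``: per-note metric dicts and the notes where
    a metric was undefined (empty gold, single-class candidates).
    """
    train_cands = corpus.all_candidates(train_ids)
    fx = FeatureExtractor(feature_config, corpus.resources).fit(train_cands, corpus.notes)
    Xtr = fx.transform(train_cands, corpus.notes)
    if ranker_spec == "ranksvm":
        pairs = build_pairs(train_cands)
        C_star = C
        if C_grid:
            C_star = select_C(Xtr, train_cands, C_grid, folds=3, seed=seed)
        model = train_ranksvm(
            Xtr.X, pairs, C=C_star, feature_names=Xtr.names, seed=seed
        )
    elif ranker_spec == "rf":
        labels = [c.label for c in train_cands]
        model = train_rf(Xtr.X, labels, B_grid=B_grid, seed=seed, feature_names=Xtr.names)
    else:
        raise ValueError(f"unknown ranker spec {ranker_spec!r}")

    rows: dict[str, dict[str, float]] = {}
    skipped: dict[str, list[str]] = {}
    for nid in sorted(test_ids):
        cands = corpus.candidates_by_note[nid]
        if not cands:
            skipped.setdefault("no_candidates", []).append(nid)
            continue
        Xte = fx.transform(cands, corpus.notes)
        ranked = score_and_rank(model, cands, Xte)
        scores = model.scores(Xte.X)
        labels = [c.label for c in cands]
        metrics = evaluate_note(
            ranked.terms, scores, labels, sorted(corpus.gold[nid]),
            corpus.n_missed[nid],
        )
        if not corpus.gold[nid]:
            skipped.setdefault("empty_gold", []).append(nid)
        if np.isnan(metrics["auc_ranking"]):
            skipped.setdefault("single_class", []).append(nid)
        rows[nid] = metrics
    return rows, skipped


# ---------------------------------------------------------------------------
# config-driven runs


@dataclass
class ExperimentConfig:
    """Everything a full run needs; synthetic when no paths are given."""

    # data: either a synthetic profile name or on-disk paths
    profile: Optional[str] = "table1"
    notes_dir: Optional[str] = None
    gold_path: Optional[str] = None
    lexicon_path: Optional[str] = None
    embeddings_path: Optional[str] = None
    # features
    feature_set: str = "full"          # "full" | "baseline"
    embedding_d: int = 50
    embedding_signal: float = 1.0
    topic_Ks: tuple[int, ...] = (50, 100, 200)
    # ranking and evaluation
    ranker: str = "ranksvm"            # "ranksvm" | "rf"
    folds: int = 10
    # C chosen once by inner cross-validation (select_C) on the default
    # synthetic corpus; the topic combiner de-biases term length
    C: float = 100.0
    topic_combiner: str = "geomean"
    C_grid: Optional[tuple[float, ...]] = None
    B_grid: tuple[int, ...] = (100, 200, 300)
    seed: int = 42
    # synthetic-scale overrides (None = profile defaults)
    n_notes: Optional[int] = None
    n_lexicon_terms: Optional[int] = None
    n_background_docs: Optional[int] = None
    # output
    out_dir: Optional[str] = None
    write_features: bool = False

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.ranker not in ("ranksvm", "rf"):
            raise ValueError(f"unknown ranker {self.ranker!r}")
        if self.feature_set not in ("full", "baseline"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for key in ("topic_Ks", "C_grid", "B_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def feature_config(self) -> FeatureConfig:
        if self.feature_set == "baseline":
            return FeatureConfig.baseline_only()
        cfg = FeatureConfig.full()
        cfg.topic_combiner = self.topic_combiner
        return cfg


def _build_corpus_from_config(cfg: ExperimentConfig):
    """Materialise (corpus, lexicon) from a config, synthetic or on-disk."""
    from .synthetic_data import (
        PROFILES,
        generate_background,
        generate_corpus,
        generate_embeddings,
        generate_lexicon,
    )
    from dataclasses import replace as dc_replace

    fc = cfg.feature_config()
    if cfg.notes_dir is not None:
        notes = load_notes(cfg.notes_dir)
        gold = load_gold(cfg.gold_path)
        lexicon = load_lexicon(cfg.lexicon_path)
        embeddings = (
            load_embeddings(cfg.embeddings_path) if fc.embedding else None
        )
        background = _background_from_notes(notes) if (fc.baseline or fc.topic) else None
    else:
        profile = PROFILES[cfg.profile or "table1"]
        overrides = {}
        if cfg.n_notes is not None:
            overrides["n_notes"] = cfg.n_notes
        if cfg.n_lexicon_terms is not None:
            overrides["n_lexicon_terms"] = cfg.n_lexicon_terms
        if cfg.n_background_docs is not None:
            overrides["n_background_docs"] = cfg.n_background_docs
        if overrides:
            profile = dc_replace(profile, **overrides)
        lexicon = generate_lexicon(profile, seed=cfg.seed)
        notes, gold, _truth = generate_corpus(profile, lexicon, seed=cfg.seed)
        background = generate_background(profile, seed=cfg.seed, lexicon=lexicon)
        embeddings = (
            generate_embeddings(
                lexicon, d=cfg.embedding_d,
                signal_strength=cfg.embedding_signal, seed=cfg.seed,
            )
            if fc.embedding
            else None
        )
    resources = prepare_resources(
        background=background,
        embeddings=embeddings,
        topic_Ks=cfg.topic_Ks if fc.topic else (),
        seed=cfg.seed,
        semantic_types=lexicon.semantic_types,
    )
    corpus = build_labeled_corpus(notes, gold, lexicon, resources)
    return corpus, lexicon


def _background_from_notes(notes: Sequence[Note]):
    from .features import BackgroundCorpus

    return BackgroundCorpus([n.stems for n in notes])


def run_experiment(cfg: ExperimentConfig) -> EvalReport:
    """Execute the full loop and (optionally) write artifacts to disk.

    Re-running with an identical config reproduces the report exactly:
    every random stage is seeded from ``cfg.seed``.
    """
    corpus, lexicon = _build_corpus_from_config(cfg)
    report = cross_validate(
        corpus,
        cfg.feature_config(),
        ranker_spec=cfg.ranker,
        folds=cfg.folds,
        seed=cfg.seed,
        C=cfg.C,
        C_grid=cfg.C_grid,
        B_grid=cfg.B_grid,
        system_name=f"{cfg.ranker}-{cfg.feature_set}",
    )
    if cfg.out_dir is not None:
        _write_artifacts(cfg, corpus, report)
    return report


def _write_artifacts(cfg: ExperimentConfig, corpus: LabeledCorpus, report: EvalReport) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_cands = corpus.all_candidates()
    write_candidates(all_cands, out / "candidates.tsv")
    fx = FeatureExtractor(cfg.feature_config(), corpus.resources).fit(all_cands, corpus.notes)
    X = fx.transform(all_cands, corpus.notes)
    if cfg.write_features:
        X.to_tsv(out / "features.tsv")
    # final model on the whole corpus, plus its ranked lists
    if cfg.ranker == "ranksvm":
        pairs = build_pairs(all_cands)
        model = train_ranksvm(X.X, pairs, C=cfg.C, feature_names=X.names, seed=cfg.seed)
        save_ranksvm(model, out / "model.tsv")
    else:
        model = train_rf(
            X.X, [c.label for c in all_cands], B_grid=cfg.B_grid,
            seed=cfg.seed, feature_names=X.names,
        )
        (out / "model.json").write_text(
            json.dumps({"B": model.B, "oob_errors": model.oob_errors}), encoding="utf-8"
        )
    ranked = []
    start = 0
    for nid in sorted(corpus.candidates_by_note):
        cands = corpus.candidates_by_note[nid]
        if not cands:
            continue
        Xn = X.X[start : start + len(cands)]
        ranked.append(score_and_rank(model, cands, Xn, feature_names=X.names))
        start += len(cands)
    write_ranked_lists(ranked, out / "ranked.tsv")
    report.to_json(out / "report.json")
    report.to_tsv(out / "report.tsv")
    with (out / "folds.tsv").open("w", encoding="utf-8") as fh:
        for nid, f in sorted(report.fold_assignment.items()):
            fh.write(f"{nid}\t{f}\n")
    log = {
        "focusrank_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "ranker": cfg.ranker,
        "feature_set": cfg.feature_set,
        "folds": cfg.folds,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2), encoding="utf-8")


def compare_systems(report_a: EvalReport, report_b: EvalReport) -> pd.DataFrame:
    """Per-metric paired t tests between two systems on the same notes.

    Returns a grid with both macro means, the mean difference (a minus b)
    and the two-sided p-value for each of the eight metrics.
    """
    ids_a = list(report_a.per_note.index)
    ids_b = list(report_b.per_note.index)
    if ids_a != ids_b:
        raise ValueError("reports cover different note sets")
    rows = []
    for metric in METRIC_NAMES:
        a = report_a.per_note[metric]
        b = report_b.per_note[metric]
        mask = a.notna() & b.notna()
        p, degenerate = paired_t_test(a[mask].to_numpy(), b[mask].to_numpy())
        rows.append(
            {
                "metric": metric,
                f"mean_{report_a.system}": float(a[mask].mean()),
                f"mean_{report_b.system}": float(b[mask].mean()),
                "mean_diff": float((a[mask] - b[mask]).mean()),
                "p_value": p,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("metric")
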