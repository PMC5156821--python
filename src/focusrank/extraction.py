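"""Note tokenisation and candidate-term extraction.

The extractor is a greedy longest-dictionary-match scanner over the
stemmed token stream of a note (maximal munch, window bounded by the
longest lexicon key). It plays the role of a medical concept detector:
every extracted candidate is a lexicon term, extraction recall over gold
terms is below 100% and measurable, and all occurrences of a canonical
term in a note are merged into a single candidate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .lexicon import Lexicon, normalize_term, stem_word

__all__ = [
    "Token",
    "Note",
    "CandidateTerm",
    "tokenize",
    "make_note",
    "extract_candidates",
    "label_candidates",
    "load_notes",
    "load_gold",
    "write_gold",
    "write_candidates",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:['’][A-Za-z0-9]+)*")
_POSSESSIVE_RE = re.compile(r"['’]s$|['’]$")


@dataclass(frozen=True)
class Token:
    text: str          # raw surface form
    start: int         # character offset in the note text
    end: int
    stem: str          # lowercased, possessive-stripped, Porter-stemmed


@dataclass
class Note:
    """One clinical document with its token sequence."""

    note_id: str
    text: str
    tokens: list[Token] = field(default_factory=list)

    @property
    def word_count(self) -> int:
        return len(self.tokens)

    @property
    def stems(self) -> list[str]:
        return [t.stem for t in self.tokens]


@dataclass
class CandidateTerm:
    """A lexicon term found in a note — the unit that gets ranked.

    ``occurrences`` are non-overlapping token spans ``[start, end)`` in
    ascending order; ``label`` is 1 for patient-important, 0 for not, None
    before gold alignment.
    """

    note_id: str
    canonical_term: str
    occurrences: list[tuple[int, int]]
    semantic_type: str
    in_chv: bool
    familiarity: Optional[float] = None
    label: Optional[int] = None

    @property
    def first_token_index(self) -> int:
        return self.occurrences[0][0]

    @property
    def tf(self) -> int:
        return len(self.occurrences)


def tokenize(text: str) -> list[Token]:
    """Deterministic word tokenisation with offsets.

    Splits on whitespace and punctuation (hyphens split words), drops
    punctuation, strips possessives, and attaches the Porter stem of each
    lowercased token. Numerals are kept as tokens.
    """
    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        raw = m.group(0)
        base = _POSSESSIVE_RE.sub("", raw)
        if not base:
            continue
        # hyphens were excluded from the token pattern, so `raw` has no
        # hyphen; hyphenated words arrive here as successive matches
        for piece_m in re.finditer(r"[A-Za-z0-9]+", base):
            piece = piece_m.group(0)
            tokens.append(
                Token(
                    text=piece,
                    start=m.start() + piece_m.start(),
                    end=m.start() + piece_m.end(),
                    stem=stem_word(piece),
                )
            )
    return tokens


def make_note(note_id: str, text: str) -> Note:
    return Note(note_id=note_id, text=text, tokens=tokenize(text))


def extract_candidates(note: Note, lexicon: Lexicon) -> list[CandidateTerm]:
    """Greedy longest-match scan of the note against the lexicon.

    At each token position the longest lexicon key starting there (up to
    ``lexicon.max_term_words`` tokens) is taken; the scan resumes after the
    match, so extracted spans never overlap. Occurrences of the same
    canonical term are merged into one candidate. Candidates are returned
    in order of first occurrence.
    """
    stems = note.stems
    n = len(stems)
    found: dict[str, CandidateTerm] = {}
    i = 0
    while i < n:
        match_entry = None
        match_len = 0
        max_w = min(lexicon.max_term_words, n - i)
        for w in range(max_w, 0, -1):
            entry = lexicon.index.get(tuple(stems[i : i + w]))
            if entry is not None:
                match_entry, match_len = entry, w
                break
        if match_entry is None:
            i += 1
            continue
        span = (i, i + match_len)
        cand = found.get(match_entry.term)
        if cand is None:
            found[match_entry.term] = CandidateTerm(
                note_id=note.note_id,
                canonical_term=match_entry.term,
                occurrences=[span],
                semantic_type=match_entry.semantic_type,
                in_chv=match_entry.in_chv,
                familiarity=match_entry.familiarity,
            )
        else:
            cand.occurrences.append(span)
        i += match_len
    return sorted(found.values(), key=lambda c: c.first_token_index)


def label_candidates(
    candidates: Sequence[CandidateTerm],
    gold: Iterable[str],
) -> tuple[list[CandidateTerm], int]:
    """Align candidates with gold terms by relaxed string match.

    A candidate is positive iff it exactly matches or subsumes (contains as
    a contiguous token subsequence) some gold term after normalisation.
    Returns the labelled candidates plus the number of gold terms matched
    by no candidate (extraction misses, needed for the extraction-aware
    AUC).
    """
    from .evaluation import relaxed_match  # local import to avoid a cycle

    gold_terms = list(gold)
    labeled = []
    matched_gold: set[int] = set()
    for cand in candidates:
        label = 0
        for gi, g in enumerate(gold_terms):
            if relaxed_match(cand.canonical_term, g):
                label = 1
                matched_gold.add(gi)
        labeled.append(replace(cand, label=label, occurrences=list(cand.occurrences)))
    n_missed = len(gold_terms) - len(matched_gold)
    return labeled, n_missed


# ---------------------------------------------------------------------------
# plain-text corpus I/O


def load_notes(notes_dir: str | Path) -> list[Note]:
    """Read every ``*.txt`` in a directory; note_id is the file stem."""
    notes = []
    for p in sorted(Path(notes_dir).glob("*.txt")):
        notes.append(make_note(p.stem, p.read_text(encoding="utf-8")))
    return notes


def load_gold(path: str | Path) -> dict[str, set[str]]:
    """Read a gold-annotation TSV (note_id <tab> term), one row per term."""
    gold: dict[str, set[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            gold.setdefault(parts[0], set()).add(parts[1])
    return gold


def write_gold(gold: dict[str, set[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for note_id in sorted(gold):
            for term in sorted(gold[note_id]):
                fh.write(f"{note_id}\t{term}\n")


def write_candidates(candidates: Sequence[CandidateTerm], path: str | Path) -> None:
    """Dump candidates to TSV for inspection or staged pipelines."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("note_id\tterm\tlabel\tfirst_token_index\tn_occurrences\tsemantic_type\n")
        for c in candidates:
            label = "" if c.label is None else str(c.label)
            fh.write(
                f"{c.note_id}\t{c.canonical_term}\t{label}\t"
                f"{c.first_token_index}\t{c.tf}\t{c.semantic_type}\n"
            )
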