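"""Controlled medical vocabulary: loading, normalisation and indexing.

The lexicon stands in for the UMLS concept dictionary (each entry carries a
coarse semantic type) merged with the consumer health vocabulary (CHV
membership flag plus an optional familiarity score in [0, 1] estimating how
likely a lay reader is to understand the term).

Entries are indexed by their normalised token sequence — lowercased,
possessives stripped, Porter-stemmed — so that dictionary matching is
case- and inflection-insensitive ("Crohn's disease" and "crohn diseases"
share the key ("crohn", "diseas")).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from ._porter import porter_stem

__all__ = [
    "DEFAULT_SEMANTIC_TYPES",
    "LexiconEntry",
    "Lexicon",
    "stem_word",
    "normalize_term",
    "load_lexicon",
    "write_lexicon",
]

#: The eight major clinical topics observed to carry important terms,
#: plus a catch-all. A custom closed set may be passed to the loaders.
DEFAULT_SEMANTIC_TYPES: tuple[str, ...] = (
    "Disease or syndrome",
    "Organic chemical",
    "Finding",
    "Neoplastic process",
    "Therapeutic or preventive procedure",
    "Amino acid, peptide, or protein",
    "Pathologic function",
    "Diagnostic procedure",
    "other",
)

_POSSESSIVE_RE = re.compile(r"['’]s$|['’]$")
_WORD_RE = re.compile(r"[A-Za-z0-9]+(?:['’][A-Za-z0-9]+)*")


def stem_word(word: str) -> str:
    """Porter stem of a lowercased word; raises on empty input."""
    if not word:
        raise ValueError("stem_word: empty input")
    return porter_stem(word.lower())


def normalize_term(text: str) -> tuple[str, ...]:
    """Normalise a free-text term to its stemmed token-sequence key.

    Splits on whitespace/punctuation (hyphens split), strips possessives,
    lowercases and Porter-stems each token.
    """
    key = []
    for m in _WORD_RE.finditer(text):
        raw = _POSSESSIVE_RE.sub("", m.group(0))
        for piece in re.findall(r"[A-Za-z0-9]+", raw):
            key.append(stem_word(piece))
    return tuple(key)


@dataclass(frozen=True)
class LexiconEntry:
    """One controlled-vocabulary term with its annotations."""

    term: str
    semantic_type: str
    in_chv: bool
    familiarity: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.term.strip():
            raise ValueError("LexiconEntry: empty term")
        if self.familiarity is not None and not 0.0 <= self.familiarity <= 1.0:
            raise ValueError(
                f"LexiconEntry: familiarity {self.familiarity!r} outside [0, 1]"
            )


@dataclass
class Lexicon:
    """An indexed set of :class:`LexiconEntry`.

    ``index`` maps normalised token sequences to entries; ``max_term_words``
    is the length of the longest key and bounds the matcher's scan window.
    """

    entries: list[LexiconEntry] = field(default_factory=list)
    semantic_types: tuple[str, ...] = DEFAULT_SEMANTIC_TYPES
    index: dict[tuple[str, ...], LexiconEntry] = field(default_factory=dict)
    max_term_words: int = 0

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[LexiconEntry],
        semantic_types: Sequence[str] = DEFAULT_SEMANTIC_TYPES,
    ) -> "Lexicon":
        lex = cls(entries=[], semantic_types=tuple(semantic_types))
        seen_terms: set[str] = set()
        for entry in entries:
            if entry.semantic_type not in lex.semantic_types:
                raise ValueError(
                    f"unknown semantic type {entry.semantic_type!r} "
                    f"for term {entry.term!r}"
                )
            if entry.term in seen_terms:
                raise ValueError(f"duplicate canonical term {entry.term!r}")
            key = normalize_term(entry.term)
            if not key:
                raise ValueError(f"term {entry.term!r} normalises to nothing")
            if key in lex.index:
                raise ValueError(
                    f"terms {lex.index[key].term!r} and {entry.term!r} "
                    f"share the normalised key {key!r}"
                )
            seen_terms.add(entry.term)
            lex.entries.append(entry)
            lex.index[key] = entry
            lex.max_term_words = max(lex.max_term_words, len(key))
        return lex

    def lookup(self, tokens: Sequence[str]) -> Optional[LexiconEntry]:
        """Exact match of a stemmed token sequence; no partial matching."""
        if not tokens:
            return None
        return self.index.get(tuple(tokens))

    def __len__(self) -> int:
        return len(self.entries)


def lookup(lexicon: Lexicon, tokens: Sequence[str]) -> Optional[LexiconEntry]:
    return lexicon.lookup(tokens)


_HEADER = ["term", "semantic_type", "in_chv", "familiarity"]


def load_lexicon(
    path: str | Path,
    semantic_types: Sequence[str] = DEFAULT_SEMANTIC_TYPES,
) -> Lexicon:
    """Load a lexicon from a UTF-8 TSV with a header row.

    Columns: term, semantic_type, in_chv (0/1), familiarity (float or "NA").
    Any malformed row raises ``ValueError`` naming the offending line.
    """
    path = Path(path)
    entries: list[LexiconEntry] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise ValueError(f"{path}: expected header {_HEADER}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            term, stype, chv_s, fam_s = fields
            try:
                if chv_s not in ("0", "1"):
                    raise ValueError(f"in_chv must be 0 or 1, got {chv_s!r}")
                fam = None if fam_s == "NA" else float(fam_s)
                entry = LexiconEntry(term, stype, chv_s == "1", fam)
                if entry.semantic_type not in semantic_types:
                    raise ValueError(f"unknown semantic type {stype!r}")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            entries.append(entry)
    try:
        return Lexicon.from_entries(entries, semantic_types)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write the lexicon back to TSV (inverse of :func:`load_lexicon`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for e in lexicon.entries:
            fam = "NA" if e.familiarity is None else repr(e.familiarity)
            fh.write(f"{e.term}\t{e.semantic_type}\t{int(e.in_chv)}\t{fam}\n")
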