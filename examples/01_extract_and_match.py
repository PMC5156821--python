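"""Candidate extraction and relaxed string matching on the sample note.

Loads the packaged sample clinical note and lexicon, runs the greedy
longest-dictionary-match extractor, and shows how the relaxed matcher
treats subsumption versus part-of containment.
"""

import focusrank
from focusrank.evaluation import relaxed_match
from focusrank.extraction import extract_candidates, make_note
from focusrank.lexicon import load_lexicon

lexicon = load_lexicon(focusrank.sample_lexicon_path())
note = make_note("sample", focusrank.sample_note_path().read_text(encoding="utf-8"))

candidates = extract_candidates(note, lexicon)
print(f"{note.word_count} words, {len(candidates)} distinct candidate terms:\n")
for cand in candidates:
    print(f"  {cand.canonical_term:28s} tf={cand.tf}  first_token={cand.first_token_index}")

# term frequency counts every non-overlapping mention of the same concept
crohn = next(c for c in candidates if c.canonical_term == "crohn disease")
print(f"\n'crohn disease' is mentioned {crohn.tf} times in this note.")

# a system term counts as correct if it equals or subsumes a gold term,
# but a fragment of a gold term stays wrong (it is usually too general)
print("\nrelaxed match decisions:")
for system, gold in [
    ("non-Hodgkin lymphoma", "lymphoma"),
    ("disease", "Crohn's disease"),
    ("Crohn disease", "crohn's disease"),
]:
    print(f"  {system!r} vs gold {gold!r}: {relaxed_match(system, gold)}")
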