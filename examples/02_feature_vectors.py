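"""Assembling per-candidate feature vectors.

Builds a two-note toy corpus, computes the baseline + consumer-vocabulary
+ semantic-type blocks for each candidate, and prints one named vector.
"""

import numpy as np

from focusrank.extraction import extract_candidates, make_note
from focusrank.features import (
    BackgroundCorpus,
    FeatureConfig,
    FeatureExtractor,
    FeatureResources,
)
from focusrank.lexicon import Lexicon, LexiconEntry

lexicon = Lexicon.from_entries([
    LexiconEntry("crohn disease", "Disease or syndrome", True, 0.35),
    LexiconEntry("metformin", "Organic chemical", True, 0.40),
    LexiconEntry("pain", "other", True, 0.95),
])
notes = {
    "n1": make_note("n1", "crohn disease with pain treated with metformin"),
    "n2": make_note("n2", "pain persists and crohn disease is stable"),
}
candidates = [c for n in notes.values() for c in extract_candidates(n, lexicon)]

resources = FeatureResources(
    background=BackgroundCorpus([n.stems for n in notes.values()]),
)
config = FeatureConfig(semantic_type=True, chv=True)
config.lexical_min_count = 1
fx = FeatureExtractor(config, resources).fit(candidates, notes)
fm = fx.transform(candidates, notes)

row = fm.rows.index(("n1", "crohn disease"))
vec = np.asarray(fm.X[row].todense()).ravel()
print("feature vector for 'crohn disease' in note n1 (nonzero entries):\n")
for name, value in zip(fm.names, vec):
    if value != 0:
        print(f"  {name:24s} {value:.4f}")
print("\nposition is the fraction of the note preceding the term;")
print("fam_bin2 marks a familiarity score in [0.2, 0.4): consumer-rated unfamiliar.")
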