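"""focusrank: learning-to-rank extraction of patient-important medical
terms from clinical notes.

Pipeline: a dictionary matcher extracts candidate terms from each note, a
feature suite describes them (frequency, structure, position, lexical
identity, POS, word embeddings, semantic type, consumer-vocabulary flags,
topic coherence), and a pairwise rankSVM — or a random-forest baseline —
ranks them by importance to the patient. Evaluation uses relaxed string
match, P/R/F at ranks 5 and 10, and two per-note AUC variants under
10-fold cross-validation. A calibrated synthetic-corpus generator makes
the whole loop runnable and testable without clinical data.
"""

__version__ = "0.1.0"

from .lexicon import Lexicon, LexiconEntry, load_lexicon, stem_word  # noqa: F401
from .extraction import (  # noqa: F401
    Note,
    CandidateTerm,
    extract_candidates,
    label_candidates,
    make_note,
    tokenize,
)
from .features import FeatureConfig, FeatureResources, assemble  # noqa: F401
from .rankers import build_pairs, score_and_rank, train_ranksvm, train_rf  # noqa: F401
from .evaluation import (  # noqa: F401
    EvalReport,
    auc_ke,
    auc_ranking,
    cross_validate,
    paired_t_test,
    prf_at_k,
    relaxed_match,
)
from .experiment import ExperimentConfig, compare_systems, run_experiment  # noqa: F401


def sample_note_path():
    """Path of the packaged sample clinical-note excerpt."""
    from importlib.resources import files

    return files("focusrank") / "data" / "sample_note.txt"


def sample_lexicon_path():
    """Path of the packaged sample lexicon covering the sample note."""
    from importlib.resources import files

    return files("focusrank") / "data" / "sample_lexicon.tsv"
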