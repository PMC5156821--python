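# Methods

## Task and pipeline

Given a clinical note, the system ranks the note's medical terms by their
importance to the patient. Importance is note-specific: the same term can
matter for one patient and be an incidental comorbidity for another, so
the unit of prediction is a (term, note) pair and every evaluation metric
is computed per note and macro-averaged.

The pipeline is: (1) tokenise the note (split on whitespace and
punctuation, hyphens split, possessives stripped, Porter stem attached to
each token); (2) extract candidates by greedy longest dictionary match
over the stemmed token stream against a controlled vocabulary, merging
all occurrences of a canonical term into one candidate; (3) featurise;
(4) rank with a pairwise SVM (or the random-forest baseline); (5) score
against gold annotations with relaxed string match.

The dictionary matcher deliberately replaces a full concept-normalisation
engine: its contract is that extraction recall over gold terms is below
100% and measurable, which is what the extraction-aware AUC needs. Scan
order is maximal munch — at each position the longest lexicon key wins,
the scan resumes after the match, so spans never overlap; equally long
competing matches cannot occur because the index maps each key to one
entry.

## Features

| block | columns | notes |
| --- | --- | --- |
| frequency | tf, idf, tfidf | idf = ln((N+1)/(df+1)) over a background corpus; smoothing keeps out-of-background terms finite |
| structure | TL, maxWL, TL*maxWL | words in term, characters of longest word; the product is monotone in both, matching the intuition that longer terms/words are less familiar |
| position | first-token index / note word count | important terms tend to occur early |
| lexical | one-hot over stemmed term strings seen >= 3 times in training | the count threshold suppresses typos; unseen terms fall into RARE |
| POS | one-hot of the head word's tag | head = final token (English noun phrases are right-headed); a small suffix-rule tagger stands in for a full tagger, with UNK on failure |
| embedding | d columns in [0,1] | mean of member-word vectors, then per-dimension min-max over the table vocabulary; OOV words skipped, all-OOV terms map to 0.5 |
| semantic type | one-hot over a closed set | the eight major clinical topics plus "other" |
| CHV | 7 binaries | membership; five half-open familiarity-score fifths of [0,1] (at most one set); has-score |
| topic | one per K in {50, 100, 200} | coherence P(t|e) from LDA fitted on the background corpus |

Topic coherence combines member words by product (independence
assumption) by default; a geometric-mean combiner is available and is
used by the experiment profile because the product shrinks geometrically
with term length and leaves multi-word terms numerically near zero. For
the same reason the topic columns are min-max rescaled to [0, 1] with
bounds fitted on the training fold — the same treatment the embedding
block receives — since raw word probabilities over a few-thousand-word
vocabulary are ~1e-3 and an l2-regularised linear model cannot use them
at that scale. Rescaling is monotone per column, so within-note orderings
are unchanged.

Fold safety: the lexical vocabulary and the topic min-max bounds are the
only fitted featuriser state and are rebuilt from the training fold in
every cross-validation fold. The POS tagset and semantic-type set are
closed and declared up front; embedding bounds come from the whole table
vocabulary, which is a training-independent resource.

## Ranking

The rankSVM minimises 1/2 ||w||^2 + (C/m) sum hinge(1 - w.(x_i - x_j))
over all within-note (important, nonimportant) pairs. It is solved by
liblinear (hinge loss, no intercept) on the pair difference vectors,
each included with both signs and per-sample cost C/(2m), which
reproduces the objective exactly; the tests verify the trained objective
against exhaustive grid search on small instances. C defaults to 100 in
the experiment profile — the value selected by the package's own
`select_C` (3-fold inner CV maximising mean per-note AUC over the grid
{0.01, 0.1, 1, 10, 100}) on the default synthetic corpus. Ranking is
invariant to positive rescaling of w; ties are broken by earlier first
occurrence, then lexicographic term order, so output is deterministic
under input permutation.

The random-forest baseline consumes the identical feature matrix; its
score is the tree-averaged positive fraction of the assigned leaves, and
the tree count B minimises out-of-bag error over a grid.

## Evaluation

Relaxed string match normalises both terms (lowercase, possessive strip,
Porter stems) and credits equality or the gold sequence occurring
contiguously inside the system term; the reverse containment does not
count, because a fragment of an important term is usually too general.
P@k divides by k (not by min(k, list length)); each gold term can be
credited once per list, so duplicated system terms cannot double-count;
notes with an empty gold set are skipped and reported. AUC counts
(positive, negative) score pairs with ties at 1/2 (trapezoidal ROC area);
single-class notes are skipped and reported. The extraction-aware variant
appends each missed gold term as a phantom positive strictly below all
candidates, which factorises as auc_ranking * found/(found+missed) in the
absence of ties. System comparisons use two-sided paired t tests over
per-note metrics; a zero-variance difference vector is reported as p = 1
(identical) or p = 0 with a degeneracy flag.

## Synthetic corpus generator

The generator reproduces the reference corpus profile: 90 notes, words
per note ~ N(816, 133) truncated at 100; distinct planted terms per note
~ N(250, 42); gold terms per note ~ N(9, 5) truncated at >= 1 (the
pre-truncation location is solved so the truncated mean still equals 9);
89% / 76% consumer-vocabulary coverage among important / nonimportant
candidates; extraction recall 0.89. The lexicon is 2 000 pseudo-terms of
1-4 pronounceable words, each word unique to its term at the stem level
so dictionary matches in generated text are unambiguous; semantic types
follow the observed topic mixture (the eight major topics carrying 75% of
the mass, "other" the rest); 76% of terms are CHV members and 57.9% of
those carry a Beta(2, 2) familiarity score.

Labels are sampled from a logistic model on the term's true features —
relative position (coefficient -7.5), semantic type (+3.75 for diseases
down to -5 for "other"), centred familiarity-bin effects, topic coherence
(+3.75 on the within-note z-score of log theta_topic(term)), CHV
membership, and a +3.75 boost for four designated globally important
terms — with a per-note intercept solved so the expected positive count
matches the drawn gold target. Coefficient magnitudes were chosen so the
Bayes-optimal within-note ranking (scoring by the true label
probabilities) attains AUC ~0.95, the regime in which a trained ranker
can plausibly reach the 0.94 reported for this task on real notes; the
per-note intercept is irrelevant to within-note ranking, so it absorbs
all between-note prevalence variation without polluting the signal. The
CHV membership log-odds is calibrated numerically: starting from the
closed-form rare-positive value ln 2.555, the generator bisects the
log-odds (re-solving every per-note intercept each step) until the
expected coverage among important candidates equals 89%; the closed form
alone under-shoots by ~3 points because the other score components
saturate the sigmoid.

Extraction misses are planted structurally: 11% of gold slots become
"modifier + term" phrases with an out-of-lexicon modifier, mirroring how
concept extractors miss multi-word terms with embedded vocabulary
entries — the embedded term is still extracted (and labelled 0, since it
does not subsume the gold phrase) while the full phrase counts as a miss.

Topic structure: six latent topics (matching the six primary diagnoses
the reference notes were drawn from); each term's primary topic is a
stable hash of its string, shared by the note generator and the
background-corpus generator, and notes/background documents draw
Dirichlet(0.5) topic mixtures over term and filler words. The background
corpus (200 documents, ~300 words) feeds both IDF and the LDA fits.

What the generator does *not* emulate: real clinical prose (notes are
shuffled term/filler token streams), sentence structure, abbreviations,
misspellings, polysemy, and any semantic relation between embedding
vectors and meaning beyond the semantic-type centroids. Passing tests
therefore demonstrate that the pipeline recovers a planted feature-based
importance signal at realistic corpus scale — not clinical performance.

## Experiment scale and defaults

The default experiment profile uses the full 90-note corpus, the paper-
scale topic profile K = {50, 100, 200}, and a 50-dimensional synthetic
embedding table (the embedding generator itself defaults to d = 200;
50 keeps the full 10-fold CV around four minutes on one CPU, and the
planted signal does not live in the embedding block). C selection runs
once up front rather than per fold. On this configuration the
full-feature rankSVM reaches macro auc_ranking ~0.92 under 10-fold CV
and beats the baseline-feature system on every metric (paired t,
p < 1e-8).

## Numerical choices and degenerate inputs

- IDF smoothing ln((N+1)/(df+1)); df of a multi-word term counts
  documents containing its stemmed sequence contiguously.
- Topic feature floor 1e-9 for out-of-vocabulary words keeps P(t|e)
  strictly inside (0, 1).
- liblinear tolerance 1e-8, max 200 000 iterations, fixed random_state;
  all fold assignments and generator stages derive from explicit seeds.
- Notes with no positive (or no negative) candidates are excluded from
  AUC averaging; notes with empty gold sets from P/R/F; both are listed
  in the report's `skipped` field.
- An infeasible generator profile (candidate words exceeding the note
  length even after shrinking to the 10-candidate floor) raises rather
  than silently degrading.

## Known limitations

- The stand-in POS tagger is a suffix heuristic; on real text a proper
  tagger should be injected via `FeatureResources.pos_tagger`.
- The rank evaluator assumes gold annotations are term strings; span
  -level credit (same string, different mention) is not modelled.
- The staged CLI's `featurize`/`train` path fits the featuriser on all
  candidates it is given (single-model mode); leakage-safe ablations
  should go through `focusrank run`, which refits per fold.
- `auc_ke` assumes missed gold terms would rank strictly last; if a
  deployed system interleaved them, the metric would be optimistic.
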