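# Methods

## Problem setting

Biomedical event extraction in the GENIA style proceeds in two
classification phases.  *Trigger detection* assigns every token one of ten
labels: nine event classes (gene expression, transcription, protein
catabolism, localization, binding, phosphorylation, regulation, positive
regulation, negative regulation) or negative.  *Edge detection* labels
ordered (trigger, entity) pairs as Theme, Cause, or negative.  Features for
both phases are organised into classes — six for triggers (sentence, main,
linear order, content, attached edge, chain), seven for edges (entity, path
length, single element, path grams, path edge, sentence, GENIA; the
terminus-token class is absorbed into the entity class) — and the package
quantifies how much each class contributes.

## Accumulated effect evaluation

All 2^n − 1 nonempty class subsets are evaluated (train on the training
split, F-score on the development split) and ranked best-first.  For the
prefix of the top j subsets, O_ij counts those containing class i, and
T_j = Σ_i O_ij.  Then

    AEE1(i) = Σ_j O_ij / j,        AEE2(i) = Σ_j O_ij / T_j.

AEE1 is the summed prefix occurrence *rate*; it is maximised (closed form
below) when every subset containing i outranks every subset that does not.
AEE2 replaces the prefix rank by the prefix's total class count, which
penalises classes that only appear inside large subsets: each AEE2 column
sums to one, so Σ_i AEE2(i) equals the ranking length J exactly — a useful
internal consistency check (63 for a complete 6-class ranking).

Both scores are comparative, not normalised to [0,1]; they are therefore
reported together with theoretical bounds for the same n.

### Bounds

For AEE1 the extremal orderings are obvious and give the closed form

    Max = 2^(n−1) + Σ_{j=2^(n−1)+1}^{2^n−1} 2^(n−1)/j
    Min = Σ_{k=1}^{2^(n−1)} k/(2^(n−1)−1+k).

For AEE2 the extremes also depend on *where the large subsets sit*, because
the denominator is the cumulative subset size.  The package uses a
constructive arrangement: for the maximum, the 2^(n−1) subsets containing
the focal class first in ascending size order, then the remainder ascending;
for the minimum, the non-containing subsets first, then the containing ones
in descending size order.  Ascending size keeps the denominators small
while the focal counts accrue (and the ordering of equal-sized subsets is
irrelevant to the focal score, which depends only on prefix sizes and
membership counts).  The construction is certified in the test suite by
exhaustive search over all permutations of the subset lattice at n = 2
(3! orderings) and n = 3 (7! = 5040 orderings); both bounds agree to
machine precision.

Incomplete rankings (an evaluator may fail on some subsets) are scored over
their actual length J; the normalisation Σ AEE2 = J still holds, but the
tabulated bounds refer to complete rankings, so reports carry a warning in
that case.

### Greedy refinement

The refinement loop is hill climbing with AEE as the objective's guide: the
best- and worst-scoring classes (AEE1, ties broken by AEE2) are looked up
in a catalogue of modified variants (4′ adds character 4-grams to the
content class; 6′ merges the attached-edge and chain namespaces; 2′ adds a
binned path length; 7′ adds a POS bag of words), the substitutions are
applied, and the combination experiment is re-run with everything else
fixed.  A round is kept only if the best F-score improves, so accepted
refinements are monotone by construction; the loop stops at the first
non-improving round.

## Detection harness

The learner is a pluggable contract (fit on labelled feature multisets,
emit per-class scores).  The shipped implementation is one-vs-rest
logistic regression (scikit-learn) over sparse count vectors, with the
regularisation constant C exposed.  Class *probabilities* are used as
scores: they are strictly positive, which makes the precision–recall
trade-off well behaved — at prediction time the negative-class score is
multiplied by β (> 0, default 0.6) before the argmax, so the predicted
trigger count is non-increasing in β for any fixed scored corpus.  β
applies to trigger detection only; edge detection is a plain argmax.  Ties
break by a fixed label order with the negative class last.

Evaluation is instance-level precision/recall/F over positively labelled
instances (a hit requires the same instance and the same label).  An empty
retrieved set yields precision 0 and is flagged.  The shared-task
"approximate span and recursive" matching needs the official tooling and is
not implemented.

For the 63-subset sweep, features are extracted and vectorised once per
class (vocabularies fitted on the training split only) and each subset is
evaluated by stacking the cached sparse blocks and fitting one classifier —
the sweep over a ~200-sentence corpus takes seconds per subset on one core.

## Corpus model

Corpora are stand-off XML: documents → sentences → tokens (surface, POS,
0-based half-open character offsets), directed dependency edges (governor →
dependent), entities anchored to head tokens (given proteins vs. predicted
triggers), and typed interactions.  The directed dependency graph must be
acyclic (validated at parse time); shortest-dependency-path queries use the
undirected view, retaining a per-step direction flag for feature strings.
Ties among equal-length paths break to the lexicographically smallest
token-index sequence; disconnected queries return an explicit no-path
value.  Serialisation is deterministic (fixed element and attribute order)
and unknown attributes round-trip.

The Porter stemmer (the classic suffix-stripping algorithm) is implemented
in `aee.stem` and validated against the algorithm's published worked
derivations; the "nonstem" feature is the suffix the stemmer removed.

## Synthetic corpora

The generator emulates the structural skeleton of an annotated event
corpus; the defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| n_documents × sentences/doc | 40 × 5 | ≈ 200 sentences |
| tokens per sentence | 6–12 | uniform |
| event priors | 0.02 × 9 classes | ≈ 18% trigger tokens |
| signal strength s | 0.8 | P(trigger surface contains its class's signature trigram) |
| context word probability | 0.2 | weak sentence-level cue |
| protein probability | 0.15 | given-entity rate among negative tokens |
| vocabulary | 300 words | letters a–y without q/x/z |

Each event class owns a signature character trigram built from letters
excluded from the background vocabulary, inserted at a random position of a
random base word — so bag-of-words and stem features see mostly unique
surfaces while the character 2/3/4-gram content features generalise.  POS
tags give a weak trigger-vs-negative cue (triggers skew verbal), and a
class-specific context word elsewhere in the sentence gives a weak
sentence-level cue.  Dependency trees are random projective trees (each
subtree spans a contiguous interval), built recursively; relations are
uniform over a small label set and carry no class signal.  Theme
interactions link triggers to proteins; Cause interactions are added for
regulation-type triggers.

What the synthetic experiments show: that the pipeline end-to-end —
generation, feature extraction, subset sweep, AEE — recovers the class in
which signal was planted (the content class wins both AEE scores in ≥ 8 of
10 seeded 200-sentence runs at s = 0.8, and detector F collapses to chance
at s = 0).  What they do not show: anything about real biomedical language —
no realistic lexical distributions, no parser noise, no nested events, no
class imbalance beyond the configured priors.  GENIA-scale results (absolute
F-scores, feature inventories of 10^5–10^6) are out of scope.

## Numerical choices and conventions

* Worked-example AEE values are reported to 3 decimals, bounds to 2,
  average contribution (F-score% / feature size) to 5 — matching the
  conventional table precision for these quantities.
* Exact rational arithmetic (`fractions.Fraction`) is used for the AEE1
  closed-form bounds; everything else is float64.
* Feature strings are namespaced `class<id>:<rule>=<value>` so subsets and
  the 6′ merge are plain multiset operations; the linear-order window and
  chain depth default to 3.
* Ranking ties break by F-score descending, then smaller feature size, then
  lexicographic subset — deterministic and biased toward the smaller model,
  consistent with AEE2's size discount.
* All randomness (generation, splits, learner seeds) derives from explicit
  integer seeds; the same configuration and seed reproduce byte-identical
  corpora and reports.

## Known limitations

* The feature-generation rules are faithful in structure (class boundaries,
  rule families, variants) but not guaranteed to match any production
  system's exact feature spellings or counts.
* The constructive AEE2 bound is certified exhaustively only at n ≤ 3;
  for larger n it is supported by the property sweep (no sampled ranking
  has ever exceeded it) but not proven.
* Edge detection on synthetic corpora is structurally exercised but its
  class signal is weaker by design; the planted-signal recovery claim is
  made for the trigger phase only.
* The learner is a linear probabilistic classifier; kernel methods used by
  production event extractors are out of scope.
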