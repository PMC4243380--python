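# Methods

## The classification model

An RDE scores a sentence x (Boolean feature vector) against a *reference
feature* r as f(x, r) = Σⱼ (P(r|j) − P(r)) xⱼ. The construction rests on
two assumptions about r: it should be (i) discriminative for the class
label and (ii) close to statistically independent of the other features.
Under those assumptions the weight P(r|j) − P(r) is proportional to the
label signal of feature j as seen through r, so the sum behaves like a
classifier whose per-feature weights were estimated on the unlabeled
corpus — which can be orders of magnitude larger than any labeled set.
Training is nothing but presence counting (N, n_j, n_r, n_jr), is one
pass, and counts from stream partitions merge exactly (`cooc_stats.merge`),
which is what makes very large corpora practical.

The SeRDE pipeline turns this into a supervised learner:

1. **Candidate pool.** All vocabulary features with unlabeled document
   frequency ≥ `min_candidate_freq` (default 100). Reference features must
   be frequent: the joint probabilities of rare candidates cannot be
   estimated reliably, and frequent words also tend to be closer to
   independent of the rest of the vocabulary.
2. **Selection.** Default strategy `bound` ranks candidates ascending by
   (1/|I(r)|) Σⱼ P(j)|P(j,r)/(P(j)P(r)) − 1|, with
   I(r) = P(r,y) − α·P(r,ȳ)·P(r) counted on labeled data (α default 1.0;
   candidates with |I(r)| < 1e−6 are excluded to avoid division blow-up).
   `chi_square` (label association) and `frequency` (unlabeled document
   frequency, needing no labels at all) are alternatives; in practice the
   frequency ranking is surprisingly competitive because frequency itself
   buys both independence and estimation accuracy.
3. **Pruning.** Features whose dependence-ratio deviation
   |P(j,r)/(P(j)P(r)) − 1| exceeds t (default 10.0) are removed from an
   RDE's weight map, since they violate the independence assumption behind
   the weight estimate. The default keeps ≥ 90% of features on the
   synthetic fixture (measured: 100%); the deviation is computed with the
   same smoothing as the weights.
4. **Ensemble.** The k RDE decision scores (k default 200) become the
   feature vector of a meta-classifier — logistic regression by default,
   random forest (500 trees, seeded) as the non-linear option. The
   decision threshold is the F1-maximizing cutoff over the observed
   dev-split scores, never tuned on test data.

All probabilities use add-ε smoothing (ε default 0.5) applied at query
time only; raw counts are stored unsmoothed so merging stays exact.
Setting ε=0 reproduces the unsmoothed estimators and raises on empty
denominators. SuRDE replaces r by the gold label itself with weights
P(y|j) − P(y) counted on labeled data.

When several classifiers are combined, their decision scores are min–max
rescaled to [0, 1] on the dev split before per-example mean combination
(`combine_mean`): logistic margins and forest probabilities live on
incomparable scales, and rank-preserving rescaling is the least committal
way to average them.

## Retrieval and filtering

GORank(s, g) = (|s ∩ g| / √(|s||g|)) · ln count(g) over lowercased token
sets. The true-cosine denominator is the default; a variant dividing by
the raw product |s||g| is available via `sqrt_denominator=False`. The
logarithm base only rescales all scores uniformly; the natural log is
fixed so serialized scores are comparable. Term token bags default to the
term name only — synonym and definition expansion are opt-in because
definition text tends to inject noise into short-query matching.
count(g) counts *distinct* annotation documents (GAF column 6) rather than
annotation rows, matching the reading of "documents related to the term";
terms absent from the GAF are excluded from the index (log 0 is never
taken). Frequency thresholds are strict: `min_count = 2000` keeps terms
with count > 2000. Ties at equal score break toward the higher count,
then the lexicographically smaller GO id.

The hierarchy filter ranks 12 classes per sentence — the 11 level-2 GO
classes (direct is_a children of the three roots) most frequent in the
training annotations, recomputed per corpus, plus OTHER — using per-class
SuRDE scores calibrated by a one-dimensional logistic regression. A
prediction is kept iff one of its level-2 classes falls within the top-n
(n = 12 keeps everything, n = 0 drops everything). A prediction whose
level-2 classes include none of the 11 named ones is treated as OTHER, so
the 12-class scheme stays exhaustive. Classes whose training labels are
single-class fall back to a constant score equal to the class frequency;
score ties break by class frequency.

## Evaluation conventions

All P/R/F1 are micro-averaged; an empty denominator yields 0. Sentence
records are (doc, span, gene): *exact* requires the identical span,
*relaxed* credits any character-span overlap for the same gene (the usual
community convention; the spans come from the splitter's paragraph
offsets). GO records are (doc, gene, term): *hierarchy* mode replaces both
sides by their is_a ancestor closures with the three roots excluded, so a
parent-of-gold prediction earns partial credit. AUC is the Mann–Whitney
statistic with half-credit ties; it is checked in the tests against an
O(n²) pair enumeration and scikit-learn's implementation.

## The synthetic benchmark

The generator (`synthdata`) produces the statistical situation RDE is
designed for, with every parameter known:

* sentence labels from a class prior (default 0.3 — evidence sentences
  are the minority in annotated corpora);
* planted reference words with explicit class conditionals (defaults
  P(r|y)=0.8, P(r|ȳ)=0.2: strongly but not perfectly discriminative);
* a fraction (default 0.3) of the remaining vocabulary *weakly
  informative* — the word's base rate is multiplied in one class and
  divided in the other by a factor drawn log-uniformly from [1.3, 3.0] —
  and all words mutually independent given the label;
* the rest pure filler, plus one gene name per sentence from a generated
  lexicon.

Word base rates are Zipf(1.1) over a 1000-word vocabulary, scaled to a
mean sentence length of 12 tokens and floored at 0.004. The floor matters:
words rarer than that can neither enter a 500-sentence vocabulary reliably
nor have their co-occurrences estimated from a 10⁵-sentence stream, so
placing label signal below it creates a benchmark no estimator could pass
— an artifact of the fixture, not a property of the method. Train, dev,
test and unlabeled splits are drawn i.i.d. from a single parameter draw;
re-drawing parameters under a different seed defines a *different* task.

The toy ontology has the GO shape that the hierarchy code exercises: 3
namespace roots, 15 level-2 terms (5 per root), leaves below (one in ten
with two level-2 parents), names sampled from the corpus vocabulary, and
per-term annotation counts from a discrete power law (tail exponent 2.0,
x_min 2) mirroring the heavy-tailed term usage in real annotation
databases. `gen_annotated_sentences` embeds a gold term's name tokens in
noise, giving retrieval and filtering benchmarks a known answer.

What passing these benchmarks shows: the estimators recover planted
signal, the selection ranking finds good references, more unlabeled data
and wider ensembles help, and the filter trades recall for precision as
designed. What it does not show: performance on real biomedical prose —
the generator has no syntax, no multi-word entities, no annotation noise,
no section structure, and conditional independence given the label is an
idealization real text violates.

## Problem sizes and numerical choices

The shipped benchmarks use 500 labeled / 250 dev / 1000 test sentences,
unlabeled streams up to 10⁵, a 1000-word vocabulary and 5 seeds; the full
acceptance script runs in about a minute on one CPU, and results are
bit-reproducible given the seed. Degenerate inputs are contracts, not
accidents: single-class training data raises, empty feature vectors score
0, empty retrieval queries raise, an empty index retrieves nothing, and
k larger than the scored candidate pool raises in `select_references`
(the high-level `fit_serde` instead shrinks k, so one configuration can
sweep unlabeled-corpus sizes whose candidate pools differ).

## Known limitations

* Dictionary gene matching only — no statistical NER or cross-species
  normalization; whole-token, case-insensitive matching is the contract.
* I(r) is implemented exactly as defined (a joint times a marginal in the
  penalty term); its α is corpus-dependent and the default 1.0 is a
  convention.
* Step-3 pruning removes the *most* reference-dependent features, which
  are also the strongest co-occurrence signals; the default t is therefore
  permissive.
* Retrieval is a linear scan over the index — appropriate for desk-scale
  ontologies, not engineered for speed.
* The level-2 class inventory is recomputed from whatever training
  annotations are supplied; with fewer than 11 represented classes the
  bank refuses to train rather than silently shrinking.
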