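# Methods

## Problem and model

`standfood` standardizes short English food-item names against a coded food
vocabulary in which every entry carries a name, a food-chain category
(raw `r`, derivative `d`, simple composite `s`, aggregated composite `c`)
and a code of the form `BASE#Fgg.TERM$Fgg.TERM$…` (a mandatory base term,
then facet descriptors). Three cooperating components produce, for each
query name, a category, the most relevant coded vocabulary entries, and a
rule-corrected final category.

### Classification

Names are lowercased, stripped of punctuation and digits, tokenized on
whitespace and Porter-stemmed; the document-term count matrix keeps a term
only if its document frequency strictly exceeds `sparsity_threshold`
(default 0.01) times the corpus size. Food names are so short that this
filter is the only feature selection needed. Four engineered columns are
appended: the number of noun, adjective and verb tokens in the name and
the name's token length — nouns indicate composite foods, adjectives and
verbs indicate state and preparation (hence derivatives/composites), and
longer names lean the same way. "Length" is measured in tokens rather than
characters so that the feature is insensitive to word length and naming
style.

Four classifier families are trained on the identical matrix and vote:
linear SVM (`LinearSVC`), random forest, gradient-boosted trees (the
boosting family) and multinomial logistic regression (the maximum-entropy
family). Library defaults are used throughout — the contribution is the
feature design and the combination, not tuned hyperparameters. The
plurality label wins; ties (2–2 or 1–1–1–1) are broken by a fixed member
priority, maxent > random forest > SVM > boosting, the descending order of
the members' typical single-model accuracy on this task. All stochastic
components (forest and boosting seeds, fold shuffling) derive from one
user-supplied seed.

Evaluation follows the standard one-vs-rest contingency form: per category,
precision TP/(TP+FP), recall TP/(TP+FN), accuracy (TP+TN)/(TP+TN+FP+FN). A
metric with a zero denominator is reported as undefined (`None`), never as
0. Cross-validation is k-fold (default k = 10) with stratification by
category whenever every class has at least k members — the class mix is
heavily skewed, and unstratified folds can lose a class entirely — falling
back to a plain shuffled split for tiny corpora (e.g. leave-one-out, where
stratification is impossible by counting).

### Description

Both the query and every vocabulary name are POS-tagged and lemmatized
into noun/adjective/verb lemma sets; vocabulary term sets are computed once
at fit time and indexed by noun lemma. Retrieval returns every entry
sharing at least one noun lemma with the query (lemma equality, not
substring match — both sides are normalized the same way). Each candidate
is scored with

    P(X) = P(N) · P(A+V),
    P(N)   = |N₁∩N₂| / |N₁∪N₂|,
    P(A+V) = (|(A₁∪V₁)∩(A₂∪V₂)|+1) / (|(A₁∪V₁)∪(A₂∪V₂)|+2).

Adjectives and verbs are pooled before comparison so inflectional variants
with one meaning ("dry"/"dried", "brown"/"browned") match after
lemmatization, and the add-one (Laplace) estimate keeps a candidate alive
when only one side states the descriptive detail. Numerically the
components are computed as exact rational numbers and converted to float
once at the end, so printed reference values like 0.4 = (3/5)·(2/3) are
reproduced exactly rather than to rounding. P(N) is defined as 0 when both
noun sets are empty (Jaccard is 0/0 there; retrieval already requires a
shared noun, so this arises only on direct similarity calls). All
candidates tied at the maximal weight are returned, sorted by name for
determinism: the system is semi-automatic and the user arbitrates genuine
ties. An empty result means the food is absent from the vocabulary;
composing new codes for such foods is out of scope.

### Correction rules

Exactly one of four rules fires per query, given the predicted category,
the query's term sets and the category of the best match (the
lexicographically first tied match when there are several):

1. predicted `r` and the adjective∪verb lemmas intersect the process
   lexicon → `d`;
2. predicted `r` or `d` and the match is `s` or `c` → the match category;
3. predicted `s`, match `c` → `c`;
4. predicted `c`, match `s` → `s`.

Rules 2–4 are evaluated before rule 1: when a raw-classified name has both
a process verb and a composite match, the match's composite evidence
dominates the r→d promotion. The rules are idempotent under a fixed match
category. The process lexicon (nature-changing processes: canning,
smoking, frying, baking, …) ships as an editable plain-text file, one
lemma per line, and can be replaced wholesale with an official process
list via `--process-lexicon`.

## Linguistic layer

The package carries its own linguistic primitives, all deterministic:

* **Stemming** — the classic Porter algorithm (steps 1a–5b of the original
  formulation), chosen because its outputs ("dried" → "dri", "fruits" →
  "fruit") are the forms the document-term matrix is defined over.
* **POS tagging** — a lexicon + suffix-rule tagger emitting coarse Penn
  tags (NN/JJ/VB/X). Food names are short noun phrases, not sentences;
  a closed-class word list, a food-adjective lexicon, -ed/-ing participle
  rules with noun exception lists, and a default-to-noun fallback tag them
  reliably and reproducibly. The tagger sits behind a one-method interface
  (`tag(tokens)`) so any Penn-tagset tagger can be swapped in.
* **Lemmatization** — irregular tables plus suffix rules for noun plurals;
  for verbs, stripped candidates ("smoked" → smoke/smok/…) are checked
  against a lexicon of cooking and preservation verbs before generic
  un-doubling rules apply, which resolves "canned" → can while keeping
  "filled" → fill.
* A small stoplist {etc, e.g., i.e., similar, and, or} is applied after
  tagging; filler tokens like "etc" carry no topical content, and counting
  them as nouns would distort the noun-set Jaccard of otherwise close
  pairs.

Tagging runs on the lowercased original name; the document-term path
strips punctuation and digits first. The two paths are deliberately
separate.

## Synthetic vocabularies

The real coded vocabulary is licensed, so `fixtures.generate_vocabulary`
produces structural stand-ins: 400 records by default at r/d/s/c =
188/132/56/24 (≈47/33/14/6%, the skew of a real coded food list at desk
scale), with grammar-valid synthetic codes. Name patterns follow how the
categories read in practice — raw commodities are bare commodity nouns,
derivatives always contain a nature-changing participle (so correction
rule 1 is exercisable on any derivative misread as raw), simple composites
are two-word preparations, aggregated composites are dish names.
Generation is a pure function of the seeded spec.

What the fixtures do *not* emulate: the term hierarchy behind real codes,
implicit facets, translation noise, synonym drift ("tinned" vs "canned" as
category-bearing features), or names absent from the vocabulary. Fixture
names are built to be nearly separable by their term features, so the
classifier's cross-validated accuracy on them (mean 0.965–0.980 across
seeds at k = 10) characterizes the pipeline's correctness, not its
accuracy on real coded data; the frozen regression bound in the test suite
is 0.85, about 0.10 below the worst observed run, so that seed and
estimator-version jitter do not trip it. Metrics on real vocabularies must
be established on the real data.

## Numerical and design choices

* Similarity arithmetic is exact (`fractions.Fraction`) until the final
  float conversion.
* The sparsity filter retains a term iff document frequency > threshold×N
  (strict, matching "appears in at most 1% … removed" read literally).
* Code parsing accepts both the canonical `#` dialect and the bare-`$`
  dialect seen in circulating code strings; serialization always emits the
  canonical form. Facet order is preserved; duplicate facet groups are
  legal.
* Vote ties, match ties and fold assignment are all deterministic given
  the seed; repeated runs are bit-identical.
* Problem sizes in the test suite (120-record corpora for ensemble tests,
  400 for the cross-validation regression check, 50 random fixtures for
  the retrieval oracle) are desk-scale stand-ins chosen to exercise every
  code path while keeping the suite fast.

## Known limitations

* The rule tagger defaults unknown open-class words to nouns; rare
  adjectives outside its lexicon ("lyonnais") are counted as nouns, which
  perturbs P(N) slightly for such names.
* Single-letter tokens are discarded as non-content, so constructions like
  "vitamin C" lose the letter.
* Non-English names, spelling correction and multi-word expressions are
  out of scope; queries are assumed to be English food noun phrases.
* Foods absent from the vocabulary yield an empty description by design;
  proposing new codes for them is future work, not a failure mode.
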