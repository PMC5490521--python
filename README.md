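# standfood

Semi-automatic standardization of free-text food-item names against a coded
food vocabulary (FoodEx2-style codes). Food composition and food consumption
datasets can only be linked once every food is classified and coded, and
doing that by hand is slow and demands expert knowledge of the coding
system. `standfood` automates the bulk of it and leaves the final choice to
the user, in three stages:

1. **Classification.** A majority-vote ensemble — linear SVM, random forest,
   gradient boosting and maximum-entropy (multinomial logistic) — assigns
   each name one of the four food-chain categories: raw commodity (`r`),
   derivative (`d`), simple composite (`s`), aggregated composite (`c`).
   Features are a document-term matrix over Porter stems of the
   preprocessed names (terms in at most 1% of documents are dropped) plus
   four engineered features: the counts of nouns, adjectives and verbs in
   the name, and its token length.
2. **Description.** The query name is POS-tagged and lemmatized into noun,
   adjective and verb sets *N₁*, *A₁*, *V₁*; every vocabulary entry sharing
   a noun lemma is retrieved and scored with the probability of a joint
   similarity event

   ```
   P(X) = P(N) · P(A+V)
   P(N)   = |N₁ ∩ N₂| / |N₁ ∪ N₂|                       (Jaccard)
   P(A+V) = (|(A₁∪V₁) ∩ (A₂∪V₂)| + 1) / (|(A₁∪V₁) ∪ (A₂∪V₂)| + 2)
   ```

   — the noun-set Jaccard index times an add-one-smoothed Jaccard of the
   pooled adjective/verb lemma sets. Pooling makes "dried apples" match
   "apple dry"; the smoothing keeps candidates alive when one side omits
   the descriptive detail. All entries tied at the top weight are returned
   with their codes; the user picks when there is more than one.
3. **Correction.** Four rules reconcile the two results: a raw-classified
   name whose adjective/verb lemmas contain a nature-changing process
   (canning, smoking, frying, baking, …) becomes a derivative; an `r`/`d`
   prediction with a composite best match takes the match's category; and
   `s`↔`c` disagreements with the match are resolved in the match's favour.

The real coded vocabulary is licensed, so the package ships a seeded
generator of structurally faithful synthetic vocabularies (category mix
skewed r > d > s > c) that powers the examples and the test suite.

## Worked example

```python
import standfood as sf

q = sf.extract_term_sets("dried vine fruits (currants, raisins and sultanas)")
c = sf.extract_term_sets("dried vine fruits (raisins etc.)")
print(q.nouns, q.verbs)
print(sf.similarity(q, c))
```

prints

```
frozenset({'vine', 'raisin', 'fruit', 'currant', 'sultana'}) frozenset({'dry'})
(0.6, 0.6666666666666666, 0.4)
```

The query and candidate share 3 of 5 noun lemmas (P(N) = 3/5) and both
carry the verb lemma *dry* (P(A+V) = (1+1)/(1+2) = 2/3), so the match
weight is 0.4. An identical name with no adjectives or verbs scores
1 × (0+1)/(0+2) = 0.5 — the smoothing never certifies a perfect match.

The full pipeline on a synthetic vocabulary:

```python
vocab = sf.generate_vocabulary(seed=7)          # 400 labeled, coded records
pipe = sf.FoodStandardizer(random_state=7).fit(vocab)
for res in pipe.standardize(["boiled cabbage", "mushroom soup"]):
    print(res.name, res.predicted_category, res.final_category,
          res.best_match.record.name, res.weight)
```

```
boiled cabbage d d cabbage 0.3333333333333333
mushroom soup c c mushroom 0.25
```

The same flow is available from the shell:

```sh
standfood make-fixture --seed 7 --out vocab.csv
standfood train --data vocab.csv --seed 7 --out model.bin
standfood classify --model model.bin --in queries.txt
standfood describe --vocab vocab.csv --in queries.txt --out matches.csv
standfood standardize --vocab vocab.csv --in queries.txt --seed 7
```

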