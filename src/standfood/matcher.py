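"""Describe food items by probabilistic lemma-set similarity.

A query name and a vocabulary name are each reduced to three lemma sets
(nouns N, adjectives A, verbs V). Vocabulary entries sharing at least one
noun lemma with the query are retrieved, and each retrieved candidate is
scored with the probability of a joint similarity event

    P(X) = P(N) * P(A+V)

where ``P(N)`` is the Jaccard index of the two noun sets and ``P(A+V)`` is
an add-one (Laplace) smoothed Jaccard of the pooled adjective∪verb sets:

    P(N)   = |N1 ∩ N2| / |N1 ∪ N2|
    P(A+V) = (|(A1∪V1) ∩ (A2∪V2)| + 1) / (|(A1∪V1) ∪ (A2∪V2)| + 2)

Pooling adjectives with verbs lets inflectional variants with the same
meaning ("dry" / "dried", "brown" / "browned") match after lemmatization;
the smoothing keeps a candidate alive when one side simply omits the
adjective/verb detail. The highest-weight candidates are the description:
a name identical to the query scores 0.5 when it has no adjectives or
verbs — smoothing never yields certainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from sklearn.base import BaseEstimator

from .lang import Tagger
from .records import FoodRecord
from .textproc import TermSets, extract_term_sets

__all__ = ["FoodMatcher", "MatchResult", "describe", "retrieve_candidates", "similarity"]


@dataclass(frozen=True)
class MatchResult:
    """A scored candidate: the vocabulary record and its weight components."""

    record: FoodRecord
    p_nouns: float
    p_adj_verb: float
    weight: float


def similarity(query: TermSets, candidate: TermSets) -> tuple[float, float, float]:
    """Return ``(p_nouns, p_adj_verb, weight)`` for two term-set bundles.

    ``p_nouns`` is defined as 0 when both noun sets are empty (no topical
    evidence either way); retrieval already guarantees a shared noun on the
    normal path, so that convention only shows on direct calls.
    """
    n1, n2 = query.nouns, candidate.nouns
    union = n1 | n2
    if union:
        p_nouns = Fraction(len(n1 & n2), len(union))
    else:
        p_nouns = Fraction(0)
    av1 = query.adjectives_and_verbs
    av2 = candidate.adjectives_and_verbs
    p_adj_verb = Fraction(len(av1 & av2) + 1, len(av1 | av2) + 2)
    weight = p_nouns * p_adj_verb
    return float(p_nouns), float(p_adj_verb), float(weight)


def retrieve_candidates(
    query_sets: TermSets,
    vocabulary: Sequence[FoodRecord],
    vocabulary_sets: Sequence[TermSets] | None = None,
    tagger: Tagger | None = None,
) -> list[FoodRecord]:
    """All vocabulary entries whose noun lemmas intersect the query's.

    An empty query noun set retrieves nothing.
    """
    if not query_sets.nouns:
        return []
    if vocabulary_sets is None:
        vocabulary_sets = [extract_term_sets(rec.name, tagger) for rec in vocabulary]
    return [
        rec
        for rec, sets in zip(vocabulary, vocabulary_sets)
        if query_sets.nouns & sets.nouns
    ]


class FoodMatcher(BaseEstimator):
    """Vocabulary-backed description engine.

    ``fit`` extracts and caches the term sets of every vocabulary entry once;
    ``describe`` then retrieves, scores and returns every candidate tied at
    the maximal weight (the system is semi-automatic: when several entries
    are equally relevant, all are surfaced and the user picks), sorted by
    candidate name for determinism. An empty result signals a food absent
    from the vocabulary.
    """

    def __init__(self, tagger: Tagger | None = None):
        self.tagger = tagger

    def fit(self, vocabulary: Sequence[FoodRecord], y: None = None) -> "FoodMatcher":
        if not vocabulary:
            raise ValueError("vocabulary must be non-empty")
        self.vocabulary_ = list(vocabulary)
        self.term_sets_ = [
            extract_term_sets(rec.name, self.tagger) for rec in self.vocabulary_
        ]
        # inverted noun-lemma index for retrieval
        index: dict[str, list[int]] = {}
        for i, sets in enumerate(self.term_sets_):
            for noun in sets.nouns:
                index.setdefault(noun, []).append(i)
        self.noun_index_ = index
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "vocabulary_"):
            raise ValueError("FoodMatcher is not fitted; call fit(vocabulary) first")

    def retrieve(self, query_sets: TermSets) -> list[FoodRecord]:
        """Candidates sharing at least one noun lemma with the query."""
        self._check_fitted()
        hits: set[int] = set()
        for noun in query_sets.nouns:
            hits.update(self.noun_index_.get(noun, ()))
        return [self.vocabulary_[i] for i in sorted(hits)]

    def score_all(self, query_sets: TermSets) -> list[MatchResult]:
        """Every retrieved candidate with its similarity weight, unsorted."""
        self._check_fitted()
        hits: set[int] = set()
        for noun in query_sets.nouns:
            hits.update(self.noun_index_.get(noun, ()))
        results = []
        for i in sorted(hits):
            p_n, p_av, w = similarity(query_sets, self.term_sets_[i])
            results.append(MatchResult(self.vocabulary_[i], p_n, p_av, w))
        return results

    def describe(self, query_name: str) -> list[MatchResult]:
        """All candidates tied at the maximal weight, sorted by name."""
        query_sets = extract_term_sets(query_name, self.tagger)
        scored = self.score_all(query_sets)
        if not scored:
            return []
        top = max(r.weight for r in scored)
        best = [r for r in scored if r.weight == top]
        return sorted(best, key=lambda r: r.record.name)


def describe(query_name: str, vocabulary: Sequence[FoodRecord]) -> list[MatchResult]:
    """One-shot description of a name against a vocabulary."""
    return FoodMatcher().fit(vocabulary).describe(query_name)
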