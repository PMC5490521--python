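"""End-to-end standardization: classify, describe, correct.

:class:`FoodStandardizer` wires the three stages together: the ensemble
classifier proposes a category, the matcher finds the most relevant
vocabulary entries, and the post-processing rules reconcile the two. When
several matches tie at the top weight, the lexicographically first one
supplies the category used by the rules (all ties are still reported for
the user to choose from — the system is semi-automatic by design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from sklearn.base import BaseEstimator

from .classifier import FoodCategoryClassifier
from .lang import Tagger
from .matcher import FoodMatcher, MatchResult
from .postprocess import ProcessLexicon, apply_rules, default_process_lexicon
from .records import FoodRecord
from .textproc import extract_term_sets

__all__ = ["FoodStandardizer", "StandardizedFood"]


@dataclass(frozen=True)
class StandardizedFood:
    """The full result for one query name."""

    name: str
    predicted_category: str
    final_category: str
    matches: tuple[MatchResult, ...]

    @property
    def best_match(self) -> MatchResult | None:
        return self.matches[0] if self.matches else None

    @property
    def weight(self) -> float | None:
        return self.matches[0].weight if self.matches else None


class FoodStandardizer(BaseEstimator):
    """Fit on a labeled, coded vocabulary; standardize new names."""

    def __init__(
        self,
        sparsity_threshold: float = 0.01,
        random_state: int | None = None,
        lexicon: ProcessLexicon | None = None,
        tagger: Tagger | None = None,
    ):
        self.sparsity_threshold = sparsity_threshold
        self.random_state = random_state
        self.lexicon = lexicon
        self.tagger = tagger

    def fit(self, vocabulary: Sequence[FoodRecord], y: None = None) -> "FoodStandardizer":
        if any(r.category is None for r in vocabulary):
            raise ValueError("every vocabulary record needs a category")
        self.classifier_ = FoodCategoryClassifier(
            sparsity_threshold=self.sparsity_threshold,
            random_state=self.random_state,
            tagger=self.tagger,
        ).fit([r.name for r in vocabulary], [r.category for r in vocabulary])
        self.matcher_ = FoodMatcher(tagger=self.tagger).fit(vocabulary)
        self.lexicon_ = self.lexicon if self.lexicon is not None else default_process_lexicon()
        return self

    def standardize(self, names: Sequence[str]) -> list[StandardizedFood]:
        predicted = self.classifier_.predict(list(names))
        results = []
        for name, pred in zip(names, predicted):
            matches = tuple(self.matcher_.describe(name))
            match_category = matches[0].record.category if matches else None
            final = apply_rules(
                extract_term_sets(name, self.tagger), pred, match_category, self.lexicon_
            )
            results.append(StandardizedFood(name, pred, final, matches))
        return results
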