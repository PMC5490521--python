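"""Category classification of food names (r / d / s / c).

The feature space is a document-term matrix over Porter stems of the
preprocessed names — terms occurring in at most a fraction
``sparsity_threshold`` of the documents are dropped — augmented with four
engineered columns: the number of nouns, adjectives and verbs in the name
and the name's token length. Nouns carry most of the information (more
nouns suggests a composite food); adjectives and verbs mostly describe
state and preparation, pointing to derivatives and composites, as do
longer names.

Four classifier families vote on each prediction: a linear support-vector
machine, a random forest, gradient-boosted trees and a maximum-entropy
(multinomial logistic) model. The plurality label wins; ties are broken by
a fixed priority order over the member classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .lang import Tagger
from .records import CATEGORIES, FoodRecord
from .textproc import count_pos_and_length, preprocess_name, stem, tokenize

__all__ = [
    "CategoryMetrics",
    "ConfusionCounts",
    "EvaluationReport",
    "FoodCategoryClassifier",
    "FoodNameVectorizer",
    "build_feature_matrix",
    "cross_validate",
    "evaluate",
    "train_ensemble",
]

#: Tie-break priority over ensemble members (strongest single model first).
TIE_BREAK_PRIORITY = ("maxent", "random_forest", "svm", "boosting")


def _stemmed_terms(name: str) -> list[str]:
    return [stem(tok) for tok in tokenize(preprocess_name(name))]


class FoodNameVectorizer(BaseEstimator):
    """Document-term counts over stems, plus the four engineered features.

    A term is retained iff its document frequency strictly exceeds
    ``sparsity_threshold`` × number of documents. The transformed matrix has
    ``len(vocabulary_) + 4`` columns; the engineered columns come last in
    the order (n_nouns, n_adjectives, n_verbs, name_length).
    """

    N_ENGINEERED = 4

    def __init__(self, sparsity_threshold: float = 0.01, tagger: Tagger | None = None):
        self.sparsity_threshold = sparsity_threshold
        self.tagger = tagger

    def fit(self, names: Sequence[str], y: None = None) -> "FoodNameVectorizer":
        if len(names) == 0:
            raise ValueError("cannot fit a vectorizer on an empty corpus")
        if not 0 < self.sparsity_threshold < 1:
            raise ValueError("sparsity_threshold must lie strictly between 0 and 1")
        doc_freq: dict[str, int] = {}
        for name in names:
            for term in set(_stemmed_terms(name)):
                doc_freq[term] = doc_freq.get(term, 0) + 1
        cutoff = self.sparsity_threshold * len(names)
        self.vocabulary_ = sorted(t for t, df in doc_freq.items() if df > cutoff)
        self._term_index_ = {t: j for j, t in enumerate(self.vocabulary_)}
        return self

    def transform(self, names: Sequence[str]) -> sp.csr_matrix:
        check_is_fitted(self, "vocabulary_")
        n_terms = len(self.vocabulary_)
        rows: list[int] = []
        cols: list[int] = []
        data: list[int] = []
        engineered = np.zeros((len(names), self.N_ENGINEERED), dtype=np.int64)
        for i, name in enumerate(names):
            for term in _stemmed_terms(name):
                j = self._term_index_.get(term)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    data.append(1)
            engineered[i] = count_pos_and_length(name, self.tagger)
        counts = sp.coo_matrix(
            (data, (rows, cols)), shape=(len(names), n_terms), dtype=np.int64
        ).tocsr()
        counts.sum_duplicates()
        return sp.hstack([counts, sp.csr_matrix(engineered)], format="csr")

    def fit_transform(self, names: Sequence[str], y: None = None) -> sp.csr_matrix:
        return self.fit(names).transform(names)

    def get_feature_names_out(self) -> np.ndarray:
        check_is_fitted(self, "vocabulary_")
        return np.asarray(
            list(self.vocabulary_) + ["n_nouns", "n_adjectives", "n_verbs", "name_length"],
            dtype=object,
        )


def build_feature_matrix(
    records: Sequence[FoodRecord | str], sparsity_threshold: float = 0.01
) -> tuple[sp.csr_matrix, FoodNameVectorizer]:
    """Fit a vectorizer on the records' names and return (matrix, vectorizer)."""
    names = [r.name if isinstance(r, FoodRecord) else r for r in records]
    vectorizer = FoodNameVectorizer(sparsity_threshold=sparsity_threshold)
    return vectorizer.fit_transform(names), vectorizer


class FoodCategoryClassifier(ClassifierMixin, BaseEstimator):
    """Majority-vote ensemble over SVM, random forest, boosting and maxent.

    Scikit-learn estimator over raw name strings: ``fit(names, categories)``
    vectorizes internally and trains all four members on the identical
    feature matrix; ``predict`` lets each member vote and picks the
    plurality label, breaking ties by :data:`TIE_BREAK_PRIORITY`.
    All stochastic components are seeded from ``random_state``.
    """

    def __init__(
        self,
        sparsity_threshold: float = 0.01,
        random_state: int | None = None,
        tagger: Tagger | None = None,
    ):
        self.sparsity_threshold = sparsity_threshold
        self.random_state = random_state
        self.tagger = tagger

    def _make_members(self) -> dict[str, BaseEstimator]:
        seed = self.random_state
        return {
            "svm": LinearSVC(random_state=seed),
            "random_forest": RandomForestClassifier(random_state=seed),
            "boosting": GradientBoostingClassifier(random_state=seed),
            "maxent": LogisticRegression(max_iter=1000, random_state=seed),
        }

    def fit(self, X: Sequence[str], y: Sequence[str]) -> "FoodCategoryClassifier":
        names = list(X)
        labels = np.asarray(y, dtype=object)
        if len(names) != len(labels):
            raise ValueError("X and y must have the same length")
        bad = set(labels) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {sorted(bad)}; expected {CATEGORIES}")
        if len(set(labels)) < 2:
            raise ValueError("training data must contain at least two categories")
        self.vectorizer_ = FoodNameVectorizer(
            sparsity_threshold=self.sparsity_threshold, tagger=self.tagger
        )
        matrix = self.vectorizer_.fit_transform(names)
        self.members_ = self._make_members()
        for member in self.members_.values():
            member.fit(matrix, labels)
        self.classes_ = np.unique(labels)
        return self

    def _member_votes(self, X: Sequence[str]) -> dict[str, np.ndarray]:
        check_is_fitted(self, "members_")
        matrix = self.vectorizer_.transform(list(X))
        return {name: member.predict(matrix) for name, member in self.members_.items()}

    def predict(self, X: Sequence[str]) -> np.ndarray:
        votes = self._member_votes(X)
        n = len(list(X)) if not hasattr(X, "__len__") else len(X)
        out = np.empty(n, dtype=object)
        for i in range(n):
            out[i] = self._resolve_votes({m: votes[m][i] for m in votes})
        return out

    @staticmethod
    def _resolve_votes(votes: Mapping[str, str]) -> str:
        counts: dict[str, int] = {}
        for label in votes.values():
            counts[label] = counts.get(label, 0) + 1
        top = max(counts.values())
        tied = {label for label, c in counts.items() if c == top}
        if len(tied) == 1:
            return next(iter(tied))
        for member in TIE_BREAK_PRIORITY:
            if votes[member] in tied:
                return votes[member]
        raise RuntimeError("unreachable: tie-break priority covers all members")


def train_ensemble(
    records: Sequence[FoodRecord],
    seed: int | None = None,
    sparsity_threshold: float = 0.01,
) -> FoodCategoryClassifier:
    """Fit the four-member ensemble on labeled vocabulary records."""
    names = [r.name for r in records]
    labels = [r.category for r in records]
    if any(lab is None for lab in labels):
        raise ValueError("all training records must carry a category")
    clf = FoodCategoryClassifier(
        sparsity_threshold=sparsity_threshold, random_state=seed
    )
    return clf.fit(names, labels)


# ---------------------------------------------------------------------------
# Evaluation: one-vs-rest confusion counts and the derived metrics.


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest tallies for a single category."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class CategoryMetrics:
    """Precision, recall and one-vs-rest accuracy for one category.

    A metric whose denominator is zero is ``None`` (undefined), never 0.
    """

    counts: ConfusionCounts

    @property
    def precision(self) -> float | None:
        denom = self.counts.tp + self.counts.fp
        return self.counts.tp / denom if denom else None

    @property
    def recall(self) -> float | None:
        denom = self.counts.tp + self.counts.fn
        return self.counts.tp / denom if denom else None

    @property
    def accuracy(self) -> float | None:
        denom = self.counts.total
        return (self.counts.tp + self.counts.tn) / denom if denom else None


@dataclass(frozen=True)
class EvaluationReport:
    per_category: dict[str, CategoryMetrics]
    accuracy: float
    n: int


def confusion_counts(
    y_true: Sequence[str], y_pred: Sequence[str], category: str
) -> ConfusionCounts:
    tp = fp = fn = tn = 0
    for truth, pred in zip(y_true, y_pred, strict=True):
        if pred == category:
            if truth == category:
                tp += 1
            else:
                fp += 1
        else:
            if truth == category:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def evaluate_predictions(
    y_true: Sequence[str], y_pred: Sequence[str]
) -> EvaluationReport:
    """Per-category precision/recall and overall accuracy from label pairs."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true:
        raise ValueError("nothing to evaluate")
    per_category = {
        cat: CategoryMetrics(confusion_counts(y_true, y_pred, cat))
        for cat in CATEGORIES
    }
    correct = sum(t == p for t, p in zip(y_true, y_pred))
    return EvaluationReport(per_category, correct / len(y_true), len(y_true))


def evaluate(
    model: FoodCategoryClassifier, records: Sequence[FoodRecord]
) -> EvaluationReport:
    """Score a fitted model on labeled records."""
    labels = [r.category for r in records]
    if any(lab is None for lab in labels):
        raise ValueError("all evaluation records must carry a category")
    preds = model.predict([r.name for r in records])
    return evaluate_predictions(labels, list(preds))


def cross_validate(
    records: Sequence[FoodRecord],
    k: int = 10,
    seed: int | None = None,
    sparsity_threshold: float = 0.01,
) -> dict:
    """Stratified k-fold cross-validation of the ensemble.

    Every record lands in a test fold exactly once and in training folds
    k−1 times. Stratification keeps each fold's category mix close to the
    corpus mix, which matters under the heavy r > d > s > c imbalance.
    Returns fold accuracies, their mean, and the out-of-fold predictions.
    """
    n = len(records)
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= {n}, got {k}")
    names = np.asarray([r.name for r in records], dtype=object)
    labels = np.asarray([r.category for r in records], dtype=object)
    if any(lab is None for lab in labels):
        raise ValueError("all records must carry a category")
    # Stratify whenever every class has at least k members; otherwise (tiny
    # corpora, leave-one-out) fall back to a plain shuffled split, where
    # stratification is impossible by counting.
    _, class_counts = np.unique(labels, return_counts=True)
    if class_counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    template = FoodCategoryClassifier(
        sparsity_threshold=sparsity_threshold, random_state=seed
    )
    fold_accuracies = []
    fold_test_indices = []
    oof = np.empty(n, dtype=object)
    for train_idx, test_idx in splitter.split(names, labels):
        model = clone(template).fit(names[train_idx], labels[train_idx])
        preds = model.predict(names[test_idx])
        oof[test_idx] = preds
        fold_accuracies.append(float(np.mean(preds == labels[test_idx])))
        fold_test_indices.append(test_idx.tolist())
    return {
        "fold_accuracies": fold_accuracies,
        "fold_test_indices": fold_test_indices,
        "mean_accuracy": float(np.mean(fold_accuracies)),
        "predictions": list(oof),
    }
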