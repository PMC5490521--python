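import numpy as np
import pytest
from sklearn.metrics import accuracy_score, precision_score, recall_score

from standfood.classifier import (
    FoodCategoryClassifier,
    FoodNameVectorizer,
    build_feature_matrix,
    confusion_counts,
    cross_validate,
    evaluate,
    evaluate_predictions,
    CategoryMetrics,
    ConfusionCounts,
    train_ensemble,
)
from standfood.fixtures import generate_vocabulary
from standfood.records import FoodRecord


class TestVectorizer:
    def test_document_frequency_boundary(self):
        # 100 docs: "flour" in 5 (5% > 1%), "quince" in 1 (1% not > 1%)
        names = (
            ["wheat flour"] * 5 + ["quince"] + ["apple"] * 50 + ["pear"] * 44
        )
        vec = FoodNameVectorizer(sparsity_threshold=0.01).fit(names)
        assert "flour" in vec.vocabulary_
        assert "quinc" not in vec.vocabulary_ and "quince" not in vec.vocabulary_

    def test_stemmed_term_entries(self):
        names = ["dried vine fruits (raisins etc.)"] * 3
        matrix, vec = build_feature_matrix(names, sparsity_threshold=0.01)
        for term in ["dri", "vine", "fruit", "raisin", "etc"]:
            j = vec.vocabulary_.index(term)
            assert matrix[0, j] == 1

    def test_row_sums_match_brute_force_recount(self, small_vocab):
        names = [r.name for r in small_vocab]
        matrix, vec = build_feature_matrix(names)
        retained = set(vec.vocabulary_)
        from standfood.textproc import preprocess_name, stem, tokenize

        for i, name in enumerate(names[:40]):
            stems = [stem(t) for t in tokenize(preprocess_name(name))]
            expected = sum(s in retained for s in stems)
            assert matrix[i, : len(vec.vocabulary_)].sum() == expected

    def test_engineered_columns_appended(self):
        vec = FoodNameVectorizer().fit(["mushroom soup", "apple"])
        X = vec.transform(["mushroom soup"])
        assert X.shape[1] == len(vec.vocabulary_) + 4
        assert X[0, -4:].toarray().tolist() == [[2, 0, 0, 2]]

    def test_vocabulary_order_independent_of_row_order(self, small_vocab):
        names = [r.name for r in small_vocab]
        v1 = FoodNameVectorizer().fit(names)
        v2 = FoodNameVectorizer().fit(list(reversed(names)))
        assert v1.vocabulary_ == v2.vocabulary_

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            FoodNameVectorizer().fit([])

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_threshold_bounds(self, bad):
        with pytest.raises(ValueError):
            FoodNameVectorizer(sparsity_threshold=bad).fit(["apple"])


class TestEnsemble:
    def test_training_accuracy_on_near_separable_corpus(self, default_vocab):
        model = train_ensemble(default_vocab, seed=7)
        report = evaluate(model, default_vocab)
        assert report.accuracy >= 0.95

    def test_same_seed_same_predictions(self, small_vocab):
        probes = [r.name for r in small_vocab[:25]]
        preds = [
            train_ensemble(small_vocab, seed=11).predict(probes) for _ in range(2)
        ]
        assert list(preds[0]) == list(preds[1])

    def test_row_permutation_invariance(self, small_vocab):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(small_vocab))
        shuffled = [small_vocab[i] for i in perm]
        probes = [r.name for r in small_vocab[:25]]
        p1 = train_ensemble(small_vocab, seed=3).predict(probes)
        p2 = train_ensemble(shuffled, seed=3).predict(probes)
        assert list(p1) == list(p2)

    def test_predictions_within_alphabet(self, small_model, small_vocab):
        preds = small_model.predict([r.name for r in small_vocab[:30]])
        assert set(preds) <= {"r", "d", "s", "c"}

    def test_single_class_corpus_rejected(self):
        names = ["apple", "pear", "plum"]
        with pytest.raises(ValueError, match="two categories"):
            FoodCategoryClassifier().fit(names, ["r", "r", "r"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown categories"):
            FoodCategoryClassifier().fit(["apple", "pear"], ["r", "z"])


class TestMajorityVote:
    resolve = staticmethod(FoodCategoryClassifier._resolve_votes)

    def test_strict_plurality(self):
        votes = {"svm": "r", "random_forest": "r", "boosting": "d", "maxent": "s"}
        assert self.resolve(votes) == "r"

    def test_unanimity(self):
        assert self.resolve(dict.fromkeys(["svm", "random_forest", "boosting", "maxent"], "c")) == "c"

    def test_two_two_tie_follows_priority(self):
        # maxent outranks all: its label wins any tie it participates in
        votes = {"svm": "r", "random_forest": "r", "boosting": "d", "maxent": "d"}
        assert self.resolve(votes) == "d"
        votes = {"svm": "d", "random_forest": "r", "boosting": "d", "maxent": "r"}
        assert self.resolve(votes) == "r"

    def test_four_way_tie_follows_priority(self):
        votes = {"svm": "r", "random_forest": "d", "boosting": "s", "maxent": "c"}
        assert self.resolve(votes) == "c"  # maxent ranks first

    def test_degenerate_identical_votes_equal_single_member(self):
        for label in "rdsc":
            votes = dict.fromkeys(["svm", "random_forest", "boosting", "maxent"], label)
            assert self.resolve(votes) == label


class TestEvaluation:
    def test_metrics_direct_arithmetic(self):
        m = CategoryMetrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert m.precision == 0.75
        assert m.recall == 0.75
        assert m.accuracy == 0.8

    def test_perfect_predictions(self):
        labels = ["r", "d", "s", "c"] * 3
        report = evaluate_predictions(labels, labels)
        assert report.accuracy == 1.0
        for cat in "rdsc":
            assert report.per_category[cat].precision == 1.0
            assert report.per_category[cat].recall == 1.0

    def test_zero_denominator_is_undefined_not_zero(self):
        report = evaluate_predictions(["r", "r"], ["d", "d"])
        assert report.per_category["d"].precision == 0.0  # predicted but never true
        assert report.per_category["d"].recall is None  # never true
        assert report.per_category["s"].precision is None  # never predicted
        assert report.per_category["r"].recall == 0.0

    def test_hand_built_table_matches_independent_tally(self):
        """20-record stub: our one-vs-rest tallies agree with sklearn's."""
        y_true = list("rrrrrddddsssccrrddsc")
        y_pred = list("rrrrdddsssscccrrddsc")
        report = evaluate_predictions(y_true, y_pred)
        assert report.accuracy == accuracy_score(y_true, y_pred)
        for cat in "rdsc":
            counts = confusion_counts(y_true, y_pred, cat)
            assert counts.total == 20
            assert report.per_category[cat].precision == pytest.approx(
                precision_score(y_true, y_pred, labels=[cat], average="macro", zero_division=np.nan)
            )
            assert report.per_category[cat].recall == pytest.approx(
                recall_score(y_true, y_pred, labels=[cat], average="macro", zero_division=np.nan)
            )


class TestCrossValidation:
    def test_leave_one_out_partition_property(self):
        vocab = generate_vocabulary(
            n_raw=3, n_derivative=3, n_simple=2, n_aggregated=2, seed=5
        )
        result = cross_validate(vocab, k=len(vocab), seed=5)
        folds = result["fold_test_indices"]
        assert len(folds) == len(vocab)
        all_indices = sorted(i for fold in folds for i in fold)
        assert all_indices == list(range(len(vocab)))

    def test_deterministic_under_fixed_seed(self, small_vocab):
        r1 = cross_validate(small_vocab, k=4, seed=7)
        r2 = cross_validate(small_vocab, k=4, seed=7)
        assert r1["fold_accuracies"] == r2["fold_accuracies"]
        assert r1["predictions"] == r2["predictions"]
        assert r1["mean_accuracy"] == r2["mean_accuracy"]

    def test_k_out_of_range_rejected(self, small_vocab):
        with pytest.raises(ValueError):
            cross_validate(small_vocab, k=len(small_vocab) + 1)
        with pytest.raises(ValueError):
            cross_validate(small_vocab, k=1)

    def test_stratified_folds_keep_class_mix(self, small_vocab):
        result = cross_validate(small_vocab, k=4, seed=7)
        labels = np.asarray([r.category for r in small_vocab], dtype=object)
        for fold in result["fold_test_indices"]:
            # every category present in every stratified fold
            assert set(labels[fold]) == {"r", "d", "s", "c"}
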