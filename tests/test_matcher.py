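import math

import pytest
from hypothesis import given, strategies as st

from standfood.fixtures import generate_vocabulary, worked_examples
from standfood.matcher import FoodMatcher, describe, retrieve_candidates, similarity
from standfood.records import FoodRecord
from standfood.textproc import TermSets, extract_term_sets


def brute_force_retrieve(query_sets, vocabulary):
    return [
        rec
        for rec in vocabulary
        if query_sets.nouns & extract_term_sets(rec.name).nouns
    ]


def brute_force_top_weight(query_sets, vocabulary):
    weights = [
        similarity(query_sets, extract_term_sets(rec.name))[2] for rec in vocabulary
    ]
    return max(weights, default=0.0)


@pytest.mark.parametrize("example", worked_examples().similarity, ids=lambda e: e.query)
def test_similarity_reproduces_reference_walkthroughs(example):
    """The scorer reproduces the reference weights from raw name strings."""
    query = extract_term_sets(example.query)
    candidate = extract_term_sets(example.best_match)
    assert query == example.query_sets
    assert candidate == example.candidate_sets
    p_n, p_av, weight = similarity(query, candidate)
    assert p_n == example.expected_p_nouns
    assert p_av == example.expected_p_adj_verb
    assert weight == example.expected_weight


def test_disjoint_noun_sets_weight_zero():
    _, _, weight = similarity(TermSets(nouns={"apple"}), TermSets(nouns={"soup"}))
    assert weight == 0.0


def test_both_noun_sets_empty_gives_zero():
    p_n, p_av, weight = similarity(TermSets(), TermSets())
    assert p_n == 0.0 and weight == 0.0 and p_av == 0.5


def test_identical_sets_never_certain():
    """Laplace smoothing caps a perfect match below 1: weight = (u+1)/(u+2)."""
    sets = TermSets(nouns={"apple"}, adjectives={"dry"}, verbs={"bake"})
    _, p_av, weight = similarity(sets, sets)
    assert p_av == weight == 3 / 4


_lemmas = st.sets(st.sampled_from("apple soup dry bake fresh vine fruit can".split()), max_size=4)
_term_sets = st.builds(TermSets, nouns=_lemmas, adjectives=_lemmas, verbs=_lemmas)


@given(_term_sets, _term_sets)
def test_similarity_symmetric_and_bounded(a, b):
    pa, pav_a, wa = similarity(a, b)
    pb, pav_b, wb = similarity(b, a)
    assert (pa, pav_a, wa) == (pb, pav_b, wb)
    assert 0.0 <= wa <= 1.0
    u = len(a.adjectives_and_verbs | b.adjectives_and_verbs)
    assert math.isclose(pav_a * (u + 2), len(a.adjectives_and_verbs & b.adjectives_and_verbs) + 1)
    assert (wa == 0.0) == (not (a.nouns & b.nouns))


TOY_VOCAB = [
    FoodRecord(name)
    for name in [
        "field mushroom",
        "canned mushroom",
        "mushroom soup",
        "fruit soup",
        "apple juice",
        "raw carrot",
    ]
]


def test_retrieve_toy_vocabulary():
    query = extract_term_sets("mushroom soup")
    hits = retrieve_candidates(query, TOY_VOCAB)
    assert [r.name for r in hits] == [
        "field mushroom",
        "canned mushroom",
        "mushroom soup",
        "fruit soup",
    ]


def test_retrieve_empty_query_nouns():
    assert retrieve_candidates(TermSets(), TOY_VOCAB) == []


@pytest.mark.parametrize("seed", range(10))
def test_retrieval_matches_brute_force_on_random_fixtures(seed):
    vocab = generate_vocabulary(
        n_raw=12, n_derivative=9, n_simple=5, n_aggregated=4, seed=seed
    )
    matcher = FoodMatcher().fit(vocab)
    query = extract_term_sets(vocab[seed % len(vocab)].name)
    expected = {r.name for r in brute_force_retrieve(query, vocab)}
    assert {r.name for r in matcher.retrieve(query)} == expected


def test_describe_perfect_match_carries_code(small_vocab):
    matcher = FoodMatcher().fit(small_vocab)
    target = small_vocab[0]
    results = matcher.describe(target.name)
    assert any(r.record.name == target.name for r in results)
    best = next(r for r in results if r.record.name == target.name)
    assert best.record.code is not None and best.record.category is not None


def test_describe_returns_all_top_ties_sorted():
    vocab = [FoodRecord("sour cherries"), FoodRecord("sweet cherries"), FoodRecord("apple juice")]
    results = describe("cherry, fresh", vocab)
    assert [r.record.name for r in results] == ["sour cherries", "sweet cherries"]
    assert len({r.weight for r in results}) == 1


def test_describe_no_shared_noun_returns_empty():
    assert describe("quinoa porridge", [FoodRecord("apple juice")]) == []


@pytest.mark.parametrize("seed", range(5))
def test_describe_top_weight_matches_brute_force(seed):
    vocab = generate_vocabulary(
        n_raw=10, n_derivative=8, n_simple=4, n_aggregated=3, seed=100 + seed
    )
    matcher = FoodMatcher().fit(vocab)
    query_name = vocab[(3 * seed) % len(vocab)].name
    results = matcher.describe(query_name)
    top = brute_force_top_weight(extract_term_sets(query_name), vocab)
    assert results and results[0].weight == top


def test_unfitted_matcher_raises():
    with pytest.raises(ValueError, match="not fitted"):
        FoodMatcher().describe("mushroom soup")
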