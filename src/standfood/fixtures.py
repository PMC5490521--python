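"""Synthetic food vocabularies and bundled walkthrough examples.

The real coded food list is licensed, so training, matching and the test
suite run on generated stand-ins that mirror its structure: one record per
food with a name, a category in {r, d, s, c} and a grammar-valid code.
Name patterns follow how the four categories actually read — raw
commodities are bare commodity nouns ("barley grains"), derivatives carry
a nature-changing process participle ("dried apricots", "toasted
buckwheat flour"), simple composites are two-word preparations ("fruit
compote"), aggregated composites are dish names ("mushroom soup", "rice
and lentil meal"). The default category mix is skewed r > d > s > c like
a real coded food list.

Generation is a pure function of the spec (seeded); every derivative name
contains at least one process-lexicon participle, so the r→d correction
rule is exercisable on any derivative the classifier calls raw.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .codes import FacetDescriptor, FoodEx2Code
from .records import FoodRecord
from .textproc import TermSets

__all__ = [
    "FixtureSpec",
    "RuleCorrectionExample",
    "SimilarityExample",
    "WorkedExamples",
    "generate_vocabulary",
    "worked_examples",
]

_COMMODITIES = tuple((
    "barley wheat oat rye buckwheat maize rice millet spelt quinoa "
    "apple pear cherry plum apricot peach strawberry raspberry currant "
    "grape orange lemon banana fig date quince melon "
    "carrot potato cabbage spinach onion garlic leek celery beetroot "
    "pea bean lentil chickpea mushroom tomato cucumber pumpkin courgette "
    "walnut almond hazelnut chestnut sunflower sesame "
    "salmon trout herring mackerel beef pork chicken lamb turkey rabbit "
    "milk egg honey"
).split())

_RAW_PARTS = ("", "grains", "leaves", "seeds", "berries", "root", "fillet")

_PROCESS_PARTICIPLES = tuple((
    "dried smoked canned boiled fried baked roasted grilled pickled "
    "fermented toasted steamed salted minced ground frozen stewed cured "
    "milled malted pressed tinned mashed"
).split())

_DERIVATIVE_PRODUCTS = ("", "flour", "flakes", "oil", "juice", "powder", "paste", "butter", "chips")

_SIMPLE_TEMPLATES = ("compote", "jam", "marmalade", "porridge", "muesli", "spread", "jelly", "chutney")

_DISH_TEMPLATES = (
    "{a} soup",
    "{a} salad",
    "{a} and {b} meal",
    "{a} pie",
    "{a} casserole",
    "{a} pizza",
    "{a} curry",
    "{a} risotto",
)

_CODE_ALPHABET = np.array(list("0123456789ABCDEFGHJKLMNPQRSTVXYZ"))


@dataclass(frozen=True)
class FixtureSpec:
    """Counts per category, seed and the word pools the generator draws from.

    Default counts give a 400-record vocabulary at roughly 47/33/14/6%
    r/d/s/c — the imbalance of real coded food lists, at desk scale.
    """

    n_raw: int = 188
    n_derivative: int = 132
    n_simple: int = 56
    n_aggregated: int = 24
    seed: int = 0
    commodities: tuple[str, ...] = _COMMODITIES
    process_participles: tuple[str, ...] = _PROCESS_PARTICIPLES
    dish_templates: tuple[str, ...] = _DISH_TEMPLATES
    noise_words: tuple[str, ...] = ()  # injected uniformly to stress the classifier

    def __post_init__(self) -> None:
        for n in (self.n_raw, self.n_derivative, self.n_simple, self.n_aggregated):
            if n < 0:
                raise ValueError("record counts must be non-negative")
        if (self.n_raw or self.n_derivative) and not self.commodities:
            raise ValueError("commodity pool must be non-empty")
        if self.n_derivative and not self.process_participles:
            raise ValueError("process participle pool must be non-empty")
        if self.n_aggregated and not self.dish_templates:
            raise ValueError("dish template pool must be non-empty")

    @property
    def total(self) -> int:
        return self.n_raw + self.n_derivative + self.n_simple + self.n_aggregated


def _pick(rng: np.random.Generator, pool: Sequence[str]) -> str:
    return pool[int(rng.integers(len(pool)))]


def _make_code(rng: np.random.Generator, category: str) -> FoodEx2Code:
    def term() -> str:
        return "A" + "".join(rng.choice(_CODE_ALPHABET, size=4))

    n_facets = {"r": 0, "d": 1, "s": 1, "c": 2}[category]
    groups = ("F28", "F04", "F02")
    facets = tuple(
        FacetDescriptor(groups[i % len(groups)], term()) for i in range(n_facets)
    )
    return FoodEx2Code(term(), facets)


def _make_name(rng: np.random.Generator, category: str, spec: FixtureSpec) -> str:
    if category == "r":
        part = _pick(rng, _RAW_PARTS)
        name = f"{_pick(rng, spec.commodities)} {part}".strip()
    elif category == "d":
        participle = _pick(rng, spec.process_participles)
        product = _pick(rng, _DERIVATIVE_PRODUCTS)
        name = f"{participle} {_pick(rng, spec.commodities)} {product}".strip()
    elif category == "s":
        name = f"{_pick(rng, spec.commodities)} {_pick(rng, _SIMPLE_TEMPLATES)}"
    else:
        template = _pick(rng, spec.dish_templates)
        name = template.format(
            a=_pick(rng, spec.commodities), b=_pick(rng, spec.commodities)
        )
    if spec.noise_words and rng.random() < 0.3:
        name = f"{name} {_pick(rng, spec.noise_words)}"
    return name


def generate_vocabulary(spec: FixtureSpec | None = None, **overrides) -> list[FoodRecord]:
    """Generate a synthetic labeled vocabulary from a spec (deterministic).

    Keyword overrides are applied on top of the default spec, e.g.
    ``generate_vocabulary(n_raw=4, seed=1)``.
    """
    spec = replace(spec or FixtureSpec(), **overrides) if overrides else (spec or FixtureSpec())
    rng = np.random.default_rng(spec.seed)
    counts = (
        ("r", spec.n_raw),
        ("d", spec.n_derivative),
        ("s", spec.n_simple),
        ("c", spec.n_aggregated),
    )
    records: list[FoodRecord] = []
    seen: set[str] = set()
    for category, n in counts:
        for _ in range(n):
            name = _make_name(rng, category, spec)
            for _attempt in range(20):  # best-effort uniqueness
                if name not in seen:
                    break
                name = _make_name(rng, category, spec)
            seen.add(name)
            records.append(FoodRecord(name, category, _make_code(rng, category)))
    return records


# ---------------------------------------------------------------------------
# Bundled walkthrough examples: the reference inputs and expected outputs the
# similarity scorer and the correction rules are specified against.


@dataclass(frozen=True)
class SimilarityExample:
    query: str
    best_match: str
    query_sets: TermSets
    candidate_sets: TermSets
    expected_p_nouns: float
    expected_p_adj_verb: float
    expected_weight: float


@dataclass(frozen=True)
class RuleCorrectionExample:
    name: str
    predicted: str
    match_category: str | None
    expected: str


@dataclass(frozen=True)
class WorkedExamples:
    similarity: tuple[SimilarityExample, ...]
    rule_corrections: tuple[RuleCorrectionExample, ...]


def worked_examples() -> WorkedExamples:
    """The reference similarity walkthroughs and rule-correction cases."""
    similarity = (
        SimilarityExample(
            query="dried vine fruits (currants, raisins and sultanas)",
            best_match="dried vine fruits (raisins etc.)",
            query_sets=TermSets(
                nouns={"vine", "fruit", "currant", "raisin", "sultana"},
                verbs={"dry"},
            ),
            candidate_sets=TermSets(nouns={"vine", "fruit", "raisin"}, verbs={"dry"}),
            expected_p_nouns=3 / 5,
            expected_p_adj_verb=2 / 3,
            expected_weight=0.4,
        ),
        SimilarityExample(
            query="mushroom soup",
            best_match="mushroom soup",
            query_sets=TermSets(nouns={"mushroom", "soup"}),
            candidate_sets=TermSets(nouns={"mushroom", "soup"}),
            expected_p_nouns=1.0,
            expected_p_adj_verb=0.5,
            expected_weight=0.5,
        ),
    )
    rule_corrections = (
        RuleCorrectionExample("Cabbage Chinese boiled", "r", None, "d"),
        RuleCorrectionExample("Marzipan", "r", "s", "s"),
        RuleCorrectionExample("Gingerbread", "r", "c", "c"),
        RuleCorrectionExample("Water, bottled, flavored, citrus", "d", "s", "s"),
        RuleCorrectionExample("Salad, tuna-vegetable, canned", "d", "c", "c"),
        RuleCorrectionExample("Multigrain rolls", "c", "s", "s"),
        RuleCorrectionExample("Croissant, filled with jam", "s", "c", "c"),
    )
    return WorkedExamples(similarity, rule_corrections)
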