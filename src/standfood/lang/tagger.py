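"""Deterministic lexicon + suffix-rule part-of-speech tagger.

Food-item names are short noun phrases, not full sentences, so a statistical
sentence tagger buys little here; a closed-class lexicon plus morphological
suffix rules tags them reliably and reproducibly. Tags are coarse Penn-style:
``NN`` (noun), ``JJ`` (adjective), ``VB`` (verb, incl. participles) and ``X``
(function words and other non-content tokens). Any object with a
``tag(tokens)`` method can be swapped in behind the same interface.
"""

from __future__ import annotations

import re
from typing import Iterable, Protocol, Sequence

__all__ = ["RuleBasedTagger", "Tagger", "word_tokens"]

_WORD_RE = re.compile(r"[a-z]+")

# Closed-class / function words: never content-bearing in a food name.
_FUNCTION_WORDS = frozenset(
    """
    a an the and or of with without in on at by for from to as per plus
    its their other more most very not no non
    """.split()
)

# Common food-domain adjectives (open class is defaulted to noun, so only
# words that would otherwise be mis-tagged need listing).
_ADJECTIVES = frozenset(
    """
    fresh raw dry sweet sour bitter savoury hot cold warm red green white
    black brown yellow pink purple whole wholemeal low high fat-free plain
    dark light soft hard fine coarse wild young new organic instant skim
    multigrain crispy crunchy creamy fatty lean ripe unripe mild strong
    """.split()
)

# Irregular participles seen in food names, with their verb lemmas.
IRREGULAR_PARTICIPLES: dict[str, str] = {
    "frozen": "freeze",
    "ground": "grind",
    "made": "make",
    "beaten": "beat",
    "broken": "break",
    "shredded": "shred",
    "sundried": "sundry",
}

# Words ending in -ed / -ing that are nouns, not verb forms.
_ED_NOUNS = frozenset("seed linseed rapeseed oilseed seaweed bed shed".split())
_ING_NOUNS = frozenset(
    """
    pudding dressing filling stuffing topping icing seasoning herring
    dumpling wing king ring spring shortening
    """.split()
)


class Tagger(Protocol):
    def tag(self, tokens: Sequence[str]) -> list[tuple[str, str]]: ...


def word_tokens(text: str) -> list[str]:
    """Lowercase word tokens for tagging (hyphens and punctuation split)."""
    return _WORD_RE.findall(text.lower())


class RuleBasedTagger:
    """Assign NN / JJ / VB / X tags to lowercase tokens."""

    def tag(self, tokens: Iterable[str]) -> list[tuple[str, str]]:
        return [(tok, self.tag_one(tok)) for tok in tokens]

    def tag_one(self, token: str) -> str:
        if len(token) <= 1 or token in _FUNCTION_WORDS:
            return "X"
        if token in _ADJECTIVES:
            return "JJ"
        if token in IRREGULAR_PARTICIPLES:
            return "VB"
        if (
            token.endswith("ed")
            and len(token) >= 4
            and not token.endswith("eed")
            and token not in _ED_NOUNS
        ):
            return "VB"
        if token.endswith("ing") and len(token) >= 5 and token not in _ING_NOUNS:
            return "VB"
        return "NN"
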