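"""Linguistic preprocessing of food-item names.

Two parallel paths feed the rest of the system:

* the *document-term* path — :func:`preprocess_name`, :func:`tokenize`,
  :func:`stem` — normalizes a name and produces the stemmed tokens that
  populate the document-term matrix;
* the *term-set* path — :func:`extract_term_sets` — POS-tags the name and
  lemmatizes its nouns, adjectives and verbs into the three sets the
  description scorer compares, e.g. "dried vine fruits (currants, raisins
  and sultanas)" yields nouns {vine, fruit, currant, raisin, sultana} and
  verbs {dry}.

Tagging runs on the lowercased original name (punctuation helps neither
path, but parenthesised lists are still word-segmented identically), while
the matrix path strips punctuation and digits first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .lang import RuleBasedTagger, Tagger, lemmatize as _lemmatize_impl, porter_stem, word_tokens

__all__ = [
    "STOPLIST",
    "TermSets",
    "count_pos_and_length",
    "extract_term_sets",
    "lemmatize",
    "preprocess_name",
    "stem",
    "tokenize",
]

#: Filler tokens excluded from term sets and POS counts after tagging.
STOPLIST = frozenset({"etc", "e.g.", "i.e.", "eg", "ie", "similar", "and", "or"})

_NON_ALPHA_RE = re.compile(r"[^a-z\s]+")
_WS_RE = re.compile(r"\s+")

_default_tagger = RuleBasedTagger()


@dataclass(frozen=True)
class TermSets:
    """Lemma sets of the nouns, adjectives and verbs of one food name."""

    nouns: frozenset[str] = field(default_factory=frozenset)
    adjectives: frozenset[str] = field(default_factory=frozenset)
    verbs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nouns", frozenset(self.nouns))
        object.__setattr__(self, "adjectives", frozenset(self.adjectives))
        object.__setattr__(self, "verbs", frozenset(self.verbs))

    @property
    def adjectives_and_verbs(self) -> frozenset[str]:
        """The pooled adjective/verb lemma set (forms like "dry"/"dried" unify)."""
        return self.adjectives | self.verbs


def preprocess_name(name: str) -> str:
    """Lowercase, drop punctuation and digits, collapse whitespace."""
    text = _NON_ALPHA_RE.sub(" ", name.lower())
    return _WS_RE.sub(" ", text).strip()


def tokenize(text: str) -> list[str]:
    """Whitespace tokens of a preprocessed name, order preserved."""
    return text.split()


def stem(token: str) -> str:
    """Porter stem of a single lowercase token (``dried`` → ``dri``)."""
    return porter_stem(token)


def lemmatize(token: str, pos_tag: str) -> str:
    """Dictionary form of a token given its POS tag (``dried``/V → ``dry``)."""
    return _lemmatize_impl(token, pos_tag)


def _tagged_content_tokens(name: str, tagger: Tagger) -> list[tuple[str, str]]:
    tokens = word_tokens(name)
    return [(tok, tag) for tok, tag in tagger.tag(tokens) if tok not in STOPLIST and tag != "X"]


def extract_term_sets(name: str, tagger: Tagger | None = None) -> TermSets:
    """POS-tag a raw name and lemmatize its nouns, adjectives and verbs."""
    tagger = tagger or _default_tagger
    nouns: set[str] = set()
    adjectives: set[str] = set()
    verbs: set[str] = set()
    for token, tag in _tagged_content_tokens(name, tagger):
        lemma = _lemmatize_impl(token, tag)
        if tag.startswith("N"):
            nouns.add(lemma)
        elif tag.startswith("J"):
            adjectives.add(lemma)
        elif tag.startswith("V"):
            verbs.add(lemma)
    return TermSets(nouns, adjectives, verbs)


def count_pos_and_length(name: str, tagger: Tagger | None = None) -> tuple[int, int, int, int]:
    """Engineered features: (#nouns, #adjectives, #verbs, token length).

    Counts are over tagged tokens (stoplist excluded); length is the token
    count of the preprocessed name. More nouns point towards composite
    foods; adjectives and verbs towards derivatives and composites; longer
    names towards both.
    """
    tagger = tagger or _default_tagger
    n_nouns = n_adj = n_verbs = 0
    for _token, tag in _tagged_content_tokens(name, tagger):
        if tag.startswith("N"):
            n_nouns += 1
        elif tag.startswith("J"):
            n_adj += 1
        elif tag.startswith("V"):
            n_verbs += 1
    return n_nouns, n_adj, n_verbs, len(tokenize(preprocess_name(name)))
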