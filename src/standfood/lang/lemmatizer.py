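"""Dictionary-backed rule lemmatizer for nouns, adjectives and verbs.

Verb lemmatization checks stripped candidates against a lexicon of verbs
common in food names (cooking and preservation processes) before falling
back to generic suffix rules; noun lemmatization is rule-driven with an
irregular-plural table. Unknown tokens come back unchanged.
"""

from __future__ import annotations

from .tagger import IRREGULAR_PARTICIPLES

__all__ = ["lemmatize", "KNOWN_VERB_LEMMAS"]

# Verbs that occur in food names as processes or preparation steps. Used to
# resolve -ed/-ing stripping ambiguity (smoked -> smoke, canned -> can,
# filled -> fill) without a full dictionary.
KNOWN_VERB_LEMMAS = frozenset(
    """
    bake boil broil roast grill fry deepfry stirfry saute steam stew poach
    braise blanch simmer toast cook microwave smoke dry can tin bottle jar
    pickle ferment brew distill cure salt sugar candy sweeten marinate
    season spice glaze coat batter bread crumb stuff fill top freeze chill
    refrigerate thaw melt mince grind mill crush mash puree blend mix whip
    beat knead roll press squeeze juice strain drain sieve filter clarify
    skim churn grate shred slice dice chop cube peel core pit stone shell
    hull husk scale gut fillet debone bone trim wash rinse soak sprout
    malt dehydrate concentrate evaporate powder flake pasteurize sterilize
    homogenize fortify enrich smoke dress garnish serve prepare process
    heat reheat boiledown reduce caramelize brown sear scramble poach
    flavor flavour color colour age ripen cream ice frost
    """.split()
)

_IRREGULAR_PLURALS = {
    "leaves": "leaf",
    "loaves": "loaf",
    "halves": "half",
    "calves": "calf",
    "knives": "knife",
    "olives": "olive",
    "chives": "chive",
    "children": "child",
    "men": "man",
    "women": "woman",
    "feet": "foot",
    "geese": "goose",
    "mice": "mouse",
}

# Singular (or invariant) words ending in -s that plural rules leave alone.
_S_SINGULARS = frozenset(
    """
    asparagus couscous citrus hummus molasses swiss cress watercress bass
    grass species series
    """.split()
)


def _lemmatize_noun(token: str) -> str:
    if token in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[token]
    if token in _S_SINGULARS or len(token) <= 3:
        return token
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(("sses", "shes", "ches", "xes", "zes", "oes")):
        return token[:-2]
    if token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


def _undouble(stem: str) -> str:
    if (
        len(stem) >= 3
        and stem[-1] == stem[-2]
        and stem[-1] not in "aeioulsz"
    ):
        return stem[:-1]
    return stem


def _lemmatize_verb(token: str) -> str:
    if token in IRREGULAR_PARTICIPLES:
        return IRREGULAR_PARTICIPLES[token]
    if token in KNOWN_VERB_LEMMAS:
        return token
    for suffix in ("ed", "ing"):
        if not token.endswith(suffix) or len(token) < len(suffix) + 2:
            continue
        stem = token[: -len(suffix)]
        # candidate order: e-restoration via single-char strip (smoked->smoke),
        # -ied -> -y (dried->dry), bare stem (boiled->boil), undoubled
        # (canned->can); the first known verb wins.
        candidates = []
        if suffix == "ed":
            candidates.append(token[:-1])
            if token.endswith("ied"):
                candidates.append(token[:-3] + "y")
        candidates.extend([stem, stem + "e", _undouble(stem)])
        for cand in candidates:
            if cand in KNOWN_VERB_LEMMAS:
                return cand
        # fallback rules for verbs outside the lexicon
        if suffix == "ed" and token.endswith("ied"):
            return token[:-3] + "y"
        return _undouble(stem)
    return token


def lemmatize(token: str, pos_tag: str) -> str:
    """Dictionary form of ``token`` given its (coarse or Penn) POS tag.

    ``pos_tag`` starting with N is treated as noun, V as verb, J/A as
    adjective; anything else returns the token unchanged.
    """
    tag = pos_tag[:1].upper()
    if tag == "N":
        return _lemmatize_noun(token)
    if tag == "V":
        return _lemmatize_verb(token)
    return token
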