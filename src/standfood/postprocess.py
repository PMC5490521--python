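"""Rule-based correction of the classifier's category with the matcher's.

The description step returns, for most queries, a vocabulary entry whose
category is known; that category is strong evidence about the query's own
category and drives four correction rules:

1. predicted raw (r) but the name's adjective/verb lemmas contain a
   nature-changing process (canning, smoking, frying, baking, ...) →
   derivative (d);
2. predicted r or d but the best match is a composite (s or c) → the
   match's category;
3. predicted simple composite (s) but the best match is aggregated (c) → c;
4. predicted aggregated (c) but the best match is simple (s) → s.

Exactly one rule fires. Composite evidence from the match (rules 2–4) is
checked before the r→d promotion of rule 1, so a raw-classified name with
both a process verb and a composite match goes straight to the composite
category.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

from .records import CATEGORIES
from .textproc import TermSets

__all__ = ["ProcessLexicon", "apply_rules", "default_process_lexicon"]


class ProcessLexicon:
    """Set of lowercase process lemmas that change the nature of a food."""

    def __init__(self, lemmas: Iterable[str] = ()):
        self.lemmas = frozenset(lemma.strip().lower() for lemma in lemmas if lemma.strip())

    @classmethod
    def from_file(cls, path: str | Path) -> "ProcessLexicon":
        """Load one lemma per line; blank lines and ``#`` comments ignored."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(line for line in lines if not line.lstrip().startswith("#"))

    def __contains__(self, lemma: str) -> bool:
        return lemma in self.lemmas

    def __len__(self) -> int:
        return len(self.lemmas)

    def intersects(self, lemmas: Iterable[str]) -> bool:
        return not self.lemmas.isdisjoint(lemmas)


def default_process_lexicon() -> ProcessLexicon:
    """The bundled process-term list."""
    text = resources.files("standfood.data").joinpath("process_lexicon.txt").read_text(
        encoding="utf-8"
    )
    return ProcessLexicon(
        line for line in text.splitlines() if not line.lstrip().startswith("#")
    )


def apply_rules(
    name_sets: TermSets,
    predicted: str,
    match_category: str | None,
    lexicon: ProcessLexicon | None = None,
) -> str:
    """Corrected category for one food item.

    ``name_sets`` are the query name's term sets, ``predicted`` the
    ensemble's category, ``match_category`` the category of the best
    description match (``None`` when the description found nothing).
    """
    if predicted not in CATEGORIES:
        raise ValueError(f"invalid predicted category {predicted!r}")
    if match_category is not None and match_category not in CATEGORIES:
        raise ValueError(f"invalid match category {match_category!r}")
    if lexicon is None:
        lexicon = default_process_lexicon()

    # rules 2-4: the match's composite evidence dominates
    if predicted in ("r", "d") and match_category in ("s", "c"):
        return match_category
    if predicted == "s" and match_category == "c":
        return "c"
    if predicted == "c" and match_category == "s":
        return "s"
    # rule 1: raw prediction contradicted by a nature-changing process term
    if predicted == "r" and lexicon.intersects(name_sets.adjectives_and_verbs):
        return "d"
    return predicted
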