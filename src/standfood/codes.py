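"""Parsing, validation and serialization of FoodEx2-style code strings.

A code is a mandatory base (list) term, optionally followed by facet
descriptors. The canonical form separates the base term from the facets
with ``#`` and the facets from each other with ``$``, each facet written
as ``<facet group>.<descriptor>``::

    A03BG#F09.A0EXH$F10.A077L$F21.A07SE

Codes also circulate with the first facet attached directly by ``$``
(``A009Q$F14.A07GX``); the parser accepts both dialects and serialization
always emits the canonical ``#`` form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["CodeParseError", "FacetDescriptor", "FoodEx2Code", "parse_code", "serialize_code"]

_FACET_GROUP_RE = re.compile(r"^F\d+$")
_TOKEN_RE = re.compile(r"^[A-Za-z0-9]+$")


class CodeParseError(ValueError):
    """Raised when a code string cannot be parsed."""


@dataclass(frozen=True)
class FacetDescriptor:
    """One facet: a facet group (e.g. ``F09``) and a term code (e.g. ``A0EXH``)."""

    facet_group: str
    descriptor: str

    def __post_init__(self) -> None:
        if not _FACET_GROUP_RE.match(self.facet_group):
            raise ValueError(f"invalid facet group {self.facet_group!r}")
        if not _TOKEN_RE.match(self.descriptor):
            raise ValueError(f"invalid facet descriptor {self.descriptor!r}")


@dataclass(frozen=True)
class FoodEx2Code:
    """A base term plus an ordered (possibly empty) sequence of facets."""

    base_term: str
    facets: tuple[FacetDescriptor, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not _TOKEN_RE.match(self.base_term):
            raise ValueError(f"invalid base term {self.base_term!r}")
        object.__setattr__(self, "facets", tuple(self.facets))

    def __str__(self) -> str:
        return serialize_code(self)


def _parse_facet(segment: str) -> FacetDescriptor:
    group, sep, descriptor = segment.partition(".")
    if not sep or not group or not descriptor:
        raise CodeParseError(
            f"malformed facet segment {segment!r}: expected '<group>.<descriptor>'"
        )
    try:
        return FacetDescriptor(group, descriptor)
    except ValueError as exc:
        raise CodeParseError(f"malformed facet segment {segment!r}: {exc}") from exc


def parse_code(code_string: str) -> FoodEx2Code:
    """Parse a code string in either the ``#`` or bare-``$`` dialect.

    Raises :class:`CodeParseError` on an empty string, an invalid base term
    or a facet segment without a ``.`` separator.
    """
    text = code_string.strip()
    if not text:
        raise CodeParseError("empty code string")
    if "#" in text:
        base, _, rest = text.partition("#")
        facet_part = rest
    elif "$" in text:
        base, _, facet_part = text.partition("$")
    else:
        base, facet_part = text, ""
    if not _TOKEN_RE.match(base):
        raise CodeParseError(f"invalid base term {base!r} in {code_string!r}")
    facets: tuple[FacetDescriptor, ...] = ()
    if facet_part:
        facets = tuple(_parse_facet(seg) for seg in facet_part.split("$"))
    return FoodEx2Code(base, facets)


def serialize_code(code: FoodEx2Code) -> str:
    """Canonical string form: base, then ``#`` iff facets exist, facets ``$``-joined."""
    if not code.facets:
        return code.base_term
    facet_part = "$".join(f"{f.facet_group}.{f.descriptor}" for f in code.facets)
    return f"{code.base_term}#{facet_part}"
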