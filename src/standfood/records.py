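"""The vocabulary record shared by the classifier and the matcher."""

from __future__ import annotations

from dataclasses import dataclass

from .codes import FoodEx2Code

__all__ = ["CATEGORIES", "FoodRecord"]

#: The four food-chain categories: raw commodity, derivative, simple
#: composite, aggregated composite.
CATEGORIES = ("r", "d", "s", "c")


@dataclass(frozen=True)
class FoodRecord:
    """One vocabulary entry: a food name, its category and its code.

    ``category`` and ``code`` are optional so that query items (name only)
    reuse the same type.
    """

    name: str
    category: str | None = None
    code: FoodEx2Code | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("food record name must be non-empty")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )
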