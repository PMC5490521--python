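"""Reading and writing vocabularies, queries and fitted models.

Vocabulary files are UTF-8 CSV with a header row and columns ``name``,
``category``, ``code`` (the last two may be empty for query-only files).
Models are persisted with joblib under a small versioned envelope.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import joblib
import pandas as pd

from .codes import parse_code, serialize_code
from .records import FoodRecord

__all__ = [
    "load_model",
    "read_names",
    "read_vocabulary",
    "save_model",
    "vocabulary_frame",
    "write_vocabulary",
]

_MODEL_FORMAT = "standfood-model/1"


def read_vocabulary(path: str | Path) -> list[FoodRecord]:
    """Load food records from a CSV with columns name[, category, code]."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "name" not in df.columns:
        raise ValueError(f"{path}: vocabulary CSV needs a 'name' column")
    records = []
    for row in df.itertuples(index=False):
        category = getattr(row, "category", "") or None
        code_text = getattr(row, "code", "") or None
        code = parse_code(code_text) if code_text else None
        records.append(FoodRecord(row.name, category, code))
    return records


def vocabulary_frame(records: Sequence[FoodRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in records],
            "category": [r.category or "" for r in records],
            "code": [serialize_code(r.code) if r.code else "" for r in records],
        }
    )


def write_vocabulary(records: Sequence[FoodRecord], path: str | Path) -> None:
    vocabulary_frame(records).to_csv(path, index=False)


def read_names(path: str | Path) -> list[str]:
    """Query names, one per line (or the name column of a CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return [r.name for r in read_vocabulary(path)]
    return [line.strip() for line in path.read_text(encoding="utf-8").splitlines() if line.strip()]


def save_model(model, path: str | Path) -> None:
    joblib.dump({"format": _MODEL_FORMAT, "model": model}, path)


def load_model(path: str | Path):
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not a {_MODEL_FORMAT} archive")
    return payload["model"]
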