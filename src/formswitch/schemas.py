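"""Row validation for the CSV knowledge-base and cohort tables.

Each table ships a JSON Schema (draft-07 style) under
``formswitch/data/schemas``.  Only the subset of keywords those schemas
use is interpreted here: ``required``, per-property ``enum``, ``pattern``
and ``type`` (string / number / integer).  Empty strings count as absent
for optional columns.
"""

from __future__ import annotations

import json
import re
from functools import lru_cache
from pathlib import Path

__all__ = ["SchemaError", "load_schema", "validate_row"]

_SCHEMA_DIR = Path(__file__).parent / "data" / "schemas"


class SchemaError(ValueError):
    """A row violating its table schema; message carries file and line."""


@lru_cache(maxsize=None)
def load_schema(name: str) -> dict:
    path = _SCHEMA_DIR / f"{name}.schema.json"
    with path.open(encoding="utf-8") as fh:
        return json.load(fh)


def validate_row(schema: dict, row: dict, *, file: str, line: int) -> None:
    where = f"{file}:{line}"
    for col in schema.get("required", ()):
        if row.get(col) in (None, ""):
            raise SchemaError(f"{where}: missing required column {col!r}")
    for col, rules in schema.get("properties", {}).items():
        value = row.get(col)
        if value in (None, ""):
            continue
        if "enum" in rules and value not in rules["enum"]:
            raise SchemaError(
                f"{where}: {col}={value!r} not in {rules['enum']}"
            )
        if "pattern" in rules and not re.search(rules["pattern"], value):
            raise SchemaError(
                f"{where}: {col}={value!r} does not match {rules['pattern']!r}"
            )
        t = rules.get("type")
        if t == "number":
            try:
                float(value)
            except ValueError:
                raise SchemaError(f"{where}: {col}={value!r} is not a number")
        elif t == "integer":
            if not re.fullmatch(r"[+-]?[0-9]+", value):
                raise SchemaError(f"{where}: {col}={value!r} is not an integer")
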