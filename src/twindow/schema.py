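"""Minimal structural validation of study reports.

Validates a report dict against the JSON schema shipped in
``docs/report.schema.json`` (a copy is packaged as ``report.schema.json``
next to this module).  Only the subset of JSON-schema keywords that the
report schema uses is implemented: ``type``, ``required``, ``properties``,
``items``, ``minimum`` and ``maximum``.
"""

from __future__ import annotations

import json
from pathlib import Path

__all__ = ["load_report_schema", "validate_report"]

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "integer": int,
    "number": (int, float),
    "null": type(None),
}


def load_report_schema() -> dict:
    """Load the published report schema from the package."""
    path = Path(__file__).with_name("report.schema.json")
    return json.loads(path.read_text())


class SchemaError(ValueError):
    pass


def _check_type(value, typespec, path):
    types = typespec if isinstance(typespec, list) else [typespec]
    py = tuple(
        t for name in types for t in (
            _TYPES[name] if isinstance(_TYPES[name], tuple) else (_TYPES[name],)
        )
    )
    if isinstance(value, bool) and bool not in py:
        raise SchemaError(f"{path}: boolean where {types} expected")
    if not isinstance(value, py):
        raise SchemaError(f"{path}: {type(value).__name__} where {types} expected")


def validate_report(obj, schema: dict | None = None, path: str = "$") -> None:
    """Raise :class:`SchemaError` when ``obj`` violates the schema."""
    if schema is None:
        schema = load_report_schema()
    if "type" in schema:
        _check_type(obj, schema["type"], path)
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                raise SchemaError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                validate_report(obj[key], sub, f"{path}.{key}")
    elif isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            validate_report(item, schema["items"], f"{path}[{i}]")
    if isinstance(obj, (int, float)) and not isinstance(obj, bool):
        if "minimum" in schema and obj < schema["minimum"]:
            raise SchemaError(f"{path}: {obj} below minimum {schema['minimum']}")
        if "maximum" in schema and obj > schema["maximum"]:
            raise SchemaError(f"{path}: {obj} above maximum {schema['maximum']}")
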