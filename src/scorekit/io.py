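"""Readers and writers for tables, catalogs and norm tables.

Tabular formats: CSV (comma-separated, UTF-8, header row, empty string =
missing), TSV, and Parquet.  Catalogs are YAML or JSON documents with
top-level keys ``id_columns``, ``missing_codes``, ``scores``, ``groups``
and optionally ``norms``; the schema is validated on load and every
definition passes :func:`~scorekit.model.validate_definition`.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import LoadError
from .model import (
    Catalog,
    ConditionSpec,
    NormTable,
    ScoreDefinition,
    validate_definition,
)
from .table import DEFAULT_ID_COLUMNS, ScoreTable

__all__ = [
    "read_table",
    "write_table",
    "read_catalog",
    "write_catalog",
    "read_norm_table",
    "default_catalog",
]

_TABLE_FORMATS = ("csv", "tsv", "parquet")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in _TABLE_FORMATS:
            raise LoadError(
                f"unknown table format {format!r} "
                f"(expected one of {_TABLE_FORMATS})"
            )
        return format
    suffix = path.suffix.lstrip(".").lower()
    if suffix in _TABLE_FORMATS:
        return suffix
    raise LoadError(
        f"cannot infer table format from {path.name!r}; pass format="
    )


def read_table(
    path,
    format: str | None = None,
    id_columns: Sequence[str] = DEFAULT_ID_COLUMNS,
    event_order: Sequence[str] | None = None,
) -> ScoreTable:
    """Load a tabular file into a :class:`ScoreTable`.

    Raises :class:`~scorekit.errors.LoadError` if the file lacks any
    identifier column (the error names them).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    if fmt == "parquet":
        frame = pd.read_parquet(path)
    else:
        frame = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
    return ScoreTable(frame, tuple(id_columns), event_order)


def write_table(table: ScoreTable, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "parquet":
        table.data.to_parquet(path, index=False)
    else:
        table.data.to_csv(
            path, sep="," if fmt == "csv" else "\t", index=False
        )


def read_norm_table(
    path, stratum_columns: Sequence[str] = ()
) -> NormTable:
    """Load a norm table from a tabular file with columns
    ``<stratum...>, raw, t``."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    frame = pd.read_csv(path, sep=sep)
    missing = [
        c for c in (*stratum_columns, "raw", "t") if c not in frame.columns
    ]
    if missing:
        raise LoadError(
            f"norm table {path.name} lacks column(s): {', '.join(missing)}"
        )
    return NormTable(frame, stratum_columns)


def _condition_from_dict(doc: dict, where: str) -> ConditionSpec:
    for key in ("column", "comparator", "reference"):
        if key not in doc:
            raise LoadError(f"{where}: condition lacks {key!r}")
    return ConditionSpec(
        doc["column"],
        doc["comparator"],
        doc["reference"],
        doc.get("missing_policy", "false"),
    )


def _definition_from_dict(doc: dict, where: str) -> ScoreDefinition:
    if not isinstance(doc, dict):
        raise LoadError(f"{where}: score entry must be a mapping")
    for key in ("name", "kernel", "items"):
        if key not in doc:
            raise LoadError(f"{where}: score entry lacks {key!r}")
    params = dict(doc.get("params") or {})
    if "conditions" in params:
        params["conditions"] = [
            _condition_from_dict(c, f"{where}.conditions[{i}]")
            for i, c in enumerate(params["conditions"])
        ]
    return ScoreDefinition(
        doc["name"],
        tuple(doc["items"]),
        doc["kernel"],
        params,
        doc.get("nm_companion"),
    )


def read_catalog(path) -> Catalog:
    """Load and validate a score catalog (YAML or JSON).

    Raises :class:`~scorekit.errors.LoadError` on schema violations, with
    the document path to the offending field in the message.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    text = path.read_text(encoding="utf-8")
    doc = (
        json.loads(text)
        if path.suffix.lower() == ".json"
        else yaml.safe_load(text)
    )
    return _catalog_from_dict(doc, base=path.parent)


def _catalog_from_dict(doc, base: Path | None = None) -> Catalog:
    if not isinstance(doc, dict):
        raise LoadError("catalog document must be a mapping")
    unknown = set(doc) - {
        "id_columns",
        "missing_codes",
        "scores",
        "groups",
        "norms",
    }
    if unknown:
        raise LoadError(
            f"catalog: unknown top-level key(s): {', '.join(sorted(unknown))}"
        )
    definitions: dict[str, ScoreDefinition] = {}
    for i, entry in enumerate(doc.get("scores") or []):
        defn = _definition_from_dict(entry, f"scores[{i}]")
        key = defn.name.render()
        if key in definitions:
            raise LoadError(f"scores[{i}]: duplicate score name {key!r}")
        violations = validate_definition(defn)
        if violations:
            raise LoadError(
                f"scores[{i}] ({key}): "
                + "; ".join(v.message for v in violations)
            )
        definitions[key] = defn
    norms: dict[str, NormTable] = {}
    for i, entry in enumerate(doc.get("norms") or []):
        for key in ("id", "path"):
            if key not in entry:
                raise LoadError(f"norms[{i}]: entry lacks {key!r}")
        norm_path = Path(entry["path"])
        if base is not None and not norm_path.is_absolute():
            norm_path = base / norm_path
        norms[entry["id"]] = read_norm_table(
            norm_path, entry.get("stratum_columns", ())
        )
    catalog = Catalog(
        definitions=definitions,
        groups=doc.get("groups") or {},
        missing_codes=frozenset(doc.get("missing_codes") or ()),
        id_columns=tuple(doc.get("id_columns") or DEFAULT_ID_COLUMNS),
        norms=norms,
    )
    problems = [
        v
        for v in catalog.validate()
        if v.kind in ("group-member", "group-prefix")
    ]
    if problems:
        raise LoadError("; ".join(v.message for v in problems))
    return catalog


def _definition_to_dict(defn: ScoreDefinition) -> dict:
    params = {}
    for key, value in defn.params.items():
        if key == "conditions":
            value = [
                {
                    "column": c.column,
                    "comparator": c.comparator,
                    "reference": sorted(c.reference)
                    if isinstance(c.reference, frozenset)
                    else c.reference,
                    "missing_policy": c.missing_policy,
                }
                for c in value
            ]
        elif isinstance(value, (set, frozenset)):
            value = sorted(value)
        params[key] = value
    return {
        "name": defn.name.render(),
        "kernel": defn.kernel,
        "items": list(defn.items),
        "params": params,
        "nm_companion": defn.nm_companion,
    }


def write_catalog(catalog: Catalog, path) -> None:
    """Serialize a catalog to YAML or JSON (by file suffix).

    ``write_catalog`` then :func:`read_catalog` round-trips to an equal
    catalog.  Loaded norm tables are not re-serialized (they live in their
    own tabular files).
    """
    path = Path(path)
    doc = {
        "id_columns": list(catalog.id_columns),
        "missing_codes": sorted(catalog.missing_codes),
        "scores": [
            _definition_to_dict(d) for d in catalog.definitions.values()
        ],
        "groups": {g: list(m) for g, m in catalog.groups.items()},
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
    else:
        path.write_text(
            yaml.safe_dump(doc, sort_keys=False), encoding="utf-8"
        )


def default_catalog() -> Catalog:
    """The catalog bundled with the package (exemplar scales)."""
    ref = resources.files("scorekit").joinpath("data/catalog.yml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _catalog_from_dict(doc)
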