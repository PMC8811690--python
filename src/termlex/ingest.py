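"""Parsing, merging, deduplication and grouping of concept exports.

Concept exports are JSON — either one array of objects or one object
per line — as produced by terminology-service download endpoints.  Field
names vary between services, so the key mapping is configurable; the
default follows the common convention ``ui`` / ``name`` / ``rootSource``
/ ``semanticTypes``.

Several query results covering overlapping search terms are merged in
listed order and then deduplicated on the unique concept identifier,
keeping the first occurrence.  Names and source codes are not part of
the duplicate key: overlapping queries retrieve the same concept under
the same identifier.
"""
from __future__ import annotations

import csv
import io
import json
from typing import Mapping, Sequence

from .errors import (
    ExportParseError,
    ExportValidationError,
    MetadataSchemaError,
    MetadataValidationError,
)
from .types import (
    COUNTRY_CATEGORIES,
    LICENSE_CLASSES,
    ConceptExport,
    ConceptRecord,
    VocabularyMetadata,
)

#: Default JSON key mapping: export key -> record field.
DEFAULT_KEY_MAP: dict[str, str] = {
    "concept_id": "ui",
    "name": "name",
    "source_vocab": "rootSource",
    "semantic_types": "semanticTypes",
}

METADATA_COLUMNS = (
    "source_vocab",
    "author",
    "country_category",
    "license_class",
    "last_update_year",
)


def _record_from_obj(
    obj: Mapping[str, object], key_map: Mapping[str, str], index: int
) -> ConceptRecord:
    if not isinstance(obj, Mapping):
        raise ExportValidationError(f"record {index}: expected a JSON object")
    values: dict[str, str] = {}
    for field in ("concept_id", "name", "source_vocab"):
        key = key_map[field]
        raw = obj.get(key)
        if raw is None or str(raw) == "":
            raise ExportValidationError(
                f"record {index}: missing or empty required key {key!r} ({field})"
            )
        values[field] = str(raw)
    sem_key = key_map["semantic_types"]
    raw_types = obj.get(sem_key, [])
    if raw_types is None:
        raw_types = []
    if isinstance(raw_types, str):
        raw_types = [raw_types]
    if not isinstance(raw_types, (list, tuple)):
        raise ExportValidationError(
            f"record {index}: {sem_key!r} must be a string or list of strings"
        )
    return ConceptRecord(
        concept_id=values["concept_id"],
        name=values["name"],
        source_vocab=values["source_vocab"],
        semantic_types=tuple(str(t) for t in raw_types),
    )


def parse_export(
    text: str,
    key_map: Mapping[str, str] | None = None,
    query_label: str = "",
) -> ConceptExport:
    """Parse a JSON array or JSON-lines concept export.

    Raises :class:`ExportParseError` (naming line/position) on malformed
    JSON and :class:`ExportValidationError` (naming the record index) on
    a record missing its id, name, or source key.  Unknown extra keys are
    ignored; record order is preserved.
    """
    mapping = dict(DEFAULT_KEY_MAP)
    if key_map:
        mapping.update(key_map)

    stripped = text.lstrip()
    objs: list[object]
    if stripped.startswith("["):
        try:
            parsed = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ExportParseError(
                f"malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
            ) from exc
        if not isinstance(parsed, list):
            raise ExportParseError("top-level JSON value is not an array")
        objs = parsed
    elif stripped == "":
        objs = []
    else:
        objs = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                objs.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise ExportParseError(
                    f"malformed JSON on line {lineno}, column {exc.colno}: {exc.msg}"
                ) from exc

    records = [_record_from_obj(obj, mapping, i) for i, obj in enumerate(objs)]
    return ConceptExport(records=records, query_label=query_label)


def merge_exports(exports: Sequence[ConceptExport]) -> ConceptExport:
    """Concatenate query results in listed order, duplicates retained."""
    if not exports:
        raise ValueError("merge_exports requires at least one export")
    records: list[ConceptRecord] = []
    labels: list[str] = []
    for export in exports:
        records.extend(export.records)
        if export.query_label:
            labels.append(export.query_label)
    return ConceptExport(records=records, query_label="+".join(labels))


def deduplicate(export: ConceptExport) -> list[ConceptRecord]:
    """Keep the first occurrence of each concept identifier.

    First-occurrence order is preserved, so deduplication is stable under
    the merge order of the contributing queries.
    """
    seen: dict[str, ConceptRecord] = {}
    for record in export.records:
        if record.concept_id not in seen:
            seen[record.concept_id] = record
    return list(seen.values())


def group_by_vocab(
    records: Sequence[ConceptRecord],
) -> dict[str, list[ConceptRecord]]:
    """Partition deduplicated records by verbatim source-vocabulary code."""
    groups: dict[str, list[ConceptRecord]] = {}
    for record in records:
        groups.setdefault(record.source_vocab, []).append(record)
    return groups


def export_to_json(export: ConceptExport, key_map: Mapping[str, str] | None = None) -> str:
    """Serialize records back to a JSON array under the given key mapping.

    Re-parsing the output yields field-identical records (round-trip).
    """
    mapping = dict(DEFAULT_KEY_MAP)
    if key_map:
        mapping.update(key_map)
    objs = [
        {
            mapping["concept_id"]: r.concept_id,
            mapping["name"]: r.name,
            mapping["source_vocab"]: r.source_vocab,
            mapping["semantic_types"]: list(r.semantic_types),
        }
        for r in export.records
    ]
    return json.dumps(objs, indent=1, ensure_ascii=False)


def parse_metadata(text: str) -> list[VocabularyMetadata]:
    """Parse a TSV vocabulary-metadata table.

    Expects a header row with columns ``source_vocab``, ``author``,
    ``country_category``, ``license_class``, ``last_update_year``.
    ``last_update_year`` may be an integer year or ``unknown``/empty.
    """
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    header = reader.fieldnames or []
    missing = [c for c in METADATA_COLUMNS if c not in header]
    if missing:
        raise MetadataSchemaError(f"metadata table missing column(s): {missing}")

    out: list[VocabularyMetadata] = []
    for rownum, row in enumerate(reader, start=2):
        country = (row["country_category"] or "").strip()
        license_class = (row["license_class"] or "").strip()
        if country not in COUNTRY_CATEGORIES:
            raise MetadataValidationError(
                f"row {rownum}: unknown country_category {country!r}"
            )
        if license_class not in LICENSE_CLASSES:
            raise MetadataValidationError(
                f"row {rownum}: unknown license_class {license_class!r}"
            )
        raw_year = (row["last_update_year"] or "").strip()
        year: int | None
        if raw_year == "" or raw_year.lower() == "unknown":
            year = None
        else:
            try:
                year = int(raw_year)
            except ValueError as exc:
                raise MetadataValidationError(
                    f"row {rownum}: last_update_year {raw_year!r} is not a year"
                ) from exc
        out.append(
            VocabularyMetadata(
                source_vocab=(row["source_vocab"] or "").strip(),
                author=(row["author"] or "").strip(),
                country_category=country,
                license_class=license_class,
                last_update_year=year,
            )
        )
    return out
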