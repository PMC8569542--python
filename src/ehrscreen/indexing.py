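"""Template-to-index mapping and document flattening.

Each composition template maps to exactly one hierarchical document index.
Leaf attribute nodes become typed value fields; string values of coded and
plain text get dual keyword/fulltext fields so they can be matched exactly
or searched; slotted (non-collection) clusters are flattened into the entry;
collection clusters become nested fields whose sub-documents keep their
structure. Field names are built recursively: the archetype concept name,
then any intermediate cluster names, then the node's ontology name, joined
with underscores — so "Body site" under the problem_diagnosis archetype
indexes as ``problem_diagnosis_Body_site``.

A patient's data in one index is a single document: an id, plus the
patient's entries as a list of flattened sub-documents each carrying a
timestamp. This keeps every cross-entry condition answerable within one
document and avoids join queries entirely.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import FlatteningError, MappingError
from .expressions import format_duration, parse_duration
from .templates import Template, TemplateNode, normalize_name

ID_FIELD = "patient_id"
TIMESTAMP_FIELD = "timestamp"

#: rm_type -> [(attribute, field kind, value type)]
DATA_TYPE_MAP = {
    "DV_BOOLEAN": [("value", "generic", "boolean")],
    "DV_CODED_TEXT": [
        ("value", "keyword", "string"),
        ("value", "fulltext", "string"),
        ("code", "keyword", "string"),
    ],
    "DV_COUNT": [("magnitude", "generic", "integer")],
    "DV_DATE": [("dateTime", "generic", "date")],
    "DV_DATE_TIME": [("dateTime", "generic", "date")],
    "DV_DURATION": [("duration", "generic", "duration")],
    "DV_IDENTIFIER": [("id", "keyword", "string")],
    "DV_QUANTITY": [
        ("magnitude", "generic", "double"),
        ("units", "keyword", "string"),
    ],
    "DV_TEXT": [("value", "keyword", "string"), ("value", "fulltext", "string")],
    "DV_URI": [("uri", "generic", "uri")],
}

#: value_type -> Elasticsearch 7.x mapping type (generic fields).
_ES_GENERIC_TYPES = {
    "boolean": "boolean",
    "integer": "integer",
    "double": "double",
    "date": "date",
    "duration": "keyword",
    "uri": "keyword",
    "string": "keyword",
    "id": "keyword",
}


def map_data_type(rm_type: str, attribute: Optional[str] = None):
    """Field rows for one reference-model data type (optionally one
    attribute). Coded and plain text values yield both a keyword and a
    fulltext field."""
    if rm_type not in DATA_TYPE_MAP:
        raise MappingError(f"unsupported rm_type {rm_type!r}")
    rows = DATA_TYPE_MAP[rm_type]
    if attribute is not None:
        rows = [r for r in rows if r[0] == attribute]
        if not rows:
            raise MappingError(f"{rm_type} has no attribute {attribute!r}")
    return list(rows)


def name_field(node, context: Iterable[str]):
    """Index field name for a node given its ancestor chain.

    ``context`` is the chain of naming ancestors: the archetype concept
    name first, then intermediate cluster/slot names. For dual-annotated
    string nodes (DV_TEXT / DV_CODED_TEXT) the keyword/fulltext pair is
    returned; otherwise the single base name.
    """
    if isinstance(node, TemplateNode):
        raw_name, rm_type = node.ontology_name, node.rm_type
    else:
        raw_name, rm_type = str(node), None
    base = "_".join(normalize_name(part) for part in (*context, raw_name))
    if rm_type in ("DV_TEXT", "DV_CODED_TEXT"):
        return (f"{base}_keyword", f"{base}_text")
    return base


def _field_base(node, context) -> str:
    return "_".join(normalize_name(part) for part in (*context, node.ontology_name))


def leaf_field_names(node: TemplateNode, context) -> dict:
    """attribute -> full field name for one leaf node."""
    base = _field_base(node, context)
    rm = node.rm_type
    if rm == "DV_TEXT":
        return {"value_keyword": f"{base}_keyword", "value_text": f"{base}_text"}
    if rm == "DV_CODED_TEXT":
        return {
            "value_keyword": f"{base}_keyword",
            "value_text": f"{base}_text",
            "code": f"{base}_code",
        }
    if rm == "DV_QUANTITY":
        return {"magnitude": f"{base}_magnitude", "units": f"{base}_units"}
    return {"value": base}


@dataclass
class FieldSpec:
    name: str
    kind: str  # generic | keyword | fulltext | object | nested
    value_type: Optional[str] = None  # boolean|integer|double|string|date|duration|uri|id
    source_path: Optional[str] = None
    children: list = field(default_factory=list)


@dataclass
class IndexSchema:
    index_name: str
    fields: list  # list[FieldSpec]; nested FieldSpecs carry children
    id_field: str = ID_FIELD
    timestamp_field: str = TIMESTAMP_FIELD
    timestamp_source_path: Optional[str] = None
    template_id: Optional[str] = None

    def iter_leaf_fields(self):
        def walk(specs, scope):
            for spec in specs:
                if spec.kind == "nested":
                    yield from walk(spec.children, spec.name)
                else:
                    yield scope, spec

        yield from walk(self.fields, None)

    def all_field_names(self) -> list[str]:
        names = [self.id_field, self.timestamp_field]

        def walk(specs):
            for spec in specs:
                names.append(spec.name)
                walk(spec.children)

        walk(self.fields)
        return names

    def field_by_name(self, name: str):
        for _scope, spec in self.iter_leaf_fields():
            if spec.name == name:
                return spec
        return None


@dataclass
class DocumentRecord:
    """One patient's document in one index: a list of flattened entries."""

    patient_id: str
    entries: list = field(default_factory=list)


def _leaf_specs(node: TemplateNode, context) -> list[FieldSpec]:
    base = _field_base(node, context)
    specs = []
    for attribute, kind, value_type in DATA_TYPE_MAP[node.rm_type]:
        names = leaf_field_names(node, context)
        if node.rm_type in ("DV_TEXT", "DV_CODED_TEXT"):
            if attribute == "value":
                name = names["value_keyword"] if kind == "keyword" else names["value_text"]
            else:
                name = names["code"]
        elif node.rm_type == "DV_QUANTITY":
            name = names[attribute]
        else:
            name = base
        specs.append(
            FieldSpec(name=name, kind=kind, value_type=value_type, source_path=node.path)
        )
    return specs


def map_template_to_schema(
    template: Template, timestamp_source: Optional[str] = None
) -> IndexSchema:
    """Build the index schema for one composition template.

    ``timestamp_source`` selects the node whose value becomes each entry's
    major time marker; the default is the first date/time node in document
    order.
    """
    fields: list[FieldSpec] = []
    first_temporal: Optional[str] = None

    def walk(node: TemplateNode, context, out: list):
        nonlocal first_temporal
        if node.is_leaf:
            if first_temporal is None and node.rm_type in ("DV_DATE", "DV_DATE_TIME"):
                first_temporal = node.path
            out.extend(_leaf_specs(node, context))
            return
        # structural node
        if node.is_collection:
            nested = FieldSpec(
                name=_field_base(node, context),
                kind="nested",
                source_path=node.path,
            )
            for child in node.children:
                walk(child, (*context, node.ontology_name), nested.children)
            out.append(nested)
        else:
            # slotted archetypes / plain clusters are flattened
            for child in node.children:
                walk(child, (*context, node.ontology_name), out)

    for archetype_id, root in template.imported_archetypes:
        prefix = template.archetype_prefix(archetype_id)
        for child in root.children:
            walk(child, (prefix,), fields)

    schema = IndexSchema(
        index_name=template.concept_set_name,
        fields=fields,
        timestamp_source_path=timestamp_source or first_temporal,
        template_id=template.template_id,
    )
    if not any(True for _ in schema.iter_leaf_fields()):
        raise MappingError(f"template {template.template_id!r} maps to no fields")
    names = schema.all_field_names()
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise MappingError(f"field name collision(s) in index {schema.index_name!r}: {dupes}")
    return schema


def build_schemas(templates: Iterable[Template]) -> dict:
    return {t.concept_set_name: map_template_to_schema(t) for t in templates}


# --------------------------------------------------------------------------
# Elasticsearch mapping emission (7.x dialect)
# --------------------------------------------------------------------------


def _es_property(spec: FieldSpec) -> dict:
    if spec.kind == "nested":
        return {
            "type": "nested",
            "properties": {c.name: _es_property(c) for c in spec.children},
        }
    if spec.kind == "keyword":
        return {"type": "keyword"}
    if spec.kind == "fulltext":
        return {"type": "text"}
    return {"type": _ES_GENERIC_TYPES[spec.value_type]}


def emit_es_mapping(schema: IndexSchema, dialect: str = "7") -> str:
    """Serialize the schema as an Elasticsearch index mapping (JSON text).

    Output is byte-stable for a fixed schema. Only the 7.x dialect is
    implemented; the parameter pins the emitted flavour.
    """
    if not dialect.startswith("7"):
        raise MappingError(f"unsupported Elasticsearch dialect {dialect!r}")
    properties = {
        schema.id_field: {"type": "keyword"},
        "entries": {
            "type": "nested",
            "properties": {
                schema.timestamp_field: {"type": "date"},
                **{spec.name: _es_property(spec) for spec in schema.fields},
            },
        },
    }
    doc = {"mappings": {"properties": properties}}
    return json.dumps(doc, indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# Entry flattening
# --------------------------------------------------------------------------


def _iso(value, path) -> str:
    if isinstance(value, _dt.datetime):
        return value.isoformat()
    if isinstance(value, _dt.date):
        return _dt.datetime.combine(value, _dt.time()).isoformat()
    if isinstance(value, str):
        try:
            _dt.datetime.fromisoformat(value)
        except ValueError as exc:
            raise FlatteningError(f"bad date/time {value!r} at {path}") from exc
        return value
    raise FlatteningError(f"bad date/time {value!r} at {path}")


def _flatten_leaf(node: TemplateNode, context, value, out: dict):
    names = leaf_field_names(node, context)
    rm = node.rm_type
    path = node.path
    if rm == "DV_BOOLEAN":
        if not isinstance(value, bool):
            raise FlatteningError(f"expected boolean at {path}, got {value!r}")
        out[names["value"]] = value
    elif rm == "DV_COUNT":
        if isinstance(value, bool) or not isinstance(value, int):
            raise FlatteningError(f"expected integer at {path}, got {value!r}")
        out[names["value"]] = value
    elif rm == "DV_QUANTITY":
        if isinstance(value, dict):
            magnitude = value.get("magnitude")
            units = value.get("units", node.units)
        else:
            magnitude, units = value, node.units
        if isinstance(magnitude, bool) or not isinstance(magnitude, (int, float)):
            raise FlatteningError(f"expected quantity magnitude at {path}, got {value!r}")
        out[names["magnitude"]] = float(magnitude)
        if units is not None:
            out[names["units"]] = units
    elif rm == "DV_CODED_TEXT":
        if isinstance(value, dict):
            code, label = value.get("code"), value.get("value")
        else:
            code, label = value, None
        if not isinstance(code, str):
            raise FlatteningError(f"expected code at {path}, got {value!r}")
        if label is None:
            for dc in node.defining_codes:
                if dc.code == code:
                    label = dc.label
                    break
        out[names["code"]] = code
        out[names["value_keyword"]] = label if label is not None else code
        out[names["value_text"]] = label if label is not None else code
    elif rm == "DV_TEXT":
        if not isinstance(value, str):
            raise FlatteningError(f"expected text at {path}, got {value!r}")
        out[names["value_keyword"]] = value
        out[names["value_text"]] = value
    elif rm in ("DV_DATE", "DV_DATE_TIME"):
        out[names["value"]] = _iso(value, path)
    elif rm == "DV_DURATION":
        if isinstance(value, _dt.timedelta):
            out[names["value"]] = format_duration(value)
        elif isinstance(value, str):
            parse_duration(value)
            out[names["value"]] = value
        else:
            raise FlatteningError(f"expected duration at {path}, got {value!r}")
    elif rm in ("DV_IDENTIFIER", "DV_URI"):
        if not isinstance(value, str):
            raise FlatteningError(f"expected string at {path}, got {value!r}")
        out[names["value"] if "value" in names else "value"] = value
    else:  # pragma: no cover
        raise FlatteningError(f"unsupported rm_type {rm!r} at {path}")


def flatten_entry(
    template: Template,
    entry_data: dict,
    patient_id: str,
    timestamp=None,
    schema: Optional[IndexSchema] = None,
) -> dict:
    """Flatten one clinical entry to an index sub-document.

    ``entry_data`` maps template node paths to raw values (collection
    clusters map to lists of child-path dicts). Returns the entry dict to
    append to the patient's :class:`DocumentRecord`.
    """
    schema = schema or map_template_to_schema(template)
    nodes = {n.path: n for n in template.nodes()}
    contexts = _node_contexts(template)
    out: dict = {}
    for path, value in entry_data.items():
        node = nodes.get(path)
        if node is None:
            raise FlatteningError(f"no node {path!r} in template {template.template_id}")
        context = contexts[path]
        if node.is_leaf:
            _flatten_leaf(node, context, value, out)
        elif node.is_collection:
            if not isinstance(value, list):
                raise FlatteningError(f"collection node {path!r} expects a list")
            sub_context = (*context, node.ontology_name)
            subdocs = []
            for item in value:
                sub: dict = {}
                for child_path, child_value in item.items():
                    child = nodes.get(child_path)
                    if child is None or not child.path.startswith(path + "/"):
                        raise FlatteningError(
                            f"bad collection member path {child_path!r} under {path!r}"
                        )
                    _flatten_leaf(child, sub_context, child_value, sub)
                subdocs.append(sub)
            out[_field_base(node, context)] = subdocs
        else:
            raise FlatteningError(
                f"slotted node {path!r}: supply its leaf paths directly"
            )
    if timestamp is None and schema.timestamp_source_path in entry_data:
        timestamp = entry_data[schema.timestamp_source_path]
    if timestamp is None:
        raise FlatteningError(
            f"entry has no timestamp and no value at {schema.timestamp_source_path!r}"
        )
    out[TIMESTAMP_FIELD] = _iso(timestamp, "<timestamp>")
    return out


def _node_contexts(template: Template) -> dict:
    """node path -> naming context chain (archetype prefix + cluster names)."""
    contexts: dict = {}

    def walk(node: TemplateNode, context):
        contexts[node.path] = context
        for child in node.children:
            walk(child, (*context, node.ontology_name))

    for archetype_id, root in template.imported_archetypes:
        prefix = template.archetype_prefix(archetype_id)
        contexts[root.path] = ()
        for child in root.children:
            walk(child, (prefix,))

    return contexts


def validate_record(schema: IndexSchema, record: DocumentRecord):
    """Check every populated field exists in the schema with a compatible
    value type; raises FlatteningError otherwise."""
    known = {spec.name: spec for _s, spec in schema.iter_leaf_fields()}
    nested = {spec.name: spec for spec in schema.fields if spec.kind == "nested"}

    def check_value(spec: FieldSpec, value, where):
        vt = spec.value_type
        ok = True
        if vt == "boolean":
            ok = isinstance(value, bool)
        elif vt == "integer":
            ok = isinstance(value, int) and not isinstance(value, bool)
        elif vt == "double":
            ok = isinstance(value, (int, float)) and not isinstance(value, bool)
        elif vt in ("string", "uri", "id", "duration"):
            ok = isinstance(value, str)
        elif vt == "date":
            try:
                _dt.datetime.fromisoformat(value)
            except (TypeError, ValueError):
                ok = False
        if not ok:
            raise FlatteningError(f"field {where} has incompatible value {value!r}")

    for entry in record.entries:
        for key, value in entry.items():
            if key == TIMESTAMP_FIELD:
                check_value(FieldSpec(key, "generic", "date"), value, key)
            elif key in nested:
                if not isinstance(value, list):
                    raise FlatteningError(f"nested field {key} expects a list")
                children = {c.name: c for c in nested[key].children}
                for sub in value:
                    for ck, cv in sub.items():
                        if ck not in children:
                            raise FlatteningError(f"unknown nested field {key}.{ck}")
                        check_value(children[ck], cv, f"{key}.{ck}")
            elif key in known:
                check_value(known[key], value, key)
            else:
                raise FlatteningError(f"unknown field {key!r} in index {schema.index_name}")


# --------------------------------------------------------------------------
# NDJSON document IO
# --------------------------------------------------------------------------


def write_documents(records: Iterable[tuple[str, DocumentRecord]], path):
    """Write (index_name, record) pairs as NDJSON, one document per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for index_name, record in records:
            fh.write(
                json.dumps(
                    {
                        "index": index_name,
                        ID_FIELD: record.patient_id,
                        "entries": record.entries,
                    },
                    sort_keys=False,
                )
            )
            fh.write("\n")


def read_documents(path) -> list[tuple[str, DocumentRecord]]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            out.append(
                (obj["index"], DocumentRecord(obj[ID_FIELD], obj.get("entries", [])))
            )
    return out


def write_bulk_file(records: Iterable[tuple[str, DocumentRecord]], path):
    """Elasticsearch bulk-API file: action line then source line per doc."""
    with open(path, "w", encoding="utf-8") as fh:
        for index_name, record in records:
            fh.write(json.dumps({"index": {"_index": index_name, "_id": record.patient_id}}))
            fh.write("\n")
            fh.write(json.dumps({ID_FIELD: record.patient_id, "entries": record.entries}))
            fh.write("\n")
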