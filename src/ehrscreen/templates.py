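"""Clinical templates and the screening-concept registry.

Templates are read from a small JSON dialect modelling openEHR templates: a
composition container importing one or more entry archetypes, each a tree of
typed attribute nodes. Screening concepts are derived from templates by five
rules:

1. a template is one concept set;
2. every attribute node becomes a concept — the node's ontology name is the
   concept name, its reference-model data type the concept type, its template
   path the concept path (the identifier), and its parent is read off the
   path prefix;
3. ``units`` of a DV_QUANTITY node becomes the concept's unit;
4. every defining code of a DV_CODED_TEXT node becomes a sub-concept under
   that node's concept;
5. all other data types map by rule 2 alone.

StartTime/EndTime are never extracted from templates: they are bound to
concrete temporal nodes per concept at screening time
(:func:`bind_time_attributes`), because which timestamp is "the" event time
(result time vs specimen time, say) depends on the study.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional

from .errors import (
    BindingTypeError,
    RegistryCollisionError,
    TemplateValidationError,
    UnsupportedTypeError,
)

#: Reference-model data types accepted on leaf attribute nodes.
DATA_TYPES = frozenset(
    {
        "DV_BOOLEAN",
        "DV_CODED_TEXT",
        "DV_COUNT",
        "DV_DATE",
        "DV_DATE_TIME",
        "DV_DURATION",
        "DV_IDENTIFIER",
        "DV_QUANTITY",
        "DV_TEXT",
        "DV_URI",
    }
)

#: Structural node types (no value of their own).
STRUCTURAL_TYPES = frozenset({"CLUSTER", "SLOT"})

TEMPORAL_TYPES = frozenset({"DV_DATE", "DV_DATE_TIME"})


def normalize_name(text: str) -> str:
    """Sanitize an ontology name: non-alphanumeric runs become one ``_``."""
    out = re.sub(r"[^0-9A-Za-z]+", "_", text).strip("_")
    return out


def reference_key(text: str) -> str:
    """Case-insensitive lookup key used when resolving expression identifiers."""
    return normalize_name(text).lower()


@dataclass(frozen=True)
class DefiningCode:
    terminology_id: str
    code: str
    label: str


@dataclass
class TemplateNode:
    node_id: str
    ontology_name: str
    rm_type: str
    path: str
    units: Optional[str] = None
    defining_codes: list[DefiningCode] = field(default_factory=list)
    is_collection: bool = False
    children: list["TemplateNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.rm_type in DATA_TYPES

    def walk(self) -> Iterable["TemplateNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Template:
    template_id: str
    concept_set_name: str
    composition_id: str
    imported_archetypes: list[tuple[str, TemplateNode]]

    def nodes(self) -> Iterable[TemplateNode]:
        for _aid, root in self.imported_archetypes:
            yield from root.walk()

    def node_at(self, path: str) -> Optional[TemplateNode]:
        for node in self.nodes():
            if node.path == path:
                return node
        return None

    def archetype_prefix(self, archetype_id: str) -> str:
        """Archetype concept name used to prefix index field names.

        ``openEHR-EHR-EVALUATION.problem_diagnosis.v1`` -> ``problem_diagnosis``.
        """
        parts = archetype_id.split(".")
        if len(parts) >= 2:
            return normalize_name(parts[1])
        return normalize_name(archetype_id)


@dataclass(frozen=True)
class Concept:
    """One screening concept (one registry row).

    ``path`` is the identifier; ``parent`` is the path of the enclosing
    concept. ``code`` is set only on sub-concepts minted from defining codes,
    in which case ``node_path`` points at the coded node carrying the data.
    """

    name: str
    path: str
    type: str
    parent: Optional[str] = None
    unit: Optional[str] = None
    start_time_binding: Optional[str] = None
    end_time_binding: Optional[str] = None
    value: Optional[object] = None
    template_id: Optional[str] = None
    node_path: Optional[str] = None
    code: Optional[DefiningCode] = None

    @property
    def is_coded_subconcept(self) -> bool:
        return self.code is not None


def _require(cond: bool, message: str):
    if not cond:
        raise TemplateValidationError(message)


def _parse_node(obj: dict, parent_path: Optional[str]) -> TemplateNode:
    _require(isinstance(obj, dict), f"node under {parent_path!r} is not an object")
    for key in ("name", "rm_type", "path"):
        _require(key in obj, f"node under {parent_path!r} missing {key!r}")
    path = obj["path"]
    rm_type = obj["rm_type"]
    if rm_type not in DATA_TYPES and rm_type not in STRUCTURAL_TYPES:
        raise UnsupportedTypeError(f"unsupported rm_type {rm_type!r} at {path}")
    if parent_path is not None:
        _require(
            path.startswith(parent_path + "/") and len(path) > len(parent_path) + 1,
            f"child path {path!r} does not extend parent {parent_path!r}",
        )
    units = obj.get("units")
    if units is not None and rm_type != "DV_QUANTITY":
        raise TemplateValidationError(
            f"units declared on non-quantity node at {path} (rm_type {rm_type})"
        )
    raw_codes = obj.get("defining_codes") or []
    if raw_codes and rm_type != "DV_CODED_TEXT":
        raise TemplateValidationError(
            f"defining_codes declared on non-coded node at {path}"
        )
    codes = []
    for c in raw_codes:
        _require(
            isinstance(c, (list, tuple)) and len(c) == 3,
            f"defining code at {path} must be [terminology, code, label]",
        )
        codes.append(DefiningCode(*c))
    children = [_parse_node(ch, path) for ch in obj.get("children", [])]
    if children and rm_type in DATA_TYPES:
        raise TemplateValidationError(f"data-typed node at {path} has children")
    return TemplateNode(
        node_id=obj.get("node_id", ""),
        ontology_name=obj["name"],
        rm_type=rm_type,
        path=path,
        units=units,
        defining_codes=codes,
        is_collection=bool(obj.get("is_collection", False)),
        children=children,
    )


def load_template(source: str | dict) -> Template:
    """Parse and validate one template from JSON text (or a parsed dict)."""
    if isinstance(source, str):
        try:
            obj = json.loads(source)
        except json.JSONDecodeError as exc:
            raise TemplateValidationError(f"template is not valid JSON: {exc}") from exc
    else:
        obj = source
    for key in ("template_id", "concept_set_name", "composition_id", "archetypes"):
        _require(key in obj, f"template missing {key!r}")
    archetypes = obj["archetypes"]
    _require(
        isinstance(archetypes, list) and len(archetypes) >= 1,
        "template must import at least one archetype",
    )
    imported = []
    seen_aids = set()
    for arch in archetypes:
        _require("archetype_id" in arch and "root" in arch, "archetype entry incomplete")
        aid = arch["archetype_id"]
        _require(aid not in seen_aids, f"duplicate archetype_id {aid!r}")
        seen_aids.add(aid)
        imported.append((aid, _parse_node(arch["root"], None)))
    template = Template(
        template_id=obj["template_id"],
        concept_set_name=obj["concept_set_name"],
        composition_id=obj["composition_id"],
        imported_archetypes=imported,
    )
    paths = [n.path for n in template.nodes()]
    dupes = {p for p in paths if paths.count(p) > 1}
    _require(not dupes, f"duplicate node paths in template: {sorted(dupes)}")
    return template


def load_template_file(path) -> Template:
    with open(path, "r", encoding="utf-8") as fh:
        return load_template(fh.read())


def load_demo_templates() -> list[Template]:
    """The bundled seven-template demo set (person, admission, lab test,
    order, imaging examination, physical sign, problem diagnosis)."""
    pkg = resources.files("ehrscreen").joinpath("data/templates")
    templates = []
    for entry in sorted(pkg.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".json"):
            templates.append(load_template(entry.read_text(encoding="utf-8")))
    return templates


def define_concepts(template: Template) -> list[Concept]:
    """Apply the five definition rules to one template.

    Deterministic: document order of nodes, then code-list order.
    """
    concepts: list[Concept] = []
    node_paths = {n.path for n in template.nodes()}

    def parent_of(path: str) -> Optional[str]:
        prefix = path.rsplit("/", 1)[0]
        return prefix if prefix in node_paths else None

    for node in template.nodes():
        concepts.append(
            Concept(
                name=node.ontology_name,
                path=node.path,
                type=node.rm_type,
                parent=parent_of(node.path),
                unit=node.units,
                template_id=template.template_id,
                node_path=node.path,
            )
        )
        for code in node.defining_codes:
            concepts.append(
                Concept(
                    name=code.label,
                    path=f"{node.path}/{code.code}",
                    type="DV_CODED_TEXT",
                    parent=node.path,
                    value=code.code,
                    template_id=template.template_id,
                    node_path=node.path,
                    code=code,
                )
            )
    return concepts


class ConceptRegistry:
    """All screening concepts from a set of templates, keyed by path.

    Concept names are display labels and may repeat across templates; paths
    are the identifiers. ``name_index`` maps a normalized name to every path
    carrying it, so ambiguous bare-name references can be diagnosed.
    """

    def __init__(self):
        self.concepts: dict[str, Concept] = {}
        self.derived: dict[str, object] = {}  # name -> DerivedConcept
        self.name_index: dict[str, list[str]] = {}
        self.templates: dict[str, Template] = {}

    @classmethod
    def from_templates(cls, templates: Iterable[Template]) -> "ConceptRegistry":
        reg = cls()
        for t in templates:
            reg.add_template(t)
        return reg

    def add_template(self, template: Template):
        if template.template_id in self.templates:
            raise RegistryCollisionError(
                f"template {template.template_id!r} already registered"
            )
        self.templates[template.template_id] = template
        for concept in define_concepts(template):
            self.add_concept(concept)

    def add_concept(self, concept: Concept):
        if concept.path in self.concepts:
            raise RegistryCollisionError(f"concept path collision: {concept.path}")
        self.concepts[concept.path] = concept
        self.name_index.setdefault(reference_key(concept.name), []).append(
            concept.path
        )

    def register_derived(self, derived):
        name = derived.name
        if reference_key(name) in self.name_index:
            raise RegistryCollisionError(
                f"derived concept {name!r} collides with a registry concept name"
            )
        if name in self.derived:
            raise RegistryCollisionError(f"derived concept {name!r} already defined")
        self.derived[name] = derived

    def lookup_name(self, name: str) -> list[str]:
        return list(self.name_index.get(reference_key(name), []))

    def template_of(self, concept: Concept) -> Template:
        return self.templates[concept.template_id]

    def bind_time_attributes(
        self,
        concept: Concept,
        start_path: Optional[str] = None,
        end_path: Optional[str] = None,
    ) -> Concept:
        """Bind StartTime/EndTime of a concept to temporal template nodes.

        Returns the updated concept and replaces the registry entry.
        Idempotent for identical paths.
        """
        template = self.templates.get(concept.template_id)
        if template is None:
            raise BindingTypeError(f"concept {concept.path} has no backing template")
        for p in (start_path, end_path):
            if p is None:
                continue
            node = template.node_at(p)
            if node is None:
                raise BindingTypeError(f"no node {p!r} in template {template.template_id}")
            if node.rm_type not in TEMPORAL_TYPES:
                raise BindingTypeError(
                    f"time binding target {p!r} has non-temporal type {node.rm_type}"
                )
        updated = replace(
            concept,
            start_time_binding=start_path if start_path is not None else concept.start_time_binding,
            end_time_binding=end_path if end_path is not None else concept.end_time_binding,
        )
        self.concepts[concept.path] = updated
        return updated

    # -- persistence ------------------------------------------------------

    def to_rows(self) -> list[dict]:
        rows = []
        for path in self.concepts:
            c = self.concepts[path]
            rows.append(
                {
                    "Name": c.name,
                    "Parent": c.parent or "",
                    "Path": c.path,
                    "Type": c.type,
                    "Unit": c.unit or "",
                    "StartTime": c.start_time_binding or "",
                    "EndTime": c.end_time_binding or "",
                    "Value": "" if c.value is None else str(c.value),
                }
            )
        return rows

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.DictWriter(
            buf,
            fieldnames=[
                "Name", "Parent", "Path", "Type", "Unit",
                "StartTime", "EndTime", "Value",
            ],
            lineterminator="\n",
        )
        writer.writeheader()
        for row in self.to_rows():
            writer.writerow(row)
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps({"concepts": self.to_rows()}, indent=2, sort_keys=False)


def bind_time_attributes(registry, concept, start_path=None, end_path=None):
    """Module-level convenience wrapper around the registry method."""
    return registry.bind_time_attributes(concept, start_path, end_path)
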