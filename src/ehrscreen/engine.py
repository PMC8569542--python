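"""Screening-condition execution: reference evaluator, compiler, and IR.

The in-memory reference engine defines the semantics of screening
conditions:

* a condition is an ordered list of groups joined by conjunction; within a
  group, members are joined by disjunction and constraints by conjunction;
* a comparison over a concept with repeated records is existential — the
  patient satisfies it if *some* record does; a chained comparison binds one
  record per referenced concept jointly across the whole chain (so the
  temporal endpoint chains quantify over event pairs, not endpoints
  separately);
* collection functions (count/max/min/first/last) aggregate the patient's
  records ordered by bound StartTime (ties by record position);
* a missing concept or attribute makes any comparison false, and
  ``attached()`` false; ``count()`` of a missing concept is 0;
* ``current_date_time()`` reads the store's injectable clock;
* quantities compare by magnitude; comparing two quantities with different
  unit strings is an error (no unit conversion is attempted).

The compiler translates a condition into a backend-agnostic boolean IR in
two phases: exact single-record atoms become same-entry field-test
predicates (term/range/exists, nested-scoped where the data lives in a
collection cluster), and everything else (cross-record aggregates,
two-concept temporal chains, arithmetic over several concepts) becomes a
candidate-narrowing predicate plus a client-side post-filter that restores
exactness. Dropping the post-filters can only widen the result set, never
exclude a matching patient.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import json
from dataclasses import dataclass, field
from typing import Optional

from .errors import (
    CompilationError,
    EvaluationError,
    UnitMismatchError,
)
from .expressions import (
    AttributeRef,
    Binary,
    Chained,
    ConceptRef,
    Definition,
    FunctionCall,
    Literal,
    Unary,
    COMPARISON_OPS,
    inline_derived,
    parse_expression,
    resolve_references,
    unparse,
)
from .indexing import (
    TIMESTAMP_FIELD,
    DocumentRecord,
    leaf_field_names,
    _field_base,
    _node_contexts,
)
from .templates import Concept, ConceptRegistry

# --------------------------------------------------------------------------
# Patient store
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Quantity:
    magnitude: float
    units: Optional[str] = None


@dataclass(frozen=True)
class Instance:
    """One record of a concept for one patient."""

    value: object
    start: _dt.datetime
    end: _dt.datetime
    order: tuple  # tie-break key (entry position, sub-document position)


class PatientStore:
    """In-memory patient documents per index plus evaluation context.

    Carries the concept registry, the index schemas, and an injectable
    clock so conditions mentioning ``current_date_time()`` are
    reproducible.
    """

    def __init__(
        self,
        registry: ConceptRegistry,
        schemas: dict,
        clock: Optional[_dt.datetime] = None,
    ):
        self.registry = registry
        self.schemas = schemas
        self.clock = clock or _dt.datetime(2024, 1, 1)
        self.documents: dict = {index: {} for index in schemas}
        self._binding_cache: dict = {}
        self._instance_cache: dict = {}

    def add_record(self, index: str, record: DocumentRecord):
        self.documents.setdefault(index, {})[record.patient_id] = record
        self._instance_cache.clear()

    def add_entry(self, index: str, patient_id: str, entry: dict):
        docs = self.documents.setdefault(index, {})
        if patient_id not in docs:
            docs[patient_id] = DocumentRecord(patient_id)
        docs[patient_id].entries.append(entry)
        self._instance_cache.clear()

    def patient_ids(self) -> list:
        ids = set()
        for docs in self.documents.values():
            ids.update(docs)
        return sorted(ids)

    def doc(self, index: str, patient_id: str) -> Optional[DocumentRecord]:
        return self.documents.get(index, {}).get(patient_id)

    # -- concept/field binding -------------------------------------------

    def binding(self, concept_path: str) -> "_Binding":
        if concept_path not in self._binding_cache:
            self._binding_cache[concept_path] = _build_binding(
                self.registry, concept_path
            )
        return self._binding_cache[concept_path]

    def instances(self, patient_id: str, concept_path: str) -> list:
        key = (patient_id, concept_path)
        if key not in self._instance_cache:
            self._instance_cache[key] = _extract_instances(
                self, self.binding(concept_path), patient_id
            )
        return self._instance_cache[key]


@dataclass(frozen=True)
class _Binding:
    """How a concept maps onto index fields."""

    concept: Concept
    index: str
    rm_type: str
    fields: dict  # attribute -> field name (leaf_field_names)
    nested_path: Optional[str]  # collection-cluster field, if any
    start_field: Optional[str]  # None -> entry timestamp
    end_field: Optional[str]
    code: Optional[str]  # defining code for coded sub-concepts
    units: Optional[str]


def _build_binding(registry: ConceptRegistry, concept_path: str) -> _Binding:
    concept = registry.concepts.get(concept_path)
    if concept is None:
        raise EvaluationError(f"unknown concept path {concept_path!r}")
    template = registry.templates[concept.template_id]
    node = template.node_at(concept.node_path)
    if node is None or not node.is_leaf:
        raise EvaluationError(
            f"concept {concept_path!r} is structural; reference a leaf concept"
        )
    contexts = _node_contexts(template)
    context = contexts[node.path]
    fields = leaf_field_names(node, context)

    # nested scope: nearest collection-cluster ancestor
    nested_path = None
    probe = node.path.rsplit("/", 1)[0]
    while probe:
        ancestor = template.node_at(probe)
        if ancestor is not None and ancestor.is_collection:
            nested_path = _field_base(ancestor, contexts[ancestor.path])
            break
        probe = probe.rsplit("/", 1)[0] if "/" in probe else ""

    def time_field(binding_path):
        if binding_path is None:
            return None
        tnode = template.node_at(binding_path)
        if tnode is None:
            raise EvaluationError(f"time binding {binding_path!r} not in template")
        return leaf_field_names(tnode, contexts[tnode.path])["value"]

    return _Binding(
        concept=concept,
        index=template.concept_set_name,
        rm_type=node.rm_type,
        fields=fields,
        nested_path=nested_path,
        start_field=time_field(concept.start_time_binding),
        end_field=time_field(concept.end_time_binding),
        code=concept.code.code if concept.code else None,
        units=node.units,
    )


def _coerce_field_value(binding: _Binding, source: dict):
    rm = binding.rm_type
    if rm == "DV_QUANTITY":
        magnitude = source.get(binding.fields["magnitude"])
        if magnitude is None:
            return None
        return Quantity(magnitude, source.get(binding.fields["units"], binding.units))
    if rm in ("DV_TEXT", "DV_CODED_TEXT"):
        return source.get(binding.fields["value_keyword"])
    if rm in ("DV_DATE", "DV_DATE_TIME"):
        raw = source.get(binding.fields["value"])
        return _dt.datetime.fromisoformat(raw) if raw is not None else None
    if rm == "DV_DURATION":
        raw = source.get(binding.fields["value"])
        if raw is None:
            return None
        from .expressions import parse_duration

        return parse_duration(raw)
    return source.get(binding.fields["value"])


def _entry_times(store, binding: _Binding, entry: dict):
    def read(field_name):
        raw = entry.get(field_name) if field_name else None
        if raw is None:
            raw = entry.get(TIMESTAMP_FIELD)
        return _dt.datetime.fromisoformat(raw) if raw is not None else None

    start = read(binding.start_field)
    end = read(binding.end_field) if binding.end_field else start
    return start, end


def _extract_instances(store: PatientStore, binding: _Binding, patient_id: str):
    doc = store.doc(binding.index, patient_id)
    if doc is None:
        return []
    out = []
    for entry_idx, entry in enumerate(doc.entries):
        start, end = _entry_times(store, binding, entry)
        sources = (
            [(sub_idx, sub) for sub_idx, sub in enumerate(entry.get(binding.nested_path) or [])]
            if binding.nested_path
            else [(0, entry)]
        )
        for sub_idx, source in sources:
            if binding.code is not None:
                if source.get(binding.fields["code"]) != binding.code:
                    continue
            value = _coerce_field_value(binding, source)
            if value is None and binding.code is None:
                continue
            out.append(Instance(value, start, end, (entry_idx, sub_idx)))
    out.sort(key=lambda i: (i.start or _dt.datetime.min, i.order))
    return out


# --------------------------------------------------------------------------
# Screening conditions
# --------------------------------------------------------------------------


@dataclass
class Group:
    """Members are OR-ed; constraints are AND-ed on top."""

    members: list = field(default_factory=list)  # expression text or AST
    constraints: list = field(default_factory=list)


@dataclass
class ScreeningCondition:
    groups: list = field(default_factory=list)

    @classmethod
    def from_json(cls, text: str) -> "ScreeningCondition":
        obj = json.loads(text)
        return cls(
            groups=[
                Group(
                    members=list(g.get("members", [])),
                    constraints=list(g.get("constraints", [])),
                )
                for g in obj["groups"]
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "groups": [
                    {
                        "members": [m if isinstance(m, str) else unparse(m) for m in g.members],
                        "constraints": [
                            c if isinstance(c, str) else unparse(c) for c in g.constraints
                        ],
                    }
                    for g in self.groups
                ]
            },
            indent=2,
        )


def _as_ast(item, registry: ConceptRegistry):
    node = parse_expression(item) if isinstance(item, str) else item
    if isinstance(node, Definition):
        raise EvaluationError("a screening condition cannot contain definitions")
    return resolve_references(node, registry)


# --------------------------------------------------------------------------
# Reference evaluator
# --------------------------------------------------------------------------


class _Missing(Exception):
    """Internal: a binding lacks a needed value; the candidate fails."""


_CHAIN_DESUGAR = {"<": "<", "<=": "<=", ">": ">", ">=": ">=", "=": "="}


def _is_comparison(node) -> bool:
    return (isinstance(node, Binary) and node.op in COMPARISON_OPS) or isinstance(
        node, Chained
    )


def _instance_refs(node, acc: dict, in_aggregate=False):
    """Ordered unique concept paths needing per-record bindings.

    ``acc`` maps path -> "instance" | "aggregate" | "count".
    """
    if isinstance(node, ConceptRef):
        if node.derived:
            raise EvaluationError(f"unexpanded derived concept {node.name!r}")
        if not in_aggregate:
            acc.setdefault(node.path, "instance")
    elif isinstance(node, AttributeRef):
        _instance_refs(node.base, acc, in_aggregate)
    elif isinstance(node, FunctionCall):
        if node.name in ("count",):
            acc.setdefault(node.args[0].path, "count")
        elif node.name in ("max", "min", "first", "last"):
            acc.setdefault(node.args[0].path, "aggregate")
        elif node.name in ("attached", "contains"):
            acc.setdefault(node.args[0].path, "aggregate")
            for a in node.args[1:]:
                _instance_refs(a, acc, in_aggregate)
        else:
            for a in node.args:
                _instance_refs(a, acc, in_aggregate)
    elif isinstance(node, Unary):
        _instance_refs(node.operand, acc, in_aggregate)
    elif isinstance(node, Binary):
        _instance_refs(node.lhs, acc, in_aggregate)
        _instance_refs(node.rhs, acc, in_aggregate)
    elif isinstance(node, Chained):
        for t in node.terms:
            _instance_refs(t, acc, in_aggregate)


def _compare(op: str, a, b):
    if isinstance(a, Quantity) and isinstance(b, Quantity):
        if (a.units or "") != (b.units or ""):
            raise UnitMismatchError(
                f"cannot compare quantities with units {a.units!r} and {b.units!r}"
            )
        a, b = a.magnitude, b.magnitude
    elif isinstance(a, Quantity):
        a = a.magnitude
    elif isinstance(b, Quantity):
        b = b.magnitude
    if isinstance(a, _dt.datetime) and isinstance(b, str):
        b = _dt.datetime.fromisoformat(b)
    if isinstance(b, _dt.datetime) and isinstance(a, str):
        a = _dt.datetime.fromisoformat(a)
    try:
        if op == "<":
            return a < b
        if op == "<=":
            return a <= b
        if op == ">":
            return a > b
        if op == ">=":
            return a >= b
        if op == "=":
            return a == b
        if op == "!=":
            return a != b
    except TypeError as exc:
        raise EvaluationError(f"incomparable values {a!r} and {b!r}") from exc
    raise EvaluationError(f"unknown comparison {op!r}")  # pragma: no cover


def _magnitude(x):
    return x.magnitude if isinstance(x, Quantity) else x


def _arith(op: str, a, b):
    a, b = _magnitude(a), _magnitude(b)
    try:
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            return a / b
        if op == "^":
            return a ** b
    except (TypeError, ZeroDivisionError) as exc:
        raise EvaluationError(f"bad arithmetic {a!r} {op} {b!r}") from exc
    raise EvaluationError(f"unknown operator {op!r}")  # pragma: no cover


class _PatientEval:
    """Evaluates a resolved AST for one patient (or, with no patient, only
    record-free expressions — used by the compiler for constant folding)."""

    def __init__(self, store: Optional[PatientStore], patient_id: Optional[str], clock=None):
        self.store = store
        self.pid = patient_id
        self.clock = clock or (store.clock if store else None)

    def _instances(self, path: str):
        if self.store is None or self.pid is None:
            raise _Missing()
        return self.store.instances(self.pid, path)

    # -- boolean level ----------------------------------------------------

    def truth(self, node) -> bool:
        if isinstance(node, Binary) and node.op in ("and", "or"):
            lhs = self.truth(node.lhs)
            if node.op == "and":
                return lhs and self.truth(node.rhs)
            return lhs or self.truth(node.rhs)
        if isinstance(node, Unary) and node.op == "not":
            return not self.truth(node.operand)
        if isinstance(node, ConceptRef):
            if node.derived:
                # lazy expansion of derived concepts in boolean position
                return self.truth(self.store.registry.derived[node.name].expression)
            return len(self._instances_safe(node.path)) > 0
        if isinstance(node, FunctionCall) and node.name == "attached":
            ref = node.args[0]
            if isinstance(ref, ConceptRef) and ref.derived:
                return self.truth(self.store.registry.derived[ref.name].expression)
            return len(self._instances_safe(ref.path)) > 0
        if isinstance(node, FunctionCall) and node.name == "contains":
            return self._contains(node)
        if isinstance(node, Literal) and isinstance(node.value, bool):
            return node.value
        if _is_comparison(node):
            return self._atom(node)
        raise EvaluationError(f"expression is not boolean: {unparse(node)}")

    def _instances_safe(self, path):
        try:
            return self._instances(path)
        except _Missing:
            return []

    def _contains(self, node) -> bool:
        ref, needle = node.args
        if not isinstance(ref, ConceptRef) or not isinstance(needle, Literal):
            raise EvaluationError("contains(concept, \"text\") expects a concept and a string")
        text = str(needle.value).lower()
        for inst in self._instances_safe(ref.path):
            if isinstance(inst.value, str) and text in inst.value.lower():
                return True
        return False

    # -- comparison atoms (joint existential binding) ---------------------

    def _atom(self, node) -> bool:
        if self.store is not None:
            node = inline_derived(node, self.store.registry)
        refs: dict = {}
        _instance_refs(node, refs)
        bound = [p for p, kind in refs.items() if kind == "instance"]
        if not bound:
            try:
                return bool(self._chain_value(node, {}))
            except _Missing:
                return False
        pools = [self._instances_safe(p) for p in bound]
        for combo in itertools.product(*pools):
            env = dict(zip(bound, combo))
            try:
                if self._chain_value(node, env):
                    return True
            except _Missing:
                continue
        return False

    def _chain_value(self, node, env) -> bool:
        if isinstance(node, Chained):
            for op, lhs, rhs in zip(node.ops, node.terms, node.terms[1:]):
                if not _compare(op, self.scalar(lhs, env), self.scalar(rhs, env)):
                    return False
            return True
        if isinstance(node, Binary) and node.op in COMPARISON_OPS:
            return _compare(node.op, self.scalar(node.lhs, env), self.scalar(node.rhs, env))
        return bool(self.scalar(node, env))

    # -- scalar level ------------------------------------------------------

    def scalar(self, node, env):
        if isinstance(node, Literal):
            return node.value
        if isinstance(node, ConceptRef):
            inst = env.get(node.path)
            if inst is None or inst.value is None:
                raise _Missing()
            return inst.value
        if isinstance(node, AttributeRef):
            inst = env.get(node.base.path)
            if inst is None:
                raise _Missing()
            value = {
                "StartTime": inst.start,
                "EndTime": inst.end,
                "Value": inst.value,
            }[node.attr]
            if value is None:
                raise _Missing()
            return value
        if isinstance(node, FunctionCall):
            return self._function(node, env)
        if isinstance(node, Unary):
            if node.op == "-":
                v = self.scalar(node.operand, env)
                return -_magnitude(v) if not isinstance(v, _dt.timedelta) else -v
            raise EvaluationError("'not' used in a scalar position")
        if isinstance(node, Binary):
            if node.op in COMPARISON_OPS or node.op in ("and", "or"):
                raise EvaluationError(
                    f"boolean expression used as a value: {unparse(node)}"
                )
            return _arith(node.op, self.scalar(node.lhs, env), self.scalar(node.rhs, env))
        raise EvaluationError(f"cannot evaluate {node!r}")

    def _function(self, node, env):
        name = node.name
        if name == "current_date_time":
            if self.clock is None:
                raise EvaluationError("no clock configured")
            return self.clock
        if name == "diff":
            a = self.scalar(node.args[0], env)
            b = self.scalar(node.args[1], env)
            if not isinstance(a, _dt.datetime) or not isinstance(b, _dt.datetime):
                raise EvaluationError("diff() expects two date/time values")
            return a - b
        if name in ("count", "max", "min", "first", "last"):
            ref = node.args[0]
            insts = self._instances_safe(ref.path)
            if name == "count":
                return len(insts)
            if not insts:
                raise _Missing()
            values = [i.value for i in insts if i.value is not None]
            if not values:
                raise _Missing()
            if name == "first":
                return insts[0].value
            if name == "last":
                return insts[-1].value
            units = {v.units for v in values if isinstance(v, Quantity)}
            if len(units) > 1:
                raise UnitMismatchError(
                    f"{name}() over mixed units {sorted(u or '' for u in units)}"
                )
            pick = max if name == "max" else min
            return pick(values, key=_magnitude)
        if name in ("attached", "contains"):
            return self.truth(node)
        raise EvaluationError(f"unknown function {name!r}")  # pragma: no cover


def evaluate(condition_or_expression, store: PatientStore) -> set:
    """Patients satisfying a condition, group, or single expression."""
    pids = store.patient_ids()
    if isinstance(condition_or_expression, ScreeningCondition):
        asts = [
            _group_ast(g, store.registry) for g in condition_or_expression.groups
        ]
        if not asts:
            raise EvaluationError("condition has no groups")
        return {
            pid
            for pid in pids
            if all(_PatientEval(store, pid).truth(a) for a in asts)
        }
    if isinstance(condition_or_expression, Group):
        ast = _group_ast(condition_or_expression, store.registry)
        return {pid for pid in pids if _PatientEval(store, pid).truth(ast)}
    ast = _as_ast(condition_or_expression, store.registry)
    return {pid for pid in pids if _PatientEval(store, pid).truth(ast)}


def _group_ast(group: Group, registry: ConceptRegistry):
    members = [_as_ast(m, registry) for m in group.members]
    constraints = [_as_ast(c, registry) for c in group.constraints]
    node = None
    if members:
        node = members[0]
        for m in members[1:]:
            node = Binary("or", node, m)
    for c in constraints:
        node = c if node is None else Binary("and", node, c)
    if node is None:
        raise EvaluationError("empty group")
    return node


@dataclass
class ScreenResult:
    patients: set
    group_counts: list


def screen(
    condition: ScreeningCondition, store: PatientStore, schemas: Optional[dict] = None
) -> ScreenResult:
    """Run a condition; also count each group independently, mirroring the
    per-group feedback a condition builder shows while editing."""
    if not condition.groups:
        raise EvaluationError("condition has no groups")
    counts = [len(evaluate(g, store)) for g in condition.groups]
    return ScreenResult(patients=evaluate(condition, store), group_counts=counts)


# --------------------------------------------------------------------------
# Query IR
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldTest:
    field: str
    op: str  # exists | eq | ne | lt | le | gt | ge | contains
    value: object = None


@dataclass(frozen=True)
class IREntry:
    """Same-entry conjunction of field tests (same sub-document for the
    nested part)."""

    index: str
    entry_tests: tuple = ()
    nested_path: Optional[str] = None
    nested_tests: tuple = ()


@dataclass(frozen=True)
class IRPostFilter:
    expression: object  # resolved, inlined AST
    el_text: str


@dataclass(frozen=True)
class IRBool:
    op: str  # and | or | not
    children: tuple


@dataclass(frozen=True)
class IRConst:
    value: bool


@dataclass
class QueryIR:
    groups: list  # one IR tree per condition group
    indexes: list


def _ir_and(children):
    kids = [c for c in children if not (isinstance(c, IRConst) and c.value)]
    if any(isinstance(c, IRConst) and not c.value for c in kids):
        return IRConst(False)
    if not kids:
        return IRConst(True)
    if len(kids) == 1:
        return kids[0]
    return IRBool("and", tuple(kids))


def _ir_or(children):
    kids = [c for c in children if not (isinstance(c, IRConst) and not c.value)]
    if any(isinstance(c, IRConst) and c.value for c in kids):
        return IRConst(True)
    if not kids:
        return IRConst(False)
    if len(kids) == 1:
        return kids[0]
    return IRBool("or", tuple(kids))


def _has_postfilter(node) -> bool:
    if isinstance(node, IRPostFilter):
        return True
    if isinstance(node, IRBool):
        return any(_has_postfilter(c) for c in node.children)
    return False


_CMP_TO_TEST = {"<": "lt", "<=": "le", ">": "gt", ">=": "ge", "=": "eq", "!=": "ne"}
_FLIP = {"<": ">", "<=": ">=", ">": "<", ">=": "<=", "=": "=", "!=": "!="}


class _Compiler:
    def __init__(self, registry: ConceptRegistry, schemas: dict, clock=None):
        self.registry = registry
        self.schemas = schemas
        self.clock = clock
        self._const = _PatientEval(None, None, clock=clock)

    # -- helpers ----------------------------------------------------------

    def _binding(self, path: str) -> _Binding:
        try:
            binding = _build_binding(self.registry, path)
        except EvaluationError as exc:
            raise CompilationError(str(exc)) from exc
        if binding.index not in self.schemas:
            raise CompilationError(
                f"concept {path!r} targets unmapped index {binding.index!r}"
            )
        return binding

    def _presence(self, binding: _Binding) -> IREntry:
        """Entry test asserting one record of the concept exists."""
        tests = []
        if binding.code is not None:
            tests.append(FieldTest(binding.fields["code"], "eq", binding.code))
        else:
            main = self._main_field(binding)
            tests.append(FieldTest(main, "exists"))
        if binding.nested_path:
            return IREntry(binding.index, (), binding.nested_path, tuple(tests))
        return IREntry(binding.index, tuple(tests))

    def _main_field(self, binding: _Binding) -> str:
        rm = binding.rm_type
        if rm == "DV_QUANTITY":
            return binding.fields["magnitude"]
        if rm in ("DV_TEXT", "DV_CODED_TEXT"):
            return binding.fields["value_keyword"]
        return binding.fields["value"]

    def _const_scalar(self, node):
        try:
            return self._const.scalar(node, {})
        except (_Missing, EvaluationError):
            return None

    def _is_ref_free(self, node) -> bool:
        refs: dict = {}
        _instance_refs(node, refs)
        return not refs

    # -- atom compilation --------------------------------------------------

    def atom(self, node):
        """One comparison / existence atom to IR. Falls back to candidate
        predicates + post-filter when no exact field form exists."""
        if isinstance(node, ConceptRef) or (
            isinstance(node, FunctionCall) and node.name == "attached"
        ):
            ref = node if isinstance(node, ConceptRef) else node.args[0]
            return self._presence(self._binding(ref.path))
        if isinstance(node, FunctionCall) and node.name == "contains":
            ref, needle = node.args
            if not isinstance(needle, Literal) or not isinstance(needle.value, str):
                raise CompilationError("contains() needs a literal string")
            binding = self._binding(ref.path)
            if binding.rm_type not in ("DV_TEXT", "DV_CODED_TEXT"):
                raise CompilationError("contains() needs a text-valued concept")
            test = FieldTest(binding.fields["value_text"], "contains", needle.value)
            if binding.nested_path:
                return IREntry(binding.index, (), binding.nested_path, (test,))
            return IREntry(binding.index, (test,))
        if isinstance(node, Literal) and isinstance(node.value, bool):
            return IRConst(node.value)
        if _is_comparison(node):
            exact = self._exact_comparison(node)
            if exact is not None:
                return exact
            return self._fallback(node)
        raise CompilationError(f"cannot compile atom {unparse(node)}")

    def _exact_comparison(self, node):
        """Single-concept comparison/chain -> one same-entry IREntry."""
        pairs = (
            list(zip(node.ops, node.terms, node.terms[1:]))
            if isinstance(node, Chained)
            else [(node.op, node.lhs, node.rhs)]
        )
        refs: dict = {}
        _instance_refs(node, refs)
        kinds = set(refs.values())
        if not refs:
            try:
                ok = self._const.truth(node)
            except (_Missing, EvaluationError):
                return None
            return IRConst(bool(ok))
        if len(refs) != 1 or kinds != {"instance"}:
            return None
        (path,) = refs
        binding = self._binding(path)
        tests = []
        if binding.code is not None:
            tests.append(FieldTest(binding.fields["code"], "eq", binding.code))
        for op, lhs, rhs in pairs:
            test = self._field_test(binding, op, lhs, rhs)
            if test is None:
                return None
            tests.append(test)
        if binding.nested_path:
            nested = [t for t in tests]
            return IREntry(binding.index, (), binding.nested_path, tuple(nested))
        return IREntry(binding.index, tuple(tests))

    def _field_test(self, binding: _Binding, op, lhs, rhs):
        lhs_free, rhs_free = self._is_ref_free(lhs), self._is_ref_free(rhs)
        if lhs_free and not rhs_free:
            op = _FLIP[op]
            lhs, rhs = rhs, lhs
        elif rhs_free and not lhs_free:
            pass
        else:
            return None
        # lhs references the concept, rhs is record-free
        lhs = self._rewrite_clock_diff(lhs, op, rhs)
        if lhs is None:
            return None
        concept_side, op, literal_side = lhs
        field = self._field_for(binding, concept_side)
        if field is None:
            return None
        value = self._const_scalar(literal_side)
        if value is None:
            return None
        if isinstance(value, Quantity):
            value = value.magnitude
        temporal = binding.rm_type in ("DV_DATE", "DV_DATE_TIME") or (
            isinstance(concept_side, AttributeRef)
            and concept_side.attr in ("StartTime", "EndTime")
        )
        if temporal and isinstance(value, str):
            # compare as dates, not strings: "2020-01-01" must equal
            # "2020-01-01T00:00:00"
            try:
                value = _dt.datetime.fromisoformat(value)
            except ValueError:
                return None
        return FieldTest(field, _CMP_TO_TEST[op], value)

    def _rewrite_clock_diff(self, concept_expr, op, literal_expr):
        """Rewrite clock-relative forms to direct field comparisons.

        ``diff(current_date_time(), x) cmp D``        -> ``x flip(cmp) clock - D``
        ``diff(current_date_time(), x) / D1 cmp n``   -> ``x flip(cmp) clock - n*D1``

        Requires an injected clock; otherwise the atom stays inexact and
        falls through to a post-filter.
        """
        node = concept_expr

        def is_clock_diff(n):
            return (
                isinstance(n, FunctionCall)
                and n.name == "diff"
                and isinstance(n.args[0], FunctionCall)
                and n.args[0].name == "current_date_time"
            )

        if isinstance(node, (ConceptRef, AttributeRef)):
            return node, op, literal_expr
        if self.clock is None:
            return None
        if is_clock_diff(node):
            d = self._const_scalar(literal_expr)
            if not isinstance(d, _dt.timedelta):
                return None
            return node.args[1], _FLIP[op], Literal(self.clock - d)
        if (
            isinstance(node, Binary)
            and node.op == "/"
            and is_clock_diff(node.lhs)
        ):
            unit = self._const_scalar(node.rhs)
            n = self._const_scalar(literal_expr)
            if not isinstance(unit, _dt.timedelta) or not isinstance(n, (int, float)) or unit <= _dt.timedelta(0):
                return None
            return node.lhs.args[1], _FLIP[op], Literal(self.clock - n * unit)
        return None

    def _field_for(self, binding: _Binding, concept_side):
        if isinstance(concept_side, ConceptRef):
            return self._main_field(binding)
        if isinstance(concept_side, AttributeRef):
            attr = concept_side.attr
            if attr == "Value":
                return self._main_field(binding)
            field = binding.start_field if attr == "StartTime" else binding.end_field
            if field is None and attr == "EndTime" and binding.start_field is not None:
                field = binding.start_field
            if binding.nested_path is not None:
                # time fields live at entry level; a nested-scope test cannot
                # see them in the same sub-document scope
                return None
            return field or TIMESTAMP_FIELD
        return None

    def _fallback(self, node):
        """Candidate presence predicates + exact client-side post-filter."""
        refs: dict = {}
        _instance_refs(node, refs)
        candidates = []
        for path, kind in refs.items():
            if kind == "count":
                continue  # count()=0 can be true with no records
            candidates.append(self._presence(self._binding(path)))
        post = IRPostFilter(node, unparse(node))
        return _ir_and(candidates + [post])

    # -- boolean compilation ----------------------------------------------

    def compile_bool(self, node):
        if isinstance(node, Binary) and node.op in ("and", "or"):
            lhs, rhs = self.compile_bool(node.lhs), self.compile_bool(node.rhs)
            return _ir_and([lhs, rhs]) if node.op == "and" else _ir_or([lhs, rhs])
        if isinstance(node, Unary) and node.op == "not":
            child = self.compile_bool(node.operand)
            if _has_postfilter(child):
                return IRPostFilter(node, unparse(node))
            if isinstance(child, IRConst):
                return IRConst(not child.value)
            return IRBool("not", (child,))
        return self.atom(node)


def compile_condition(
    condition: ScreeningCondition,
    registry: ConceptRegistry,
    schemas: dict,
    clock: Optional[_dt.datetime] = None,
) -> QueryIR:
    """Translate a screening condition into the backend-agnostic query IR.

    Index predicates over-approximate the condition; post-filters restore
    exactness. Pass the evaluation clock to enable exact translation of
    clock-relative (age, recency) comparisons.
    """
    if not condition.groups:
        raise CompilationError("condition has no groups")
    compiler = _Compiler(registry, schemas, clock=clock)
    trees = []
    for group in condition.groups:
        if not group.members and not group.constraints:
            raise CompilationError("empty group")
        ast = _group_ast(group, registry)
        ast = inline_derived(ast, registry)
        trees.append(compiler.compile_bool(ast))
    indexes = sorted(_collect_indexes(trees))
    return QueryIR(groups=trees, indexes=indexes)


#: spec-facing alias — the operation is conventionally called "compile".
compile = compile_condition


def _collect_indexes(trees) -> set:
    out = set()

    def walk(node):
        if isinstance(node, IREntry):
            out.add(node.index)
        elif isinstance(node, IRBool):
            for c in node.children:
                walk(c)

    for t in trees:
        walk(t)
    return out


# --------------------------------------------------------------------------
# IR interpretation (reference back end standing in for a search server)
# --------------------------------------------------------------------------


def _test_value(test: FieldTest, raw):
    if test.op == "exists":
        return raw is not None
    if raw is None:
        return False
    if test.op == "contains":
        return isinstance(raw, str) and str(test.value).lower() in raw.lower()
    value = test.value
    if isinstance(value, _dt.datetime) and isinstance(raw, str):
        try:
            raw = _dt.datetime.fromisoformat(raw)
        except ValueError:
            return False
    try:
        if test.op == "eq":
            return raw == value
        if test.op == "ne":
            return raw != value
        if test.op == "lt":
            return raw < value
        if test.op == "le":
            return raw <= value
        if test.op == "gt":
            return raw > value
        if test.op == "ge":
            return raw >= value
    except TypeError:
        return False
    raise EvaluationError(f"unknown field test {test.op!r}")  # pragma: no cover


def _entry_matches(node: IREntry, entry: dict) -> bool:
    for test in node.entry_tests:
        if not _test_value(test, entry.get(test.field)):
            return False
    if node.nested_path is not None:
        subdocs = entry.get(node.nested_path) or []
        return any(
            all(_test_value(t, sub.get(t.field)) for t in node.nested_tests)
            for sub in subdocs
        )
    return True


def _run_node(node, store: PatientStore, pid: str, drop_postfilters=False) -> bool:
    if isinstance(node, IRConst):
        return node.value
    if isinstance(node, IRBool):
        if node.op == "and":
            return all(_run_node(c, store, pid, drop_postfilters) for c in node.children)
        if node.op == "or":
            return any(_run_node(c, store, pid, drop_postfilters) for c in node.children)
        return not _run_node(node.children[0], store, pid, drop_postfilters)
    if isinstance(node, IREntry):
        if node.index not in store.schemas:
            raise EvaluationError(f"IR references unmapped index {node.index!r}")
        for test in node.entry_tests + node.nested_tests:
            if store.schemas[node.index].field_by_name(test.field) is None and test.field != TIMESTAMP_FIELD:
                raise EvaluationError(
                    f"field {test.field!r} absent from index {node.index!r}"
                )
        doc = store.doc(node.index, pid)
        if doc is None:
            return False
        return any(_entry_matches(node, entry) for entry in doc.entries)
    if isinstance(node, IRPostFilter):
        if drop_postfilters:
            return True
        return _PatientEval(store, pid).truth(node.expression)
    raise EvaluationError(f"unknown IR node {node!r}")  # pragma: no cover


def run_ir(ir: QueryIR, store: PatientStore, drop_postfilters: bool = False) -> set:
    """Execute the IR against a store: index predicates, then post-filters.

    With ``drop_postfilters=True`` only the candidate predicates run,
    yielding the (super)set the search backend alone would return.
    """
    return {
        pid
        for pid in store.patient_ids()
        if all(_run_node(tree, store, pid, drop_postfilters) for tree in ir.groups)
    }


# --------------------------------------------------------------------------
# Elasticsearch Query DSL emission (7.x)
# --------------------------------------------------------------------------


def _es_value(value):
    if isinstance(value, _dt.datetime):
        return value.isoformat()
    return value


def _es_test(test: FieldTest, scope: str) -> dict:
    field_name = f"{scope}.{test.field}"
    if test.op == "exists":
        return {"exists": {"field": field_name}}
    if test.op == "eq":
        return {"term": {field_name: _es_value(test.value)}}
    if test.op == "ne":
        return {"bool": {"must_not": [{"term": {field_name: _es_value(test.value)}}]}}
    if test.op == "contains":
        return {"match": {field_name: _es_value(test.value)}}
    range_op = {"lt": "lt", "le": "lte", "gt": "gt", "ge": "gte"}[test.op]
    return {"range": {field_name: {range_op: _es_value(test.value)}}}


def _es_entry(node: IREntry) -> dict:
    clauses = [_es_test(t, "entries") for t in node.entry_tests]
    if node.nested_path is not None:
        inner_scope = f"entries.{node.nested_path}"
        inner = [_es_test(t, inner_scope) for t in node.nested_tests]
        clauses.append(
            {"nested": {"path": inner_scope, "query": {"bool": {"filter": inner}}}}
        )
    query = clauses[0] if len(clauses) == 1 else {"bool": {"filter": clauses}}
    return {"nested": {"path": "entries", "query": query}}


def _project(node, index: str, over: bool):
    """Project an IR tree onto one index: foreign leaves and post-filters
    become True when over-approximating (False under negation)."""
    if isinstance(node, IRConst):
        return node
    if isinstance(node, IRPostFilter):
        return IRConst(over)
    if isinstance(node, IREntry):
        return node if node.index == index else IRConst(over)
    if isinstance(node, IRBool):
        if node.op == "not":
            return _ir_not(_project(node.children[0], index, not over))
        kids = [_project(c, index, over) for c in node.children]
        return _ir_and(kids) if node.op == "and" else _ir_or(kids)
    raise CompilationError(f"unknown IR node {node!r}")  # pragma: no cover


def _ir_not(child):
    if isinstance(child, IRConst):
        return IRConst(not child.value)
    return IRBool("not", (child,))


def _es_render(node) -> dict:
    if isinstance(node, IRConst):
        if node.value:
            return {"match_all": {}}
        return {"bool": {"must_not": [{"match_all": {}}]}}
    if isinstance(node, IREntry):
        return _es_entry(node)
    if isinstance(node, IRBool):
        if node.op == "and":
            return {"bool": {"filter": [_es_render(c) for c in node.children]}}
        if node.op == "or":
            return {
                "bool": {
                    "should": [_es_render(c) for c in node.children],
                    "minimum_should_match": 1,
                }
            }
        return {"bool": {"must_not": [_es_render(node.children[0])]}}
    raise CompilationError(f"cannot render {node!r}")  # pragma: no cover


def _group_indexes(tree) -> set:
    out = set()

    def walk(n):
        if isinstance(n, IREntry):
            out.add(n.index)
        elif isinstance(n, IRBool):
            for c in n.children:
                walk(c)

    walk(tree)
    return out


def _postfilter_texts(tree) -> list:
    out = []

    def walk(n):
        if isinstance(n, IRPostFilter):
            out.append(n.el_text)
        elif isinstance(n, IRBool):
            for c in n.children:
                walk(c)

    walk(tree)
    return out


def emit_es_query(ir: QueryIR) -> str:
    """Serialize the IR as Elasticsearch 7.x Query DSL (JSON text).

    Each group yields one candidate query per index it touches (patient id
    sets are intersected across groups client-side); post-filters are not
    emitted — they run client-side on the retrieved candidates. Output is
    byte-stable for a fixed IR.
    """
    groups = []
    for tree in ir.groups:
        indexes = sorted(_group_indexes(tree))
        index_queries = {}
        for index in indexes:
            projected = _project(tree, index, over=True)
            index_queries[index] = {"query": _es_render(projected)}
        if not index_queries:
            index_queries["_all"] = {"query": {"match_all": {}}}
        groups.append(
            {
                "index_queries": index_queries,
                "post_filters": _postfilter_texts(tree),
            }
        )
    doc = {"combine": "intersect patient ids across groups", "groups": groups}
    return json.dumps(doc, indent=2, sort_keys=True)
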