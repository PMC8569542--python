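"""The eligibility-criteria expression language (an EL subset).

The language covers what screening conditions actually need: arithmetic,
relational and logical operators, chained comparisons (``27 < mmse < 30``),
collection functions over repeated records (``count/max/min/first/last``),
existence (``attached(aspirin)``), free-text containment
(``contains(findings, "hematoma")``), signed time differences
(``diff(a.StartTime, b.EndTime)``), the evaluation clock
(``current_date_time()``), ISO-8601 duration literals (``PT48H``), and
``name := expression`` definitions introducing derived concepts.

Precedence, loosest to tightest::

    or < and < not < comparisons < "+"/"-" < "*"/"/" < unary "-" < "^"

Chained comparisons mix ``=`` with one direction of inequalities (as the
temporal patterns require) and desugar to a conjunction over adjacent pairs
in which every term is evaluated once against a single record binding.

Concept references are bare identifiers or ``[bracketed names]`` (the two
are interchangeable surface syntax); resolution against a concept registry
binds each reference to a unique concept path or a derived-concept name.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Union

from .errors import (
    DependencyCycleError,
    ELSyntaxError,
    AmbiguousReferenceError,
    UnresolvedReferenceError,
)
from .templates import ConceptRegistry

# --------------------------------------------------------------------------
# AST
# --------------------------------------------------------------------------

ATTRIBUTES = ("StartTime", "EndTime", "Value")
COLLECTION_FUNCTIONS = ("count", "max", "min", "first", "last")
#: name -> arity for free functions.
FREE_FUNCTIONS = {
    "attached": 1,
    "diff": 2,
    "current_date_time": 0,
    "contains": 2,
}

COMPARISON_OPS = ("<", "<=", ">", ">=", "=", "!=")


@dataclass(frozen=True)
class Literal:
    value: object  # int | float | str | bool | datetime.timedelta


@dataclass(frozen=True)
class ConceptRef:
    name: str
    path: Optional[str] = None  # set by resolution for simple concepts
    derived: bool = False  # set by resolution for derived concepts


@dataclass(frozen=True)
class AttributeRef:
    base: ConceptRef
    attr: str  # StartTime | EndTime | Value


@dataclass(frozen=True)
class FunctionCall:
    name: str
    args: tuple


@dataclass(frozen=True)
class Unary:
    op: str  # "not" | "-"
    operand: object


@dataclass(frozen=True)
class Binary:
    op: str
    lhs: object
    rhs: object


@dataclass(frozen=True)
class Chained:
    """``a < b = c < d`` — at least three terms, ops in one direction."""

    terms: tuple
    ops: tuple


@dataclass(frozen=True)
class Definition:
    name: str
    expression: object


Expression = Union[Literal, ConceptRef, AttributeRef, FunctionCall, Unary, Binary, Chained]


@dataclass
class DerivedConcept:
    """A concept defined by an expression over other concepts."""

    name: str
    expression: object
    dependencies: set = field(default_factory=set)


# --------------------------------------------------------------------------
# Durations
# --------------------------------------------------------------------------

# Calendar units have no context in the expression language, so fixed
# lengths are used: 1 Y = 365.25 d, 1 M = 30.4375 d.
_DUR_SECONDS = {
    "Y": 365.25 * 86400,
    "MO": 30.4375 * 86400,
    "W": 7 * 86400,
    "D": 86400,
    "H": 3600,
    "MI": 60,
    "S": 1,
}

_DURATION_RE = re.compile(
    r"P(?:(?P<Y>\d+(?:\.\d+)?)Y)?(?:(?P<MO>\d+(?:\.\d+)?)M)?"
    r"(?:(?P<W>\d+(?:\.\d+)?)W)?(?:(?P<D>\d+(?:\.\d+)?)D)?"
    r"(?:T(?:(?P<H>\d+(?:\.\d+)?)H)?(?:(?P<MI>\d+(?:\.\d+)?)M)?"
    r"(?:(?P<S>\d+(?:\.\d+)?)S)?)?"
)


def parse_duration(text: str) -> _dt.timedelta:
    m = _DURATION_RE.fullmatch(text)
    if not m or all(v is None for v in m.groupdict().values()):
        raise ELSyntaxError(f"malformed duration literal {text!r}")
    seconds = 0.0
    for key, value in m.groupdict().items():
        if value is not None:
            seconds += float(value) * _DUR_SECONDS[key]
    return _dt.timedelta(seconds=seconds)


def format_duration(delta: _dt.timedelta) -> str:
    """Canonical ISO text: sign, whole days, then H/M/S components."""
    total = delta.total_seconds()
    sign = "-" if total < 0 else ""
    total = abs(total)
    days, rem = divmod(total, 86400)
    hours, rem = divmod(rem, 3600)
    minutes, secs = divmod(rem, 60)
    out = f"{sign}P"
    if days:
        out += f"{int(days)}D"
    time_part = ""
    if hours:
        time_part += f"{int(hours)}H"
    if minutes:
        time_part += f"{int(minutes)}M"
    if secs:
        s = f"{secs:.6f}".rstrip("0").rstrip(".")
        time_part += f"{s}S"
    if time_part:
        out += "T" + time_part
    if out in ("P", "-P"):
        out += "T0S"
    return out


# --------------------------------------------------------------------------
# Tokenizer
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<WS>\s+)
  | (?P<DURATION>P(?=\d|T\d)[\d.YMWDTHS]*)
  | (?P<NUMBER>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
  | (?P<STRING>"[^"\n]*")
  | (?P<IDENT>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<BRACKET>\[[^\]\n]+\])
  | (?P<OP>:=|<=|>=|!=|≤|≥|≠|[-+*/^<>=(),.])
    """,
    re.VERBOSE,
)

_OP_ALIASES = {"≤": "<=", "≥": ">=", "≠": "!="}
_KEYWORDS = {"and", "or", "not", "true", "false"}


@dataclass(frozen=True)
class _Token:
    kind: str
    text: str
    line: int
    column: int


def _tokenize(text: str) -> list[_Token]:
    tokens = []
    line, col, pos = 1, 0, 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise ELSyntaxError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        tok = m.group()
        if kind != "WS":
            value = _OP_ALIASES.get(tok, tok)
            if kind == "IDENT" and tok in _KEYWORDS:
                kind = "KEYWORD"
            tokens.append(_Token(kind, value, line, col))
        newlines = tok.count("\n")
        if newlines:
            line += newlines
            col = len(tok) - tok.rfind("\n") - 1
        else:
            col += len(tok)
        pos = m.end()
    tokens.append(_Token("EOF", "", line, col))
    return tokens


# --------------------------------------------------------------------------
# Parser
# --------------------------------------------------------------------------


class _Parser:
    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def _error(self, message: str):
        tok = self.cur
        raise ELSyntaxError(message, tok.line, tok.column)

    def _accept(self, kind: str, text: Optional[str] = None) -> Optional[_Token]:
        tok = self.cur
        if tok.kind == kind and (text is None or tok.text == text):
            self.i += 1
            return tok
        return None

    def _expect(self, kind: str, text: Optional[str] = None) -> _Token:
        tok = self._accept(kind, text)
        if tok is None:
            want = text or kind
            self._error(f"expected {want!r}, found {self.cur.text or 'end of input'!r}")
        return tok

    def parse(self):
        # definition lookahead: IDENT ":="
        if (
            self.cur.kind == "IDENT"
            and self.tokens[self.i + 1].kind == "OP"
            and self.tokens[self.i + 1].text == ":="
        ):
            name = self._expect("IDENT").text
            self._expect("OP", ":=")
            expr = self.expr()
            self._expect("EOF")
            return Definition(name, expr)
        expr = self.expr()
        self._expect("EOF")
        return expr

    def expr(self):
        return self.or_expr()

    def or_expr(self):
        node = self.and_expr()
        while self._accept("KEYWORD", "or"):
            node = Binary("or", node, self.and_expr())
        return node

    def and_expr(self):
        node = self.not_expr()
        while self._accept("KEYWORD", "and"):
            node = Binary("and", node, self.not_expr())
        return node

    def not_expr(self):
        if self._accept("KEYWORD", "not"):
            return Unary("not", self.not_expr())
        return self.comparison()

    def comparison(self):
        terms = [self.sum_()]
        ops = []
        while self.cur.kind == "OP" and self.cur.text in COMPARISON_OPS:
            ops.append(self._accept("OP").text)
            terms.append(self.sum_())
        if not ops:
            return terms[0]
        if len(ops) == 1:
            return Binary(ops[0], terms[0], terms[1])
        directions = {op for op in ops if op != "="}
        if directions and not (
            directions <= {"<", "<="} or directions <= {">", ">="}
        ):
            self._error(f"chained comparison mixes directions: {ops}")
        return Chained(tuple(terms), tuple(ops))

    def sum_(self):
        node = self.term()
        while True:
            if self._accept("OP", "+"):
                node = Binary("+", node, self.term())
            elif self._accept("OP", "-"):
                node = Binary("-", node, self.term())
            else:
                return node

    def term(self):
        node = self.factor()
        while True:
            if self._accept("OP", "*"):
                node = Binary("*", node, self.factor())
            elif self._accept("OP", "/"):
                node = Binary("/", node, self.factor())
            else:
                return node

    def factor(self):
        if self._accept("OP", "-"):
            return Unary("-", self.factor())
        return self.power()

    def power(self):
        base = self.postfix()
        if self._accept("OP", "^"):
            return Binary("^", base, self.factor())
        return base

    def postfix(self):
        node = self.primary()
        while self._accept("OP", "."):
            name = self._expect("IDENT").text
            if name in ATTRIBUTES:
                if not isinstance(node, ConceptRef):
                    self._error(f"attribute {name!r} requires a concept reference")
                node = AttributeRef(node, name)
            elif name in COLLECTION_FUNCTIONS:
                self._expect("OP", "(")
                self._expect("OP", ")")
                if not isinstance(node, ConceptRef):
                    self._error(f"collection function {name!r} requires a concept reference")
                node = FunctionCall(name, (node,))
            else:
                self._error(f"unknown attribute or collection function {name!r}")
        return node

    def primary(self):
        tok = self.cur
        if tok.kind == "NUMBER":
            self.i += 1
            text = tok.text
            if "." in text or "e" in text or "E" in text:
                return Literal(float(text))
            return Literal(int(text))
        if tok.kind == "DURATION":
            self.i += 1
            try:
                return Literal(parse_duration(tok.text))
            except ELSyntaxError:
                raise ELSyntaxError(
                    f"malformed duration literal {tok.text!r}", tok.line, tok.column
                ) from None
        if tok.kind == "STRING":
            self.i += 1
            return Literal(tok.text[1:-1])
        if tok.kind == "KEYWORD" and tok.text in ("true", "false"):
            self.i += 1
            return Literal(tok.text == "true")
        if tok.kind == "BRACKET":
            self.i += 1
            return ConceptRef(tok.text[1:-1].strip())
        if tok.kind == "IDENT":
            self.i += 1
            if self._accept("OP", "("):
                if tok.text not in FREE_FUNCTIONS:
                    raise ELSyntaxError(
                        f"unknown function {tok.text!r}", tok.line, tok.column
                    )
                args = []
                if not self._accept("OP", ")"):
                    args.append(self.expr())
                    while self._accept("OP", ","):
                        args.append(self.expr())
                    self._expect("OP", ")")
                if len(args) != FREE_FUNCTIONS[tok.text]:
                    raise ELSyntaxError(
                        f"{tok.text} expects {FREE_FUNCTIONS[tok.text]} argument(s), "
                        f"got {len(args)}",
                        tok.line,
                        tok.column,
                    )
                return FunctionCall(tok.text, tuple(args))
            return ConceptRef(tok.text)
        if self._accept("OP", "("):
            node = self.expr()
            self._expect("OP", ")")
            return node
        self._error(f"unexpected token {tok.text or 'end of input'!r}")


def parse_expression(text: str):
    """Parse expression text to an AST; ``name := expr`` yields a Definition."""
    return _Parser(_tokenize(text)).parse()


# --------------------------------------------------------------------------
# Unparser
# --------------------------------------------------------------------------

_PREC = {
    "or": 1,
    "and": 2,
    "not": 3,
    "cmp": 4,
    "+": 5,
    "-": 5,
    "*": 6,
    "/": 6,
    "neg": 7,
    "^": 8,
    "atom": 9,
}

_BARE_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")


def _prec(node) -> int:
    if isinstance(node, Binary):
        return _PREC["cmp"] if node.op in COMPARISON_OPS else _PREC[node.op]
    if isinstance(node, Chained):
        return _PREC["cmp"]
    if isinstance(node, Unary):
        return _PREC["not"] if node.op == "not" else _PREC["neg"]
    return _PREC["atom"]


def _wrap(text: str, need: bool) -> str:
    return f"({text})" if need else text


def unparse(node) -> str:
    """Canonical text form; ``parse_expression(unparse(x))`` equals ``x``."""
    if isinstance(node, Definition):
        return f"{node.name} := {unparse(node.expression)}"
    if isinstance(node, Literal):
        v = node.value
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, _dt.timedelta):
            return format_duration(v)
        if isinstance(v, str):
            return json.dumps(v)
        return repr(v)
    if isinstance(node, ConceptRef):
        if _BARE_IDENT_RE.match(node.name) and node.name not in _KEYWORDS:
            return node.name
        return f"[{node.name}]"
    if isinstance(node, AttributeRef):
        return f"{unparse(node.base)}.{node.attr}"
    if isinstance(node, FunctionCall):
        if node.name in COLLECTION_FUNCTIONS:
            return f"{unparse(node.args[0])}.{node.name}()"
        args = ", ".join(unparse(a) for a in node.args)
        return f"{node.name}({args})"
    if isinstance(node, Unary):
        my = _prec(node)
        inner = _wrap(unparse(node.operand), _prec(node.operand) < my)
        return f"not {inner}" if node.op == "not" else f"-{inner}"
    if isinstance(node, Chained):
        my = _PREC["cmp"]
        parts = [_wrap(unparse(node.terms[0]), _prec(node.terms[0]) <= my)]
        for op, term in zip(node.ops, node.terms[1:]):
            parts.append(op)
            parts.append(_wrap(unparse(term), _prec(term) <= my))
        return " ".join(parts)
    if isinstance(node, Binary):
        my = _prec(node)
        lhs_p, rhs_p = _prec(node.lhs), _prec(node.rhs)
        if node.op == "^":
            lhs = _wrap(unparse(node.lhs), lhs_p <= my)  # right-assoc
            rhs = _wrap(unparse(node.rhs), rhs_p < _PREC["neg"])
        elif node.op in COMPARISON_OPS:
            # comparisons are non-associative: parenthesize nested ones
            lhs = _wrap(unparse(node.lhs), lhs_p <= my)
            rhs = _wrap(unparse(node.rhs), rhs_p <= my)
        else:
            lhs = _wrap(unparse(node.lhs), lhs_p < my)
            rhs = _wrap(unparse(node.rhs), rhs_p <= my)  # left-assoc
        if node.op in ("and", "or"):
            return f"{lhs} {node.op} {rhs}"
        return f"{lhs} {node.op} {rhs}"
    raise TypeError(f"not an AST node: {node!r}")


# --------------------------------------------------------------------------
# Resolution and dependencies
# --------------------------------------------------------------------------


def resolve_references(node, registry: ConceptRegistry):
    """Bind every concept reference to a unique path or derived name.

    Bare names match registry concept names case-insensitively after
    sanitization; a reference may also be a literal concept path. Ambiguous
    names raise with the candidate paths listed.
    """
    if isinstance(node, Definition):
        return Definition(node.name, resolve_references(node.expression, registry))
    if isinstance(node, ConceptRef):
        if node.path is not None or node.derived:
            return node
        if node.name in registry.derived:
            return replace(node, derived=True)
        if node.name.startswith("/") and node.name in registry.concepts:
            return replace(node, path=node.name)
        candidates = registry.lookup_name(node.name)
        if len(candidates) == 1:
            return replace(node, path=candidates[0])
        if len(candidates) > 1:
            raise AmbiguousReferenceError(node.name, candidates)
        raise UnresolvedReferenceError(f"unknown concept or derived concept {node.name!r}")
    if isinstance(node, AttributeRef):
        return AttributeRef(resolve_references(node.base, registry), node.attr)
    if isinstance(node, FunctionCall):
        return FunctionCall(
            node.name, tuple(resolve_references(a, registry) for a in node.args)
        )
    if isinstance(node, Unary):
        return Unary(node.op, resolve_references(node.operand, registry))
    if isinstance(node, Binary):
        return Binary(
            node.op,
            resolve_references(node.lhs, registry),
            resolve_references(node.rhs, registry),
        )
    if isinstance(node, Chained):
        return Chained(
            tuple(resolve_references(t, registry) for t in node.terms), node.ops
        )
    return node


def collect_dependencies(node) -> set:
    """Concept paths and derived names referenced by a resolved AST."""
    deps = set()

    def walk(n):
        if isinstance(n, ConceptRef):
            deps.add(n.name if n.derived else n.path)
        elif isinstance(n, AttributeRef):
            walk(n.base)
        elif isinstance(n, FunctionCall):
            for a in n.args:
                walk(a)
        elif isinstance(n, Unary):
            walk(n.operand)
        elif isinstance(n, Binary):
            walk(n.lhs)
            walk(n.rhs)
        elif isinstance(n, Chained):
            for t in n.terms:
                walk(t)
        elif isinstance(n, Definition):
            walk(n.expression)

    walk(node)
    return deps


def define_derived(source: Union[str, Definition], registry: ConceptRegistry) -> DerivedConcept:
    """Parse/resolve a definition and register it as a derived concept.

    References to not-yet-registered derived names are rejected, so
    intermediate concepts must be defined first; this makes the dependency
    graph acyclic by construction.
    """
    definition = parse_expression(source) if isinstance(source, str) else source
    if not isinstance(definition, Definition):
        raise ELSyntaxError("expected a 'name := expression' definition")
    resolved = resolve_references(definition.expression, registry)
    derived = DerivedConcept(
        name=definition.name,
        expression=resolved,
        dependencies=collect_dependencies(resolved),
    )
    registry.register_derived(derived)
    return derived


def dependency_order(derived: Iterable[DerivedConcept]) -> list[DerivedConcept]:
    """Topological order of derived concepts (dependencies first).

    Deterministic: ready nodes are emitted in name order. A cycle raises
    with its member names.
    """
    items = {d.name: d for d in derived}
    pending = {
        name: {dep for dep in d.dependencies if dep in items}
        for name, d in items.items()
    }
    order = []
    while pending:
        ready = sorted(name for name, deps in pending.items() if not deps)
        if not ready:
            raise DependencyCycleError(sorted(pending))
        for name in ready:
            order.append(items[name])
            del pending[name]
        for deps in pending.values():
            deps.difference_update(ready)
    return order


def inline_derived(node, registry: ConceptRegistry):
    """Expand every derived-concept reference to its defining expression."""
    if isinstance(node, ConceptRef) and node.derived:
        return inline_derived(registry.derived[node.name].expression, registry)
    if isinstance(node, Definition):
        return Definition(node.name, inline_derived(node.expression, registry))
    if isinstance(node, AttributeRef):
        base = inline_derived(node.base, registry)
        if not isinstance(base, ConceptRef):
            raise ELSyntaxError(
                f"attribute {node.attr!r} applied to a non-simple derived concept"
            )
        return AttributeRef(base, node.attr)
    if isinstance(node, FunctionCall):
        return FunctionCall(
            node.name, tuple(inline_derived(a, registry) for a in node.args)
        )
    if isinstance(node, Unary):
        return Unary(node.op, inline_derived(node.operand, registry))
    if isinstance(node, Binary):
        return Binary(
            node.op,
            inline_derived(node.lhs, registry),
            inline_derived(node.rhs, registry),
        )
    if isinstance(node, Chained):
        return Chained(
            tuple(inline_derived(t, registry) for t in node.terms), node.ops
        )
    return node


def derived_library_to_json(derived: Iterable[DerivedConcept]) -> str:
    """Persist a derived-concept library (name, expression text, deps)."""
    rows = [
        {
            "name": d.name,
            "expression": unparse(d.expression),
            "dependencies": sorted(str(x) for x in d.dependencies),
        }
        for d in dependency_order(derived)
    ]
    return json.dumps({"derived_concepts": rows}, indent=2)
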