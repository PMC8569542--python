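"""Temporal and collection constraints for screening conditions.

Two-event temporal patterns follow Allen's interval algebra: thirteen
jointly-exhaustive, pairwise-disjoint relations between strict intervals,
each materialized both as an executable classifier and as an expression
chain over ``StartTime``/``EndTime`` attributes. An ``Interval`` extension
covers durations between events (``diff(a.StartTime, b.EndTime) <= PT48H``),
and a small library of predefined collection constraints (First time,
Stable, Increase, Decrease) covers repeated measurements; further constraint
templates can be registered at run time.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional

from .errors import ConstraintError, DegenerateIntervalError
from .expressions import (
    AttributeRef,
    ConceptRef,
    format_duration,
    parse_expression,
    unparse,
)

# --------------------------------------------------------------------------
# Allen relations
# --------------------------------------------------------------------------

RELATION_LABELS = (
    "Before",
    "Meets",
    "Overlaps",
    "Begins",
    "BegunBy",
    "During",
    "Contains",
    "Equals",
    "OverlappedBy",
    "Ends",
    "EndedBy",
    "MetBy",
    "After",
)

#: label -> inverse label under argument swap.
RELATION_INVERSES = {
    "Before": "After",
    "After": "Before",
    "Meets": "MetBy",
    "MetBy": "Meets",
    "Overlaps": "OverlappedBy",
    "OverlappedBy": "Overlaps",
    "Begins": "BegunBy",
    "BegunBy": "Begins",
    "During": "Contains",
    "Contains": "During",
    "Ends": "EndedBy",
    "EndedBy": "Ends",
    "Equals": "Equals",
}

#: label -> endpoint chain with {a}/{b} concept placeholders.
_RELATION_CHAINS = {
    "Before": "{a}.StartTime<{a}.EndTime<{b}.StartTime<{b}.EndTime",
    "Meets": "{a}.StartTime<{a}.EndTime={b}.StartTime<{b}.EndTime",
    "Overlaps": "{a}.StartTime<{b}.StartTime<{a}.EndTime<{b}.EndTime",
    "Begins": "{a}.StartTime={b}.StartTime<{a}.EndTime<{b}.EndTime",
    "BegunBy": "{a}.StartTime={b}.StartTime<{b}.EndTime<{a}.EndTime",
    "During": "{b}.StartTime<{a}.StartTime<{a}.EndTime<{b}.EndTime",
    "Contains": "{a}.StartTime<{b}.StartTime<{b}.EndTime<{a}.EndTime",
    "Equals": "{a}.StartTime={b}.StartTime<{b}.EndTime={a}.EndTime",
    "OverlappedBy": "{b}.StartTime<{a}.StartTime<{b}.EndTime<{a}.EndTime",
    "Ends": "{b}.StartTime<{a}.StartTime<{a}.EndTime={b}.EndTime",
    "EndedBy": "{a}.StartTime<{b}.StartTime<{b}.EndTime={a}.EndTime",
    "MetBy": "{b}.StartTime<{b}.EndTime={a}.StartTime<{a}.EndTime",
    "After": "{b}.StartTime<{b}.EndTime<{a}.StartTime<{a}.EndTime",
}


@dataclass(frozen=True)
class EventInterval:
    """A strict event interval: start < end. Endpoints may be timestamps or
    any mutually comparable values (integers in tests)."""

    start: object
    end: object

    def validate(self):
        if self.start == self.end:
            raise DegenerateIntervalError(
                f"point interval ({self.start!r}); pad instantaneous events "
                "by an epsilon before classification"
            )
        if self.start > self.end:
            raise DegenerateIntervalError(
                f"interval start {self.start!r} after end {self.end!r}"
            )


def classify_relation(i1: EventInterval, i2: EventInterval) -> str:
    """The unique Allen relation holding between two strict intervals."""
    i1.validate()
    i2.validate()
    s1, e1, s2, e2 = i1.start, i1.end, i2.start, i2.end
    if e1 < s2:
        return "Before"
    if e2 < s1:
        return "After"
    if e1 == s2:
        return "Meets"
    if e2 == s1:
        return "MetBy"
    if s1 == s2:
        if e1 == e2:
            return "Equals"
        return "Begins" if e1 < e2 else "BegunBy"
    if e1 == e2:
        return "Ends" if s2 < s1 else "EndedBy"
    if s1 < s2:
        return "Contains" if e2 < e1 else "Overlaps"
    return "During" if e1 < e2 else "OverlappedBy"


def _ref_text(concept) -> str:
    if isinstance(concept, ConceptRef):
        return unparse(concept)
    return unparse(ConceptRef(str(concept)))


def relation_expression(label: str, c1, c2) -> str:
    """Endpoint-chain expression asserting ``label`` between two concepts."""
    if label not in _RELATION_CHAINS:
        raise ConstraintError(f"unknown temporal relation {label!r}")
    return _RELATION_CHAINS[label].format(a=_ref_text(c1), b=_ref_text(c2))


# --------------------------------------------------------------------------
# Interval extension
# --------------------------------------------------------------------------

_INTERVAL_COMPARATORS = ("<", "<=", ">", ">=", "=")


def _attr_text(attr) -> str:
    if isinstance(attr, AttributeRef):
        return unparse(attr)
    if isinstance(attr, str):
        try:
            parse_expression(attr)
        except Exception as exc:
            raise ConstraintError(f"not an attribute reference: {attr!r}") from exc
        return attr
    raise ConstraintError(f"not an attribute reference: {attr!r}")


def interval_constraint(c1_attr, c2_attr, cmp: str, d: _dt.timedelta) -> str:
    """``diff(a, b) cmp D`` — signed duration between two event attributes.

    ``diff`` is first argument minus second; D must be non-negative.
    """
    if cmp not in _INTERVAL_COMPARATORS:
        raise ConstraintError(f"unsupported comparator {cmp!r}")
    if d < _dt.timedelta(0):
        raise ConstraintError(f"negative interval {d!r}")
    a, b = _attr_text(c1_attr), _attr_text(c2_attr)
    return f"diff({a}, {b}) {cmp} {format_duration(d)}"


def within_last_diff_form(concept_attr, d: _dt.timedelta) -> str:
    """"Event within the last D" as a pair of signed-diff bounds."""
    a = _attr_text(concept_attr)
    dur = format_duration(d)
    return f"diff(current_date_time(), {a}) <= {dur} and diff({a}, current_date_time()) <= PT0S"


def within_last_window_form(concept_attr, d: _dt.timedelta) -> str:
    """"Event within the last D" as a chained window comparison."""
    a = _attr_text(concept_attr)
    return f"current_date_time() - {format_duration(d)} <= {a} <= current_date_time()"


# --------------------------------------------------------------------------
# Collection constraints
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstraintTemplate:
    """A named expression pattern with ``[placeholder]`` parameters."""

    name: str
    parameters: tuple  # of (name, kind); kinds: concept | value | duration | comparator
    el_pattern: str


BUILTIN_CONSTRAINTS = (
    ConstraintTemplate("First time", (("concept", "concept"),), "[concept].count()=1"),
    ConstraintTemplate(
        "Stable",
        (("concept", "concept"), ("value", "value")),
        "[concept].max()-[concept].min()<[value]",
    ),
    ConstraintTemplate(
        "Increase", (("concept", "concept"),), "[concept].last()>[concept].first()"
    ),
    ConstraintTemplate(
        "Decrease", (("concept", "concept"),), "[concept].last()<[concept].first()"
    ),
)


def _format_param(kind: str, value) -> str:
    if kind == "concept":
        return _ref_text(value)
    if kind == "duration":
        if not isinstance(value, _dt.timedelta):
            raise ConstraintError(f"duration parameter expects a timedelta, got {value!r}")
        return format_duration(value)
    if kind == "comparator":
        if value not in _INTERVAL_COMPARATORS:
            raise ConstraintError(f"bad comparator parameter {value!r}")
        return str(value)
    if isinstance(value, bool):
        return "true" if value else "false"
    return repr(value) if isinstance(value, (int, float)) else str(value)


class ConstraintRegistry:
    """Built-in plus self-defined constraint templates."""

    def __init__(self):
        self.templates: dict[str, ConstraintTemplate] = {
            t.name: t for t in BUILTIN_CONSTRAINTS
        }

    def register(self, template: ConstraintTemplate) -> str:
        if template.name in self.templates:
            raise ConstraintError(
                f"constraint {template.name!r} already registered"
            )
        # validate: the pattern must parse once dummy parameters are filled
        dummy = template.el_pattern
        for pname, kind in template.parameters:
            stand_in = {"concept": "x", "value": "1", "duration": "PT1H", "comparator": "<"}[kind]
            dummy = dummy.replace(f"[{pname}]", stand_in)
        try:
            parse_expression(dummy)
        except Exception as exc:
            raise ConstraintError(
                f"constraint pattern does not parse: {template.el_pattern!r} ({exc})"
            ) from exc
        self.templates[template.name] = template
        return template.name

    def expand(self, name: str, concept, **params) -> str:
        if name not in self.templates:
            raise ConstraintError(f"unknown constraint {name!r}")
        template = self.templates[name]
        supplied = dict(params)
        out = template.el_pattern
        for pname, kind in template.parameters:
            if kind == "concept":
                value = concept
            elif pname in supplied:
                value = supplied.pop(pname)
            else:
                raise ConstraintError(
                    f"constraint {name!r} missing parameter {pname!r}"
                )
            out = out.replace(f"[{pname}]", _format_param(kind, value))
        if supplied:
            raise ConstraintError(f"unknown parameter(s) {sorted(supplied)} for {name!r}")
        return out

    def to_json_rows(self) -> list[dict]:
        return [
            {
                "name": t.name,
                "parameters": [list(p) for p in t.parameters],
                "el_pattern": t.el_pattern,
            }
            for t in self.templates.values()
        ]


_DEFAULT_REGISTRY = ConstraintRegistry()


def expand_collection_constraint(name: str, concept, registry: Optional[ConstraintRegistry] = None, **params) -> str:
    """Expand a named constraint template for a concept; see Table of
    built-ins (First time, Stable, Increase, Decrease)."""
    return (registry or _DEFAULT_REGISTRY).expand(name, concept, **params)


def register_custom_constraint(template: ConstraintTemplate, registry: Optional[ConstraintRegistry] = None) -> str:
    return (registry or _DEFAULT_REGISTRY).register(template)
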