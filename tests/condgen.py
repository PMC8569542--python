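"""Seeded random screening-condition generator shared by test suites.

Draws atoms over the bundled demo concept set (coded presence, quantity and
score comparisons, range chains, collection aggregates, free-text
containment, clock-relative age bounds, and two-event temporal chains) and
combines them with and/or/not into grouped conditions. Used to exercise the
compiler against the reference evaluator on inputs neither was written
around.
"""

from __future__ import annotations

import random

from ehrscreen import (
    Group,
    ScreeningCondition,
    build_demo_context,
    relation_expression,
)
from ehrscreen.constraints import RELATION_LABELS


def screening_context():
    """Demo context with StartTime/EndTime bound for drug-order concepts so
    temporal chains have real event intervals."""
    templates, registry, schemas = build_demo_context()
    for code in ("ASA", "HEP", "CLO"):
        path = f"/order/order_item/{code}"
        registry.bind_time_attributes(
            registry.concepts[path],
            start_path="/order/order_start_time",
            end_path="/order/order_stop_time",
        )
    return templates, registry, schemas


def bind_order_intervals(store):
    """Bind drug-order concepts to start/stop times on an existing store."""
    for code in ("ASA", "HEP", "CLO"):
        path = f"/order/order_item/{code}"
        store.registry.bind_time_attributes(
            store.registry.concepts[path],
            start_path="/order/order_start_time",
            end_path="/order/order_stop_time",
        )
    store._binding_cache.clear()
    store._instance_cache.clear()
    return store


_CODED = (
    "aspirin",
    "clopidogrel",
    "heparin",
    "evacuation_of_intracerebral_hematoma",
    "cerebral_hemorrhage",
    "cerebral_infarction",
    "essential_hypertension",
    "obesity",
    "escherichia_coli",
)

_QUANTITIES = (
    ("white_blood_cell_count", 2.0, 14.0),
    ("systolic_blood_pressure", 100.0, 190.0),
    ("heart_rate", 50.0, 110.0),
    ("body_temperature", 36.0, 39.0),
    ("weight", 40.0, 95.0),
    ("mmse", 10, 30),
    ("moca", 8, 30),
    ("colony_count", 100, 4500),
)

_CMPS = ("<", "<=", ">", ">=")
_TEXTS = ("hematoma", "stenosis", "abnormality", "infarcts")


def random_atom(rng: random.Random) -> str:
    kind = rng.randrange(9)
    if kind == 0:
        return f"attached({rng.choice(_CODED)})"
    if kind == 1:
        name, lo, hi = rng.choice(_QUANTITIES)
        v = rng.uniform(lo, hi)
        v = round(v, 1) if isinstance(lo, float) else int(v)
        return f"{name} {rng.choice(_CMPS)} {v}"
    if kind == 2:
        name, lo, hi = rng.choice(_QUANTITIES)
        a, b = sorted((rng.uniform(lo, hi), rng.uniform(lo, hi)))
        if isinstance(lo, float):
            a, b = round(a, 1), round(b, 1)
        else:
            a, b = int(a), int(b)
        return f"{a} <= {name} <= {b}"
    if kind == 3:
        return f'sex = "{rng.choice(("Female", "Male"))}"'
    if kind == 4:
        lo = rng.randrange(18, 70)
        hi = lo + rng.randrange(5, 30)
        return f"{lo} <= age <= {hi}"
    if kind == 5:
        agg = rng.randrange(4)
        if agg == 0:
            return f"white_blood_cell_count.count() = {rng.randrange(0, 4)}"
        if agg == 1:
            return f"white_blood_cell_count.last() > {round(rng.uniform(4, 11), 1)}"
        if agg == 2:
            return (
                "white_blood_cell_count.max() - white_blood_cell_count.min()"
                f" < {round(rng.uniform(0.5, 6.0), 1)}"
            )
        return "white_blood_cell_count.last() < white_blood_cell_count.first()"
    if kind == 6:
        return f'contains(findings, "{rng.choice(_TEXTS)}")'
    if kind == 7:
        label = rng.choice(RELATION_LABELS)
        c1, c2 = rng.sample(["aspirin", "heparin", "clopidogrel"], 2)
        return relation_expression(label, c1, c2)
    days = rng.randrange(30, 1800)
    drug = rng.choice(("aspirin", "heparin"))
    return f"diff(current_date_time(), {drug}.StartTime) <= P{days}D"


def random_member(rng: random.Random, depth: int = 0) -> str:
    roll = rng.random()
    if depth < 2 and roll < 0.25:
        return f"({random_member(rng, depth + 1)} {rng.choice(('and', 'or'))} {random_member(rng, depth + 1)})"
    if depth < 2 and roll < 0.35:
        return f"not ({random_member(rng, depth + 1)})"
    return random_atom(rng)


def random_condition(rng: random.Random) -> ScreeningCondition:
    groups = []
    for _ in range(rng.randrange(1, 4)):
        members = [random_member(rng) for _ in range(rng.randrange(1, 3))]
        constraints = []
        if rng.random() < 0.3:
            constraints.append(random_atom(rng))
        groups.append(Group(members=members, constraints=constraints))
    return ScreeningCondition(groups=groups)
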