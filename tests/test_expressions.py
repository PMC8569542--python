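"""Expression grammar, canonical unparsing, resolution, dependencies."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from ehrscreen import (
    define_derived,
    dependency_order,
    parse_expression,
    resolve_references,
    unparse,
)
from ehrscreen.errors import (
    AmbiguousReferenceError,
    DependencyCycleError,
    ELSyntaxError,
    RegistryCollisionError,
    UnresolvedReferenceError,
)
from ehrscreen.expressions import (
    AttributeRef,
    Binary,
    Chained,
    ConceptRef,
    Definition,
    DerivedConcept,
    FunctionCall,
    Literal,
    Unary,
    collect_dependencies,
)
from ehrscreen.templates import ConceptRegistry, load_template


class TestParsing:
    def test_definition_with_power(self):
        node = parse_expression("BMI := weight/height^2")
        assert node == Definition(
            "BMI",
            Binary("/", ConceptRef("weight"), Binary("^", ConceptRef("height"), Literal(2))),
        )

    def test_chained_comparison(self):
        node = parse_expression("27<mmse<30")
        assert node == Chained(
            (Literal(27), ConceptRef("mmse"), Literal(30)), ("<", "<")
        )

    def test_attached_disjunction(self):
        node = parse_expression("attached(aspirin) or attached(clopidogrel)")
        assert node == Binary(
            "or",
            FunctionCall("attached", (ConceptRef("aspirin"),)),
            FunctionCall("attached", (ConceptRef("clopidogrel"),)),
        )

    def test_bracketed_and_bare_names_are_interchangeable(self):
        assert parse_expression("[wbc].count()=1") == parse_expression("wbc.count()=1")

    def test_duration_literal(self):
        node = parse_expression("PT48H")
        assert node == Literal(dt.timedelta(hours=48))

    def test_unicode_comparators_accepted(self):
        assert parse_expression("x ≥ 1") == parse_expression("x >= 1")

    @pytest.mark.parametrize(
        "bad", ["a <<", "foo(", "a := ", "27 < mmse > 30", "unknownfn(x)", 'a."Start"']
    )
    def test_malformed_input_raises_syntax_error(self, bad):
        with pytest.raises(ELSyntaxError):
            parse_expression(bad)

    def test_syntax_error_carries_position(self):
        with pytest.raises(ELSyntaxError) as err:
            parse_expression("a <<")
        assert err.value.line == 1 and err.value.column >= 2

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("a + b * c", Binary("+", ConceptRef("a"), Binary("*", ConceptRef("b"), ConceptRef("c")))),
            ("-a ^ 2", Unary("-", Binary("^", ConceptRef("a"), Literal(2)))),
            ("2 ^ 3 ^ 2", Binary("^", Literal(2), Binary("^", Literal(3), Literal(2)))),
            ("not a and b", Binary("and", Unary("not", ConceptRef("a")), ConceptRef("b"))),
            ("a or b and c", Binary("or", ConceptRef("a"), Binary("and", ConceptRef("b"), ConceptRef("c")))),
            ("a - b - c", Binary("-", Binary("-", ConceptRef("a"), ConceptRef("b")), ConceptRef("c"))),
            ("not a < b", Unary("not", Binary("<", ConceptRef("a"), ConceptRef("b")))),
        ],
    )
    def test_operator_precedence_vectors(self, text, expected):
        assert parse_expression(text) == expected


TABLE_EXPRESSIONS = [
    "current_date_time() - encounter.StartTime",
    "(systolic_blood_pressure >= 120 and systolic_blood_pressure <= 220)"
    " and (40 <= heart_rate <= 100) and blood_oxygen_saturation >= 92"
    " and body_temperature <= 38.5",
    "27 < mmse < 30",
    "attached(aspirin) or attached(clopidogrel)",
    "cognitive_impairment_diagnosis or mmse < 24 or moca < 26",
    "obesity_diagnosis or icd_10_obesity or bmi_obesity",
    "attached(sulpiride) or attached(risperidone)",
    "BMI := weight / height ^ 2",
    "wbc.count() = 1",
    "wbc.max() - wbc.min() < 10",
    "wbc.last() < wbc.first()",
    "diff(current_date_time(), heparin.StartTime) <= PT48H",
]


class TestUnparsing:
    def test_definition_canonical_form(self):
        assert unparse(parse_expression("BMI := weight/height^2")) == "BMI := weight / height ^ 2"

    @pytest.mark.parametrize("text", TABLE_EXPRESSIONS)
    def test_descriptive_expressions_reach_fixed_point(self, text):
        once = unparse(parse_expression(text))
        assert parse_expression(once) == parse_expression(text)
        assert unparse(parse_expression(once)) == once

    def test_literal_rendering(self):
        assert unparse(Literal(38.5)) == "38.5"
        assert unparse(Literal(True)) == "true"
        assert unparse(Literal("I61")) == '"I61"'
        assert unparse(Literal(dt.timedelta(hours=48))) == "P2D"


# -- random AST round-trip property ----------------------------------------

_identifiers = st.from_regex(r"[a-z_][a-z0-9_]{0,6}", fullmatch=True).filter(
    lambda s: s not in {"and", "or", "not", "true", "false"}
    and not (s[0] == "p" and False)
)
_bracket_names = st.from_regex(r"[a-z][a-z ]{0,8}[a-z]", fullmatch=True).map(
    lambda s: " ".join(s.split())
)
_refs = st.one_of(_identifiers, _bracket_names).map(ConceptRef)

_literals = st.one_of(
    st.integers(0, 10**6).map(Literal),
    # non-negative: a leading minus parses as unary negation, not a literal
    st.floats(min_value=0, allow_nan=False, allow_infinity=False, width=64)
    .map(abs)
    .map(Literal),
    st.booleans().map(Literal),
    st.text(alphabet="abcdefghijklmnopqrstuvwxyz0123456789 _", max_size=8).map(Literal),
    st.integers(0, 10**7).map(lambda s: Literal(dt.timedelta(seconds=s))),
)


def _compounds(children):
    arith = st.sampled_from(["+", "-", "*", "/", "^"])
    cmps = st.sampled_from(["<", "<=", ">", ">=", "=", "!="])
    chain_ops = st.sampled_from([("<", "<="), (">=", ">"), ("<", "="), ("=", ">")])
    return st.one_of(
        st.tuples(arith, children, children).map(lambda t: Binary(*t)),
        st.tuples(cmps, children, children).map(lambda t: Binary(*t)),
        children.map(lambda c: Unary("-", c)),
        children.map(lambda c: Unary("not", c)),
        st.tuples(st.sampled_from(["and", "or"]), children, children).map(
            lambda t: Binary(*t)
        ),
        st.tuples(chain_ops, children, children, children).map(
            lambda t: Chained((t[1], t[2], t[3]), t[0])
        ),
        _refs.map(lambda r: AttributeRef(r, "StartTime")),
        _refs.map(lambda r: FunctionCall("count", (r,))),
        _refs.map(lambda r: FunctionCall("attached", (r,))),
        st.tuples(children, children).map(lambda t: FunctionCall("diff", t)),
        st.just(FunctionCall("current_date_time", ())),
    )


_asts = st.recursive(st.one_of(_literals, _refs), _compounds, max_leaves=25)


class TestRoundTrip:
    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(_asts)
    def test_parse_inverts_unparse(self, ast):
        """parse(unparse(x)) structurally equals x for generated ASTs."""
        assert parse_expression(unparse(ast)) == ast

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(_asts)
    def test_definitions_round_trip(self, ast):
        node = Definition("derived_x", ast)
        assert parse_expression(unparse(node)) == node


# -- resolution --------------------------------------------------------------


def _registry_with_duplicate_wbc(demo_templates):
    registry = ConceptRegistry.from_templates(demo_templates)
    clone = {
        "template_id": "t_lab2",
        "concept_set_name": "lab2",
        "composition_id": "composition.lab2.v1",
        "archetypes": [
            {
                "archetype_id": "openEHR-EHR-OBSERVATION.lab_other.v1",
                "root": {
                    "node_id": "at0000",
                    "name": "Other lab",
                    "rm_type": "CLUSTER",
                    "path": "/lab2",
                    "children": [
                        {
                            "node_id": "at0001",
                            "name": "White blood cell count",
                            "rm_type": "DV_QUANTITY",
                            "units": "10^9/L",
                            "path": "/lab2/wbc",
                        }
                    ],
                },
            }
        ],
    }
    registry.add_template(load_template(clone))
    return registry


class TestResolution:
    def test_unique_name_binds_to_path(self, demo_registry):
        node = resolve_references(parse_expression("mmse < 24"), demo_registry)
        assert node.lhs.path == "/physical_sign/mmse"

    def test_names_are_case_insensitive_and_sanitized(self, demo_registry):
        node = resolve_references(parse_expression("[Body site]"), demo_registry)
        assert node.path == "/problem_diagnosis/body_site"

    def test_ambiguous_name_lists_candidates(self, demo_templates):
        registry = _registry_with_duplicate_wbc(demo_templates)
        with pytest.raises(AmbiguousReferenceError) as err:
            resolve_references(
                parse_expression("white_blood_cell_count > 10"), registry
            )
        assert sorted(err.value.candidates) == [
            "/lab2/wbc",
            "/lab_test/white_blood_cell_count",
        ]

    def test_ambiguity_resolvable_by_path_reference(self, demo_templates):
        registry = _registry_with_duplicate_wbc(demo_templates)
        node = resolve_references(
            parse_expression("[/lab2/wbc] > 10"), registry
        )
        assert node.lhs.path == "/lab2/wbc"

    def test_unknown_identifier_raises(self, demo_registry):
        with pytest.raises(UnresolvedReferenceError):
            resolve_references(parse_expression("no_such_thing = 1"), demo_registry)

    def test_derived_reference_recorded_as_dependency(self, demo_templates):
        registry = ConceptRegistry.from_templates(demo_templates)
        define_derived("chemotherapy := attached(altretamine) or attached(bendamustine)", registry)
        outer = define_derived("recent_chemo := chemotherapy", registry)
        assert outer.dependencies == {"chemotherapy"}

    def test_derived_name_clash_with_concept_rejected(self, demo_templates):
        registry = ConceptRegistry.from_templates(demo_templates)
        with pytest.raises(RegistryCollisionError):
            define_derived("mmse := moca", registry)


class TestDependencyOrder:
    def test_obesity_chain_orders_intermediates_first(self, demo_templates):
        registry = ConceptRegistry.from_templates(demo_templates)
        bmi = define_derived("bmi_value := weight / height ^ 2", registry)
        bmi_ob = define_derived("bmi_obesity := bmi_value >= 28", registry)
        icd = define_derived("icd_10_obesity := obesity", registry)
        dx = define_derived(
            'obesity_diagnosis := contains(clinical_description, "obesity")', registry
        )
        top = define_derived(
            "obesity_overweight := obesity_diagnosis or icd_10_obesity or bmi_obesity",
            registry,
        )
        order = [d.name for d in dependency_order([top, icd, bmi_ob, dx, bmi])]
        assert order.index("bmi_value") < order.index("bmi_obesity")
        assert order.index("bmi_obesity") < order.index("obesity_overweight")
        assert order.index("icd_10_obesity") < order.index("obesity_overweight")
        assert order.index("obesity_diagnosis") < order.index("obesity_overweight")

    def test_cycle_is_reported_with_members(self):
        a = DerivedConcept("a", ConceptRef("b", derived=True), {"b"})
        b = DerivedConcept("b", ConceptRef("a", derived=True), {"a"})
        with pytest.raises(DependencyCycleError) as err:
            dependency_order([a, b])
        assert set(err.value.members) == {"a", "b"}

    def test_independent_definitions_valid_against_reachability(self):
        """Any emitted order must put dependencies first; verify against a
        brute-force reachability check."""
        items = [
            DerivedConcept("d1", Literal(1), set()),
            DerivedConcept("d2", Literal(1), {"d1"}),
            DerivedConcept("d3", Literal(1), set()),
            DerivedConcept("d4", Literal(1), {"d2", "d3"}),
        ]
        order = [d.name for d in dependency_order(items)]
        deps = {d.name: d.dependencies for d in items}
        for i, name in enumerate(order):
            for dep in deps[name]:
                assert order.index(dep) < i

    def test_collect_dependencies_walks_every_branch(self, demo_registry):
        node = resolve_references(
            parse_expression("mmse < 24 and attached(aspirin) or not (weight > 50)"),
            demo_registry,
        )
        assert collect_dependencies(node) == {
            "/physical_sign/mmse",
            "/order/order_item/ASA",
            "/physical_sign/weight",
        }
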