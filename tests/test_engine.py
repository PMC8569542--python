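"""Reference evaluator semantics, compiler, IR interpreter, DSL emission."""

import datetime as dt
import json
import random

import pytest

from ehrscreen import (
    Group,
    PatientStore,
    ScreeningCondition,
    compile_condition,
    define_derived,
    emit_es_query,
    evaluate,
    flatten_entry,
    run_ir,
    screen,
)
from ehrscreen.errors import CompilationError, UnitMismatchError
from ehrscreen.synth import build_demo_context

import condgen


@pytest.fixture()
def ctx():
    templates, registry, schemas = build_demo_context()
    by_name = {t.concept_set_name: t for t in templates}
    store = PatientStore(registry, schemas, clock=dt.datetime(2024, 1, 1))
    return by_name, store


def _sign_entry(by_name, when="2022-05-01T09:00:00", **values):
    paths = {
        "sbp": "/physical_sign/systolic_blood_pressure",
        "hr": "/physical_sign/heart_rate",
        "spo2": "/physical_sign/blood_oxygen_saturation",
        "temp": "/physical_sign/body_temperature",
        "mmse": "/physical_sign/mmse",
        "weight": "/physical_sign/weight",
        "height": "/physical_sign/height",
    }
    data = {"/physical_sign/measurement_time": when}
    for key, value in values.items():
        data[paths[key]] = value
    return flatten_entry(by_name["physical_sign"], data, "ignored")


def _lab_entry(by_name, when, wbc):
    return flatten_entry(
        by_name["lab_test"],
        {
            "/lab_test/specimen_collection_time": when,
            "/lab_test/white_blood_cell_count": wbc,
        },
        "ignored",
    )


class TestEvaluatorSemantics:
    def test_bare_comparison_is_existential(self, ctx):
        by_name, store = ctx
        store.add_entry("physical_sign", "P1", _sign_entry(by_name, mmse=23))
        store.add_entry(
            "physical_sign", "P1", _sign_entry(by_name, "2022-06-01T09:00:00", mmse=25)
        )
        store.add_entry("physical_sign", "P2", _sign_entry(by_name, mmse=27))
        assert evaluate("mmse < 24", store) == {"P1"}

    def test_missing_concept_makes_comparison_false(self, ctx):
        by_name, store = ctx
        store.add_entry("physical_sign", "P1", _sign_entry(by_name, sbp=120))
        assert evaluate("mmse < 24", store) == set()
        assert evaluate("attached(mmse)", store) == set()
        # ...but its negation is then true
        assert evaluate("not (mmse < 24)", store) == {"P1"}

    def test_stable_condition_conjunction_matches(self, ctx):
        """A patient with SBP 130, HR 70, SpO2 95, T 37 satisfies the
        vital-signs stability expression."""
        by_name, store = ctx
        store.add_entry(
            "physical_sign", "P1", _sign_entry(by_name, sbp=130, hr=70, spo2=95, temp=37)
        )
        store.add_entry(
            "physical_sign", "P2", _sign_entry(by_name, sbp=130, hr=70, spo2=95, temp=39.5)
        )
        text = (
            "(systolic_blood_pressure >= 120 and systolic_blood_pressure <= 220)"
            " and (40 <= heart_rate <= 100) and blood_oxygen_saturation >= 92"
            " and body_temperature <= 38.5"
        )
        assert evaluate(text, store) == {"P1"}

    def test_collection_functions_order_by_start_time(self, ctx):
        by_name, store = ctx
        store.add_entry("lab_test", "P1", _lab_entry(by_name, "2022-03-01T08:00:00", 12.0))
        store.add_entry("lab_test", "P1", _lab_entry(by_name, "2022-01-01T08:00:00", 6.0))
        store.add_entry("lab_test", "P1", _lab_entry(by_name, "2022-02-01T08:00:00", 8.0))
        assert evaluate("white_blood_cell_count.last() > 10", store) == {"P1"}
        assert evaluate("white_blood_cell_count.first() > 5.9", store) == {"P1"}
        assert evaluate(
            "white_blood_cell_count.last() < white_blood_cell_count.first()", store
        ) == set()
        assert evaluate("white_blood_cell_count.count() = 3", store) == {"P1"}
        assert evaluate(
            "white_blood_cell_count.max() - white_blood_cell_count.min() < 6.1", store
        ) == {"P1"}

    def test_count_of_missing_concept_is_zero(self, ctx):
        by_name, store = ctx
        store.add_entry("physical_sign", "P1", _sign_entry(by_name, sbp=120))
        assert evaluate("white_blood_cell_count.count() = 0", store) == {"P1"}

    def test_unit_mismatch_raises(self, ctx):
        by_name, store = ctx
        store.add_entry("physical_sign", "P1", _sign_entry(by_name, weight=70.0, sbp=130.0))
        with pytest.raises(UnitMismatchError):
            evaluate("weight > systolic_blood_pressure", store)

    def test_chain_binds_one_record_jointly(self, ctx):
        """27<mmse<30 requires a single record in the window, not two
        records satisfying one bound each."""
        by_name, store = ctx
        store.add_entry("physical_sign", "P1", _sign_entry(by_name, mmse=26))
        store.add_entry(
            "physical_sign", "P1", _sign_entry(by_name, "2022-06-01T09:00:00", mmse=30)
        )
        store.add_entry("physical_sign", "P2", _sign_entry(by_name, mmse=28))
        assert evaluate("27 < mmse < 30", store) == {"P2"}
        assert evaluate("(27 < mmse) and (mmse < 30)", store) == {"P1", "P2"}

    def test_derived_concepts_evaluate_lazily_and_inlined_equally(self, ctx):
        by_name, store = ctx
        registry = store.registry
        define_derived("bmi_obesity := bmi >= 28", registry)
        define_derived("icd_10_obesity := obesity", registry)
        define_derived(
            'obesity_diagnosis := contains(clinical_description, "obesity")', registry
        )
        define_derived(
            "obesity_overweight := obesity_diagnosis or icd_10_obesity or bmi_obesity",
            registry,
        )
        # P1 by BMI (100kg / 1.8m^2 = 30.9), P2 by diagnosis code, P3 neither
        store.add_entry(
            "physical_sign", "P1", _sign_entry(by_name, weight=100.0, height=1.8)
        )
        store.add_entry(
            "problem_diagnosis",
            "P2",
            flatten_entry(
                by_name["problem_diagnosis"],
                {
                    "/problem_diagnosis/diagnosis": "E66",
                    "/problem_diagnosis/date_of_onset": "2021-01-01T00:00:00",
                },
                "ignored",
            ),
        )
        store.add_entry(
            "physical_sign", "P3", _sign_entry(by_name, weight=60.0, height=1.8)
        )
        from ehrscreen import inline_derived, parse_expression, resolve_references

        lazy = evaluate("obesity_overweight", store)
        expanded = inline_derived(
            resolve_references(parse_expression("obesity_overweight"), registry),
            registry,
        )
        assert lazy == evaluate(expanded, store) == {"P1", "P2"}


class TestScreen:
    def test_groups_intersect_and_counts_are_per_group(self, ctx):
        by_name, store = ctx
        store.add_entry("physical_sign", "P1", _sign_entry(by_name, mmse=20, sbp=150))
        store.add_entry("physical_sign", "P2", _sign_entry(by_name, mmse=20, sbp=120))
        store.add_entry("physical_sign", "P3", _sign_entry(by_name, mmse=28, sbp=150))
        condition = ScreeningCondition(
            [Group(members=["mmse < 24"]), Group(members=["systolic_blood_pressure > 140"])]
        )
        result = screen(condition, store)
        assert result.patients == {"P1"}
        assert result.group_counts == [2, 2]

    def test_adding_a_group_never_grows_the_result(self, ctx):
        by_name, store = ctx
        store.add_entry("physical_sign", "P1", _sign_entry(by_name, mmse=20, sbp=150))
        store.add_entry("physical_sign", "P2", _sign_entry(by_name, mmse=20))
        base = ScreeningCondition([Group(members=["mmse < 24"])])
        extended = ScreeningCondition(
            base.groups + [Group(members=["systolic_blood_pressure > 100"])]
        )
        assert evaluate(extended, store) <= evaluate(base, store)

    def test_condition_json_round_trip(self):
        condition = ScreeningCondition(
            [Group(members=["mmse < 24", "moca < 26"], constraints=["mmse.count() > 1"])]
        )
        clone = ScreeningCondition.from_json(condition.to_json())
        assert clone.to_json() == condition.to_json()


class TestCompiler:
    def test_demographic_condition_compiles_without_postfilter(self, ctx):
        """Sex + age bounds become pure index predicates (term + ranges on
        the birth-date field)."""
        _by_name, store = ctx
        condition = ScreeningCondition(
            [Group(members=['sex = "Female"']), Group(members=["20 <= age <= 60"])]
        )
        ir = compile_condition(condition, store.registry, store.schemas, clock=store.clock)
        doc = json.loads(emit_es_query(ir))
        assert all(g["post_filters"] == [] for g in doc["groups"])
        text = json.dumps(doc)
        assert '"entries.person_Sex_keyword": "Female"' in text
        assert '"range": {"entries.person_Date_of_birth"' in json.dumps(doc, separators=(", ", ": "))

    def test_decrease_constraint_becomes_candidate_plus_postfilter(self, ctx):
        _by_name, store = ctx
        condition = ScreeningCondition(
            [
                Group(
                    members=[
                        "white_blood_cell_count.last() < white_blood_cell_count.first()"
                    ]
                )
            ]
        )
        ir = compile_condition(condition, store.registry, store.schemas)
        doc = json.loads(emit_es_query(ir))
        (group,) = doc["groups"]
        assert group["post_filters"] == [
            "white_blood_cell_count.last() < white_blood_cell_count.first()"
        ]
        assert "exists" in json.dumps(group["index_queries"]["lab_test"])

    def test_empty_condition_rejected(self, ctx):
        _by_name, store = ctx
        with pytest.raises(CompilationError):
            compile_condition(ScreeningCondition([]), store.registry, store.schemas)

    def test_unmapped_concept_rejected(self, ctx):
        _by_name, store = ctx
        schemas = {k: v for k, v in store.schemas.items() if k != "lab_test"}
        with pytest.raises(CompilationError):
            compile_condition(
                ScreeningCondition([Group(members=["white_blood_cell_count > 10"])]),
                store.registry,
                schemas,
            )

    def test_term_and_range_shapes(self, ctx):
        _by_name, store = ctx
        condition = ScreeningCondition(
            [Group(members=["attached(cerebral_hemorrhage)"]), Group(members=["mmse < 24"])]
        )
        doc = json.loads(emit_es_query(compile_condition(condition, store.registry, store.schemas)))
        g1, g2 = doc["groups"]
        q1 = g1["index_queries"]["problem_diagnosis"]["query"]
        assert q1["nested"]["query"] == {
            "term": {"entries.problem_diagnosis_Diagnosis_code": "I61"}
        }
        q2 = g2["index_queries"]["physical_sign"]["query"]
        assert q2["nested"]["query"] == {"range": {"entries.physical_sign_MMSE": {"lt": 24}}}

    def test_postfilter_only_group_emits_match_all(self, ctx):
        _by_name, store = ctx
        condition = ScreeningCondition(
            [Group(members=["white_blood_cell_count.count() = 0"])]
        )
        doc = json.loads(emit_es_query(compile_condition(condition, store.registry, store.schemas)))
        (group,) = doc["groups"]
        assert group["index_queries"] == {"_all": {"query": {"match_all": {}}}}
        assert group["post_filters"] == ["white_blood_cell_count.count() = 0"]

    def test_emission_is_byte_stable(self, ctx):
        _by_name, store = ctx
        condition = ScreeningCondition([Group(members=["mmse < 24"])])
        ir = compile_condition(condition, store.registry, store.schemas)
        assert emit_es_query(ir) == emit_es_query(ir)


class TestCompilerEquivalence:
    def test_run_ir_equals_evaluate_on_random_conditions(self):
        """Fuzz: compiled IR and the reference engine agree patient-for-
        patient on a seeded store."""
        from ehrscreen import GeneratorConfig, generate_store

        store, _ = generate_store(GeneratorConfig(n_patients=120, seed=3))
        condgen.bind_order_intervals(store)
        rng = random.Random(42)
        for _ in range(30):
            condition = condgen.random_condition(rng)
            expected = evaluate(condition, store)
            ir = compile_condition(
                condition, store.registry, store.schemas, clock=store.clock
            )
            assert run_ir(ir, store) == expected, condition.to_json()
            assert run_ir(ir, store, drop_postfilters=True) >= expected

    def test_nested_scope_matches_qualifying_subdocument_only(self, ctx):
        by_name, store = ctx
        entry = flatten_entry(
            by_name["lab_test"],
            {
                "/lab_test/specimen_collection_time": "2021-01-01T08:00:00",
                "/lab_test/microbiology_finding": [
                    {
                        "/lab_test/microbiology_finding/organism": "ECOLI",
                        "/lab_test/microbiology_finding/colony_count": 30,
                    }
                ],
            },
            "ignored",
        )
        store.add_entry("lab_test", "P1", entry)
        entry2 = flatten_entry(
            by_name["lab_test"],
            {
                "/lab_test/specimen_collection_time": "2021-01-01T08:00:00",
                "/lab_test/microbiology_finding": [
                    {
                        "/lab_test/microbiology_finding/organism": "SAUR",
                        "/lab_test/microbiology_finding/colony_count": 500,
                    }
                ],
            },
            "ignored",
        )
        store.add_entry("lab_test", "P2", entry2)
        condition = ScreeningCondition([Group(members=["colony_count > 100"])])
        ir = compile_condition(condition, store.registry, store.schemas)
        assert run_ir(ir, store) == evaluate(condition, store) == {"P2"}
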