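# ehrscreen

Patient screening for clinical research over electronic health records.

Recruiting for a clinical study starts with eligibility criteria — "female
patients aged 60–70 diagnosed with cerebral hemorrhage or cerebral
infarction taking aspirin" — that someone has to turn into queries against
the hospital's clinical data repository. Two things make that hard. First,
many criteria mention *derived* concepts that are not stored anywhere
(body-mass index, "chemotherapy" as a family of drugs, "cognitive
impairment" as a diagnosis *or* a low test score). Second, criteria that
join demographics, diagnoses, labs and orders are awkward and slow as
multi-table SQL.

`ehrscreen` addresses both, for informaticians and study coordinators who
work with openEHR-style data:

* **Concepts from clinical templates.** Templates (a composition importing
  entry archetypes, in a small JSON dialect) are walked by five rules into a
  registry of screening concepts with the attributes *Name, Parent, Path,
  Type, Unit, StartTime, EndTime, Value*. Attribute nodes become concepts;
  `units` of a `DV_QUANTITY` becomes the unit; every defining code of a
  `DV_CODED_TEXT` becomes a sub-concept (so `aspirin` and
  `cerebral_hemorrhage` are first-class names). Event times are bound per
  concept at screening time, since "the" timestamp of a lab value is a
  study-level choice.

* **An eligibility expression language.** Criteria are written in a small
  expression language (an openEHR Expression Language subset):
  `BMI := weight / height ^ 2`, `27 < mmse < 30`,
  `attached(aspirin) or attached(clopidogrel)`,
  `wbc.last() < wbc.first()`,
  `diff(current_date_time(), heparin.StartTime) <= PT48H`.
  `name := expr` definitions introduce derived concepts that nest; the
  dependency graph is topologically ordered before use. All 13 Allen
  relations between two events ship as endpoint-chain templates
  (`a.StartTime<a.EndTime=b.StartTime<b.EndTime` is *Meets*), alongside an
  interval extension for durations between events and predefined collection
  constraints (*First time, Stable, Increase, Decrease*) that users can
  extend.

* **A document-index execution model.** Each composition template maps to
  one hierarchical index schema: typed fields, dual keyword/fulltext fields
  for text values, collection clusters as nested sub-documents, and
  archetype-prefixed field names (`problem_diagnosis_Body_site`). A
  patient's records in one index form a single document, so cross-source
  criteria intersect patient-id sets instead of joining tables. Conditions
  compile to a backend-agnostic boolean IR — same-entry field predicates
  plus client-side post-filters for cross-record aggregates and temporal
  chains — from which Elasticsearch 7.x Query DSL is emitted. A reference
  in-memory engine defines the exact semantics; the compiled form is
  checked against it, mirroring the methodological requirement that both
  execution routes return identical result counts.

A seeded synthetic-data module generates patient stores over the bundled
seven-template demo set (person, admission, lab test, order, imaging,
physical sign, problem diagnosis) and plants known-eligible patients for
six benchmark screening queries, so every query has a ground-truth answer
by construction.

## Worked example

Generate a 300-patient store with six known-eligible patients planted for
the stroke cohort query, then screen:

```bash
ehrscreen generate --n 300 --seed 7 --plant query3=6 --out demo
# wrote 300 patients to demo (12 ground-truth matches)

cat > demo/stroke.el <<'EOF'
sex = "Female"
60 <= age <= 70
attached(cerebral_hemorrhage) or attached(cerebral_infarction)
EOF

ehrscreen screen --condition demo/stroke.el --data demo/documents.ndjson
# patients matched: 12
# group 1: 134
# group 2: 52
# group 3: 48
```

Each line of the `.el` file is one AND-ed group (disjunction is written
inside a group). The per-group counts are the feedback a condition builder
shows while editing: 134 of the 300 patients are female, 52 are aged 60–70
(`age` is a bundled derived concept computed from the birth date at the
evaluation clock), 48 carry one of the two stroke codes — and 12 satisfy
all three groups: the 6 planted patients plus 6 incidental matches, exactly
the set listed in `demo/ground_truth.json`.

`ehrscreen compile --condition demo/stroke.el` prints the emitted
Elasticsearch query (term on `person_Sex_keyword`, date ranges on
`person_Date_of_birth`, a term on `problem_diagnosis_Diagnosis_code` —
no post-filters needed for this condition), and
`ehrscreen concepts` exports the concept registry as CSV.

## Layout

| Module | Purpose |
| --- | --- |
| `ehrscreen.templates` | template dialect, concept definition rules, registry |
| `ehrscreen.expressions` | grammar, AST, parser/unparser, resolution, derived concepts |
| `ehrscreen.constraints` | Allen relations, interval extension, collection constraints |
| `ehrscreen.indexing` | data-type/field mapping, schemas, flattening, ES mappings |
| `ehrscreen.engine` | reference evaluator, compiler, IR interpreter, Query DSL |
| `ehrscreen.synth` | seeded synthetic stores and benchmark scenarios |
| `ehrscreen.cli` | `ehrscreen` command-line entry point |

Design notes and modelling assumptions are in `docs/methods.md`; the
grammar ships as `src/ehrscreen/data/grammar.ebnf`.
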