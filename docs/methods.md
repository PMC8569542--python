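# Methods and design notes

## Scope and model

The package turns eligibility criteria into executable queries over an
EHR-shaped document store in four stages: (1) screening concepts are
defined from clinical templates; (2) criteria are written in a small
expression language, with derived concepts layered over simple ones;
(3) templates are mapped to hierarchical index schemas and patient entries
flattened into documents; (4) conditions compile to a boolean query IR
executed either by emitting search-engine Query DSL or by the bundled
reference engine. The reference engine is the executable definition of the
semantics; the compiler is correct exactly when it agrees with it.

## Concept definition

A template is one concept set. Every attribute node yields a concept whose
name is the node's ontology name, whose type is the node's reference-model
type, and whose path (the identifier) is the node's template path; parents
are recovered from path prefixes. `DV_QUANTITY.units` populates the unit
attribute; each defining code of a `DV_CODED_TEXT` node becomes a
sub-concept under that node's concept, so coded values are addressable by
name. Concept names are display labels and may collide across templates —
paths are the only identifiers. Bare names in expressions resolve through a
sanitized, case-insensitive index; an ambiguous name is an error listing
the candidate paths, and a `[/literal/path]` reference disambiguates.

StartTime/EndTime are deliberately not extracted from templates: a lab
value's event time may be the specimen time or the result time depending on
the study, so bindings are set per concept at screening time
(`bind_time_attributes`). Unbound concepts fall back to the entry's
timestamp for StartTime and reuse StartTime for EndTime, which makes
instantaneous records usable in `diff()` comparisons but (intentionally)
never satisfiable by the strict two-event relation chains.

Template-level default values are recorded on `Concept.value` but never
applied during screening; nothing in the execution semantics consults them.

## Expression language

The grammar covers what printed screening criteria actually use:
arithmetic, relational and logical operators, chained comparisons,
collection functions (`count/max/min/first/last`), `attached()`,
`contains()` for free-text fields, `diff()` and `current_date_time()` for
time, ISO-8601 duration literals, and `:=` definitions. Precedence, from
loosest: `or` < `and` < `not` < comparisons < `+ -` < `* /` < unary `-`
< `^`. Chains may interleave `=` with one direction of inequalities —
required by the two-event endpoint chains (`Meets` is
`a.StartTime<a.EndTime=b.StartTime<b.EndTime`). `=` is equality; `:=`
introduces definitions. `contains` is this package's fulltext operator:
the base operator set has no free-text predicate, and dual-indexed text
fields are unreachable without one.

Duration literals use fixed-length calendar units (1 Y = 365.25 d,
1 M = 30.4375 d) because the language has no calendar context; `P` followed
by a digit is reserved for durations, so identifiers cannot take that
shape. Canonical unparsing inserts minimal parentheses and is an exact
structural inverse of parsing (`parse(unparse(x)) = x`), property-tested on
random ASTs.

Derived concepts must be defined dependencies-first, which keeps the graph
acyclic by construction; `dependency_order` still performs an explicit
topological sort (name-ordered among ready nodes, cycles reported with
members) for libraries loaded from files. Evaluation expands derived
references lazily at boolean positions and inlines them inside comparison
atoms; compilation fully inlines first. Both routes are checked equal.

## Evaluation semantics

Per patient:

* A comparison atom over repeated records is **existential**: true iff some
  record satisfies it. Within one atom (including a whole chained
  comparison) each referenced concept is bound to a *single* record
  jointly — `27<mmse<30` needs one score inside the window, and a two-event
  relation chain quantifies over pairs of events, not endpoints
  independently. Across atoms, quantifiers are independent and boolean
  operators compose truth values; `not` therefore negates the existential
  (patients with no MMSE record satisfy `not (mmse < 24)`).
* Collection functions aggregate the patient's records ordered by bound
  StartTime, ties broken by record position. `count()` of an absent concept
  is 0; the other aggregates make the enclosing comparison false.
* A missing concept or attribute makes comparisons and `attached()` false —
  never an error. The one hard error is comparing two quantities with
  different unit strings (`UnitMismatchError`); there is no unit
  conversion, by design. Quantity-vs-number comparisons use the magnitude.
* `current_date_time()` reads the store's injected clock, so screenings are
  reproducible; age-style criteria are expressed as
  `diff(current_date_time(), date_of_birth) / P1Y`.

The existential reading of bare comparisons is a modelling choice the
language itself does not force; it is isolated in the atom evaluator and
could be switched to a universal (per-group) reading without touching the
grammar.

## Index mapping

Each composition template maps to exactly one index. Leaf types map as:
boolean/count/date/duration/uri → single typed value field; quantity →
magnitude (double) + units (keyword); identifier → keyword; text and coded
text → keyword *and* fulltext fields (suffixes `_keyword`/`_text`), coded
text additionally a `_code` keyword field. That is 10 reference-model
types over 12 attribute rows, audited in the tests. Field names prefix the
archetype concept name and join ontology-name words with underscores
("Body site" in the problem-diagnosis archetype → 
`problem_diagnosis_Body_site`), recursing through intermediate clusters;
sanitization replaces non-alphanumeric runs with `_`. Slotted
(non-collection) clusters are flattened into the entry; collection
clusters become nested fields whose sub-documents keep their structure.

One document per patient per index holds all of that patient's entries as
a nested list, each entry stamped with a timestamp taken from a
configurable source node (default: the template's first date/time node in
document order). This is what removes joins: any cross-entry or
cross-source condition is answerable from per-patient documents and
patient-id set algebra. The alternative — one document per encounter —
would shift collection functions onto the client for no benefit at this
scale. Entity-framework indirection is skipped entirely: schemas and
documents are emitted directly. The Elasticsearch emitter is pinned to the
7.x mapping dialect and versioned so other dialects can be added.

## Compilation and the two-phase execution model

Atoms that touch a single concept and a record-free side compile to
**same-entry field tests** (term/range/exists, nested-scoped where the
value lives in a collection cluster; a defining-code sub-concept
contributes its code equality to the same entry scope). Equality on coded
and text values targets `_keyword` fields; `contains` targets `_text`
fields; date-valued tests compare as dates. Clock-relative forms
`diff(current_date_time(), x) cmp D` and `… / D1 cmp n` are rewritten to
date-range predicates on the underlying field — an exact monotone
transform, so age bounds need no post-filter.

Everything else — cross-record aggregates (`last() < first()`,
`max()-min()`), two-event chains, multi-concept arithmetic — becomes a
client-side **post-filter** (the atom evaluated by the reference engine)
conjoined with candidate-narrowing presence predicates for every concept
whose records the atom requires. `count()` comparisons get no presence
candidate, because `count() = 0` is true precisely for patients without
records. A `not` over a subtree containing a post-filter lifts the whole
negation into one post-filter, keeping the invariant that dropping all
post-filters can only widen the result (verified on randomized
conditions). Pure Query DSL cannot express the cross-record comparisons at
all, so the split is forced; pushing them into server-side scripts is the
plausible alternative and would change only the back end behind the IR.

The emitted DSL groups candidate queries per index per condition group;
group results intersect by patient id client-side. `match` is used for
`contains` in the DSL; tokenized match and the engine's case-insensitive
substring test can disagree on a live server — the IR interpreter, not the
DSL, is the checked execution route.

## Synthetic data

The generator emulates a cerebrovascular-disease repository at desk scale:
per patient one demographic record; Poisson counts of admissions (mean
1.2), vitals (2.0) and labs (2.0); imaging with probability 0.35; coded
diagnoses by prevalence (hypertension 0.25, cerebral infarction 0.10,
obesity 0.08, hemorrhage 0.06, cognitive impairment 0.05, subarachnoid
hemorrhage 0.03); drug/procedure orders by prevalence (aspirin 0.25 down
to 0.02); WBC normal around 6.5×10⁹/L. Values are rounded so serialized
stores are byte-stable under a fixed seed. Vocabularies are tiny bundled
code lists, not licensed terminology subsets.

Scenario plants force eligibility (set sex/birth date, add a diagnosis,
order or lab) on disjoint seeded patient blocks; ground truth is then
recomputed over the whole store, so incidental matches are included by
construction. What the generator does **not** model: realistic visit
longitudinality, correlated comorbidity, free-text beyond a four-item
findings pool, terminology breadth, or missingness mechanisms — so green
tests demonstrate semantic correctness of the machinery, not clinical
validity of any particular criterion on real data.

Test problem sizes were chosen to exercise the properties convincingly at
interactive cost: exhaustive interval enumeration on a [0,4] integer grid
(100 pairs — every endpoint ordering of two strict intervals occurs),
1,200 random ASTs for round-tripping, 1,000 random chains for desugaring,
100 random conditions against a 220-patient store for compiler agreement,
and 300-patient stores for the six benchmark scenarios.

## Known limitations

* No unit conversion; unit strings must match exactly.
* Timezone-naive timestamps interpreted on a single clock; dates at
  midnight.
* Fixed-length calendar units in durations (documented above).
* Occurrence upper bounds in templates are recorded but not enforced on
  data.
* The expression subset excludes quantifiers, interval types, and complex
  collection computations (e.g. averaged rates per week) — consistent with
  the constraint families the tool is scoped to.
* The live-search integration path is limited to emitting mapping and
  query JSON; no client round-trip is attempted.
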