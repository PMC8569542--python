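"""Seeded synthetic patient stores over the bundled demo templates.

The generator emulates the shape of a hospital clinical data repository for
cerebrovascular disease at desk scale: demographics, admissions, physical
signs (including MMSE/MoCA scores), laboratory tests (white blood cell
count and friends, with an occasional microbiology collection cluster),
medication/procedure orders, imaging reports with free-text findings, and
coded problem diagnoses over a tiny ICD-10-like vocabulary (cerebral
hemorrhage I61, cerebral infarction I63, ...).

Scenario builders plant known-eligible patients for six benchmark screening
queries (single-concept procedure lookup, demographic filters, multi-source
conjunctions, and a collection-function query on the last WBC value), so
every query has a ground-truth answer by construction. Ground-truth sets
are produced by the reference evaluator and can be re-derived by brute
force. A fixed seed fully determines the store, byte for byte.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import PatientStore, Group, ScreeningCondition, evaluate
from .errors import ConfigError
from .expressions import define_derived
from .indexing import build_schemas, emit_es_mapping, flatten_entry, write_documents
from .templates import ConceptRegistry, load_demo_templates

_DEFAULT_CLOCK = _dt.datetime(2024, 1, 1)

DIAGNOSIS_PREVALENCE = {
    "I61": 0.06,  # cerebral hemorrhage
    "I63": 0.10,  # cerebral infarction
    "I60": 0.03,  # subarachnoid hemorrhage
    "I10": 0.25,  # hypertension
    "E66": 0.08,  # obesity
    "F00": 0.05,  # cognitive impairment
}

ORDER_PREVALENCE = {
    "ASA": 0.25,
    "CLO": 0.10,
    "HEP": 0.08,
    "SUL": 0.03,
    "RIS": 0.03,
    "ALT": 0.02,
    "BEN": 0.02,
    "EVAC": 0.04,
    "THROMB": 0.03,
}

_FINDINGS_POOL = (
    "No acute intracranial abnormality",
    "Intracerebral hematoma in the left basal ganglia",
    "Chronic lacunar infarcts, no hemorrhage",
    "Severe coronary stenosis suspected on scout view",
)

_WARDS = ("Neurology", "Neurosurgery", "Geriatrics", "Emergency")


def build_demo_context():
    """(templates, registry, schemas) for the bundled demo set.

    Registers the standard derived concepts used by the benchmark queries:
    ``age`` (years from date of birth at the evaluation clock) and ``bmi``.
    """
    templates = load_demo_templates()
    registry = ConceptRegistry.from_templates(templates)
    define_derived("age := diff(current_date_time(), date_of_birth) / P1Y", registry)
    define_derived("bmi := weight / height ^ 2", registry)
    schemas = build_schemas(templates)
    return templates, registry, schemas


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic store."""

    n_patients: int = 300
    seed: int = 0
    clock: _dt.datetime = _DEFAULT_CLOCK
    sex_female_p: float = 0.5
    age_range: tuple = (18.0, 90.0)  # years at clock
    #: mean records per patient per source
    record_rates: dict = field(
        default_factory=lambda: {
            "patient_admission": 1.2,
            "physical_sign": 2.0,
            "lab_test": 2.0,
            "imaging_examination": 0.35,  # Bernoulli
        }
    )
    diagnosis_prevalence: dict = field(default_factory=lambda: dict(DIAGNOSIS_PREVALENCE))
    order_prevalence: dict = field(default_factory=lambda: dict(ORDER_PREVALENCE))
    #: (scenario label, number of planted eligible patients)
    plant: list = field(default_factory=list)


# --------------------------------------------------------------------------
# Benchmark screening conditions
# --------------------------------------------------------------------------


def scenario_conditions() -> dict:
    """The six benchmark screening conditions, by label."""
    return {
        "query1": ScreeningCondition(
            [Group(members=["attached(evacuation_of_intracerebral_hematoma)"])]
        ),
        "query2": ScreeningCondition(
            [
                Group(members=['sex = "Female"']),
                Group(members=["20 <= age <= 60"]),
            ]
        ),
        "query3": ScreeningCondition(
            [
                Group(members=['sex = "Female"']),
                Group(members=["60 <= age <= 70"]),
                Group(
                    members=[
                        "attached(cerebral_hemorrhage)",
                        "attached(cerebral_infarction)",
                    ]
                ),
            ]
        ),
        "query4": ScreeningCondition(
            [
                Group(members=['sex = "Female"']),
                Group(members=["60 <= age <= 70"]),
                Group(
                    members=[
                        "attached(cerebral_hemorrhage)",
                        "attached(cerebral_infarction)",
                    ]
                ),
                Group(members=["attached(aspirin)"]),
            ]
        ),
        "query5": ScreeningCondition(
            [
                Group(members=['sex = "Female"']),
                Group(members=["60 <= age <= 70"]),
                Group(
                    members=[
                        "attached(cerebral_hemorrhage)",
                        "attached(cerebral_infarction)",
                    ]
                ),
                Group(members=["attached(white_blood_cell_count)"]),
                Group(members=["attached(aspirin)"]),
            ]
        ),
        "query6": ScreeningCondition(
            [Group(members=["white_blood_cell_count.last() > 10"])]
        ),
    }


SCENARIO_DESCRIPTIONS = {
    "query1": "patients with an evacuation-of-intracerebral-hematoma procedure",
    "query2": "female patients aged 20-60",
    "query3": "female patients aged 60-70 with cerebral hemorrhage or infarction",
    "query4": "query3 cohort additionally taking aspirin",
    "query5": "query4 cohort additionally with a WBC laboratory result",
    "query6": "patients whose most recent WBC count exceeds 10 x 10^9/L",
}


# --------------------------------------------------------------------------
# Profile generation
# --------------------------------------------------------------------------


def _event_time(rng, clock) -> _dt.datetime:
    days = float(rng.uniform(1.0, 1825.0))
    return clock - _dt.timedelta(days=days, seconds=float(rng.integers(0, 86400)))


def _base_profile(rng, idx: int, config: GeneratorConfig) -> dict:
    clock = config.clock
    age = float(rng.uniform(*config.age_range))
    dob = clock - _dt.timedelta(days=age * 365.25 + float(rng.uniform(0, 0.9)))
    profile = {
        "sex": "F" if rng.random() < config.sex_female_p else "M",
        "dob": dob,
        "identifier": f"MRN{idx:06d}",
        "name": f"Patient {idx:04d}",
        "admissions": [],
        "signs": [],
        "labs": [],
        "diagnoses": [],
        "orders": [],
        "imaging": [],
    }
    for _ in range(int(rng.poisson(config.record_rates["patient_admission"]))):
        adm = _event_time(rng, clock)
        stay = _dt.timedelta(days=float(rng.uniform(1, 20)))
        profile["admissions"].append(
            {
                "ward": _WARDS[int(rng.integers(0, len(_WARDS)))],
                "admission": adm,
                "discharge": adm + stay,
                "stay": stay,
                "readmission": bool(len(profile["admissions"])),
            }
        )
    for _ in range(int(rng.poisson(config.record_rates["physical_sign"]))):
        sign = {
            "t": _event_time(rng, clock),
            "sbp": round(float(rng.normal(130, 20)), 1),
            "dbp": round(float(rng.normal(80, 12)), 1),
            "hr": round(float(rng.normal(75, 12)), 1),
            "spo2": round(float(np.clip(rng.normal(96, 2), 70, 100)), 1),
            "temp": round(float(rng.normal(36.8, 0.5)), 1),
            "height": round(float(rng.normal(1.65, 0.1)), 2),
            "weight": round(float(rng.normal(65, 12)), 1),
        }
        if rng.random() < 0.5:
            sign["mmse"] = int(rng.integers(8, 31))
        if rng.random() < 0.5:
            sign["moca"] = int(rng.integers(5, 31))
        profile["signs"].append(sign)
    for _ in range(int(rng.poisson(config.record_rates["lab_test"]))):
        t = _event_time(rng, clock)
        lab = {
            "t": t,
            "wbc": round(max(0.5, float(rng.normal(6.5, 2.5))), 1),
            "micro": [],
        }
        if rng.random() < 0.7:
            lab["hgb"] = round(float(rng.normal(135, 18)), 1)
        if rng.random() < 0.7:
            lab["plt"] = round(max(20.0, float(rng.normal(250, 60))), 1)
        if rng.random() < 0.7:
            lab["glu"] = round(max(2.0, float(rng.normal(5.6, 1.4))), 1)
        if rng.random() < 0.15:
            for _m in range(int(rng.integers(1, 3))):
                lab["micro"].append(
                    {
                        "organism": "ECOLI" if rng.random() < 0.6 else "SAUR",
                        "colonies": int(rng.integers(50, 5000)),
                    }
                )
        profile["labs"].append(lab)
    for code, p in config.diagnosis_prevalence.items():
        if rng.random() < p:
            profile["diagnoses"].append({"code": code, "onset": _event_time(rng, clock)})
    for code, p in config.order_prevalence.items():
        if rng.random() < p:
            start = _event_time(rng, clock)
            profile["orders"].append(
                {
                    "code": code,
                    "start": start,
                    "stop": start + _dt.timedelta(days=float(rng.uniform(1, 90))),
                    "dose": round(float(rng.uniform(25, 500)), 0),
                }
            )
    if rng.random() < config.record_rates["imaging_examination"]:
        profile["imaging"].append(
            {
                "exam": "CTH" if rng.random() < 0.7 else "MRB",
                "t": _event_time(rng, clock),
                "findings": _FINDINGS_POOL[int(rng.integers(0, len(_FINDINGS_POOL)))],
            }
        )
    return profile


def _set_age(profile, rng, clock, lo, hi):
    age = float(rng.uniform(lo, hi))
    profile["dob"] = clock - _dt.timedelta(days=age * 365.25 + float(rng.uniform(0, 0.9)))


def _ensure_order(profile, rng, clock, code):
    if not any(o["code"] == code for o in profile["orders"]):
        start = _event_time(rng, clock)
        profile["orders"].append(
            {
                "code": code,
                "start": start,
                "stop": start + _dt.timedelta(days=float(rng.uniform(1, 90))),
                "dose": round(float(rng.uniform(25, 500)), 0),
            }
        )


def _ensure_diagnosis(profile, rng, clock, codes):
    if not any(d["code"] in codes for d in profile["diagnoses"]):
        code = codes[int(rng.integers(0, len(codes)))]
        profile["diagnoses"].append({"code": code, "onset": _event_time(rng, clock)})


def _ensure_lab(profile, rng, clock):
    if not profile["labs"]:
        profile["labs"].append(
            {
                "t": _event_time(rng, clock),
                "wbc": round(max(0.5, float(rng.normal(6.5, 2.5))), 1),
                "micro": [],
            }
        )


def _apply_plant(label: str, profile: dict, rng, clock):
    if label == "query1":
        _ensure_order(profile, rng, clock, "EVAC")
    elif label == "query2":
        profile["sex"] = "F"
        _set_age(profile, rng, clock, 25, 55)
    elif label in ("query3", "query4", "query5"):
        profile["sex"] = "F"
        _set_age(profile, rng, clock, 61, 69)
        _ensure_diagnosis(profile, rng, clock, ["I61", "I63"])
        if label in ("query4", "query5"):
            _ensure_order(profile, rng, clock, "ASA")
        if label == "query5":
            _ensure_lab(profile, rng, clock)
    elif label == "query6":
        _ensure_lab(profile, rng, clock)
        last = max(profile["labs"], key=lambda lab: lab["t"])
        last["wbc"] = round(float(rng.uniform(10.5, 16.0)), 1)
    else:
        raise ConfigError(f"unknown scenario label {label!r}")


# --------------------------------------------------------------------------
# Materialization
# --------------------------------------------------------------------------


def _materialize(profile: dict, pid: str, templates_by_name: dict, store: PatientStore):
    def add(index, template, data, timestamp=None):
        entry = flatten_entry(
            template, data, pid, timestamp=timestamp, schema=store.schemas[index]
        )
        store.add_entry(index, pid, entry)

    t = templates_by_name
    add(
        "person",
        t["person"],
        {
            "/person/name": profile["name"],
            "/person/sex": profile["sex"],
            "/person/date_of_birth": profile["dob"].date(),
            "/person/identifier": profile["identifier"],
        },
        timestamp=profile["dob"],
    )
    for adm in profile["admissions"]:
        add(
            "patient_admission",
            t["patient_admission"],
            {
                "/patient_admission/admission_ward": adm["ward"],
                "/patient_admission/admission_time": adm["admission"],
                "/patient_admission/discharge_time": adm["discharge"],
                "/patient_admission/length_of_stay": adm["stay"],
                "/patient_admission/readmission": adm["readmission"],
            },
        )
    for sign in profile["signs"]:
        data = {
            "/physical_sign/measurement_time": sign["t"],
            "/physical_sign/systolic_blood_pressure": sign["sbp"],
            "/physical_sign/diastolic_blood_pressure": sign["dbp"],
            "/physical_sign/heart_rate": sign["hr"],
            "/physical_sign/blood_oxygen_saturation": sign["spo2"],
            "/physical_sign/body_temperature": sign["temp"],
            "/physical_sign/height": sign["height"],
            "/physical_sign/weight": sign["weight"],
        }
        if "mmse" in sign:
            data["/physical_sign/mmse"] = sign["mmse"]
        if "moca" in sign:
            data["/physical_sign/moca"] = sign["moca"]
        add("physical_sign", t["physical_sign"], data)
    for lab in profile["labs"]:
        data = {
            "/lab_test/test_name": "CBC",
            "/lab_test/specimen_collection_time": lab["t"],
            "/lab_test/result_time": lab["t"] + _dt.timedelta(hours=4),
            "/lab_test/white_blood_cell_count": lab["wbc"],
        }
        if "hgb" in lab:
            data["/lab_test/hemoglobin"] = lab["hgb"]
        if "plt" in lab:
            data["/lab_test/platelet_count"] = lab["plt"]
        if "glu" in lab:
            data["/lab_test/glucose"] = lab["glu"]
        if lab["micro"]:
            data["/lab_test/microbiology_finding"] = [
                {
                    "/lab_test/microbiology_finding/organism": m["organism"],
                    "/lab_test/microbiology_finding/colony_count": m["colonies"],
                }
                for m in lab["micro"]
            ]
        add("lab_test", t["lab_test"], data)
    for dx in profile["diagnoses"]:
        add(
            "problem_diagnosis",
            t["problem_diagnosis"],
            {
                "/problem_diagnosis/diagnosis": dx["code"],
                "/problem_diagnosis/date_of_onset": dx["onset"],
                "/problem_diagnosis/status/diagnostic_certainty": "confirmed",
            },
        )
    for order in profile["orders"]:
        add(
            "order",
            t["order"],
            {
                "/order/order_item": order["code"],
                "/order/dose": order["dose"],
                "/order/order_start_time": order["start"],
                "/order/order_stop_time": order["stop"],
            },
        )
    for img in profile["imaging"]:
        add(
            "imaging_examination",
            t["imaging_examination"],
            {
                "/imaging_examination/examination_name": img["exam"],
                "/imaging_examination/examination_time": img["t"],
                "/imaging_examination/findings": img["findings"],
                "/imaging_examination/report_uri": f"ehr://imaging/{pid}",
            },
        )


def generate_store(config: GeneratorConfig, out_dir: Optional[str] = None):
    """Generate a seeded patient store (and optionally write it out).

    Returns ``(store, ground_truth)`` where ground_truth maps each planted
    scenario label to the sorted list of eligible patient ids computed by
    the reference evaluator over the whole store (planted patients plus
    incidental matches).

    With ``out_dir``, writes ``documents.ndjson``, ``ground_truth.json``
    and one search-index mapping file per template.
    """
    if config.n_patients < 0:
        raise ConfigError("n_patients must be non-negative")
    total_planted = sum(k for _label, k in config.plant)
    if total_planted > config.n_patients:
        raise ConfigError(
            f"cannot plant {total_planted} patients into a store of {config.n_patients}"
        )
    for _label, k in config.plant:
        if k < 0:
            raise ConfigError("planted count must be non-negative")

    templates, registry, schemas = build_demo_context()
    templates_by_name = {t.concept_set_name: t for t in templates}
    store = PatientStore(registry, schemas, clock=config.clock)
    rng = np.random.default_rng(config.seed)

    profiles = [_base_profile(rng, i, config) for i in range(config.n_patients)]

    # disjoint planting blocks over a seeded shuffle of patient positions
    positions = list(rng.permutation(config.n_patients))
    cursor = 0
    for label, k in config.plant:
        for pos in positions[cursor : cursor + k]:
            _apply_plant(label, profiles[int(pos)], rng, config.clock)
        cursor += k

    for i, profile in enumerate(profiles):
        _materialize(profile, f"P{i:05d}", templates_by_name, store)

    conditions = scenario_conditions()
    ground_truth = {
        label: sorted(evaluate(conditions[label], store))
        for label, _k in config.plant
    }

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        pairs = []
        for index in sorted(store.documents):
            for pid in sorted(store.documents[index]):
                pairs.append((index, store.documents[index][pid]))
        write_documents(pairs, os.path.join(out_dir, "documents.ndjson"))
        with open(os.path.join(out_dir, "ground_truth.json"), "w", encoding="utf-8") as fh:
            json.dump(ground_truth, fh, indent=2, sort_keys=True)
        for index, schema in schemas.items():
            with open(
                os.path.join(out_dir, f"mapping_{index}.json"), "w", encoding="utf-8"
            ) as fh:
                fh.write(emit_es_mapping(schema))

    return store, ground_truth


@dataclass
class Scenario:
    label: str
    description: str
    condition: ScreeningCondition
    store: PatientStore
    expected: set


def scenario_suite(seed: int = 7, n_patients: int = 300) -> list:
    """Six benchmark fixtures at reduced scale over one shared store.

    Each fixture's expected set comes from the reference evaluator and is
    independently recomputable by brute force over the store's documents.
    """
    plant = [
        ("query1", 7),
        ("query2", 10),
        ("query3", 6),
        ("query4", 5),
        ("query5", 5),
        ("query6", 6),
    ]
    config = GeneratorConfig(n_patients=n_patients, seed=seed, plant=plant)
    store, _truth = generate_store(config)
    conditions = scenario_conditions()
    return [
        Scenario(
            label=label,
            description=SCENARIO_DESCRIPTIONS[label],
            condition=conditions[label],
            store=store,
            expected=evaluate(conditions[label], store),
        )
        for label, _k in plant
    ]
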