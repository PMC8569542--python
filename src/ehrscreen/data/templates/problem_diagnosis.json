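{
  "template_id": "t_problem_diagnosis",
  "concept_set_name": "problem_diagnosis",
  "composition_id": "composition.problem_diagnosis.v1",
  "archetypes": [
    {
      "archetype_id": "openEHR-EHR-EVALUATION.problem_diagnosis.v1",
      "root": {
        "node_id": "at0000",
        "name": "Problem diagnosis",
        "rm_type": "CLUSTER",
        "path": "/problem_diagnosis",
        "children": [
          {
            "node_id": "at0001",
            "name": "Diagnosis",
            "rm_type": "DV_CODED_TEXT",
            "path": "/problem_diagnosis/diagnosis",
            "defining_codes": [
              ["ICD-10", "I61", "Cerebral hemorrhage"],
              ["ICD-10", "I63", "Cerebral infarction"],
              ["ICD-10", "I60", "Subarachnoid hemorrhage"],
              ["ICD-10", "I10", "Essential hypertension"],
              ["ICD-10", "E66", "Obesity"],
              ["ICD-10", "F00", "Cognitive impairment diagnosis"]
            ]
          },
          {"node_id": "at0002", "name": "Body site", "rm_type": "DV_TEXT", "path": "/problem_diagnosis/body_site"},
          {"node_id": "at0003", "name": "Clinical description", "rm_type": "DV_TEXT", "path": "/problem_diagnosis/clinical_description"},
          {"node_id": "at0004", "name": "Date of onset", "rm_type": "DV_DATE_TIME", "path": "/problem_diagnosis/date_of_onset"},
          {
            "node_id": "at0005",
            "name": "Status",
            "rm_type": "SLOT",
            "path": "/problem_diagnosis/status",
            "children": [
              {
                "node_id": "at0006",
                "name": "Diagnostic certainty",
                "rm_type": "DV_CODED_TEXT",
                "path": "/problem_diagnosis/status/diagnostic_certainty",
                "defining_codes": [
                  ["local", "confirmed", "Confirmed"],
                  ["local", "provisional", "Provisional"]
                ]
              }
            ]
          }
        ]
      }
    }
  ]
}
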