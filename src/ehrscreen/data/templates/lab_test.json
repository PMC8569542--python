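{
  "template_id": "t_lab_test",
  "concept_set_name": "lab_test",
  "composition_id": "composition.lab_test.v1",
  "archetypes": [
    {
      "archetype_id": "openEHR-EHR-OBSERVATION.lab_test_single.v1",
      "root": {
        "node_id": "at0000",
        "name": "Laboratory test",
        "rm_type": "CLUSTER",
        "path": "/lab_test",
        "children": [
          {
            "node_id": "at0001",
            "name": "Test name",
            "rm_type": "DV_CODED_TEXT",
            "path": "/lab_test/test_name",
            "defining_codes": [
              ["local-lab", "CBC", "Complete blood count"],
              ["local-lab", "BMP", "Basic metabolic panel"]
            ]
          },
          {"node_id": "at0002", "name": "Specimen collection time", "rm_type": "DV_DATE_TIME", "path": "/lab_test/specimen_collection_time"},
          {"node_id": "at0003", "name": "Result time", "rm_type": "DV_DATE_TIME", "path": "/lab_test/result_time"},
          {"node_id": "at0004", "name": "White blood cell count", "rm_type": "DV_QUANTITY", "units": "10^9/L", "path": "/lab_test/white_blood_cell_count"},
          {"node_id": "at0005", "name": "Hemoglobin", "rm_type": "DV_QUANTITY", "units": "g/L", "path": "/lab_test/hemoglobin"},
          {"node_id": "at0006", "name": "Platelet count", "rm_type": "DV_QUANTITY", "units": "10^9/L", "path": "/lab_test/platelet_count"},
          {"node_id": "at0007", "name": "Glucose", "rm_type": "DV_QUANTITY", "units": "mmol/L", "path": "/lab_test/glucose"},
          {
            "node_id": "at0008",
            "name": "Microbiology finding",
            "rm_type": "CLUSTER",
            "is_collection": true,
            "path": "/lab_test/microbiology_finding",
            "children": [
              {
                "node_id": "at0009",
                "name": "Organism",
                "rm_type": "DV_CODED_TEXT",
                "path": "/lab_test/microbiology_finding/organism",
                "defining_codes": [
                  ["local-micro", "ECOLI", "Escherichia coli"],
                  ["local-micro", "SAUR", "Staphylococcus aureus"]
                ]
              },
              {"node_id": "at0010", "name": "Colony count", "rm_type": "DV_COUNT", "path": "/lab_test/microbiology_finding/colony_count"}
            ]
          }
        ]
      }
    }
  ]
}
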