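{
  "template_id": "t_person",
  "concept_set_name": "person",
  "composition_id": "composition.person.v1",
  "archetypes": [
    {
      "archetype_id": "openEHR-EHR-ADMIN_ENTRY.person.v1",
      "root": {
        "node_id": "at0000",
        "name": "Person",
        "rm_type": "CLUSTER",
        "path": "/person",
        "children": [
          {"node_id": "at0001", "name": "Name", "rm_type": "DV_TEXT", "path": "/person/name"},
          {
            "node_id": "at0002",
            "name": "Sex",
            "rm_type": "DV_CODED_TEXT",
            "path": "/person/sex",
            "defining_codes": [
              ["local", "F", "Female"],
              ["local", "M", "Male"]
            ]
          },
          {"node_id": "at0003", "name": "Date of birth", "rm_type": "DV_DATE", "path": "/person/date_of_birth"},
          {"node_id": "at0004", "name": "Identifier", "rm_type": "DV_IDENTIFIER", "path": "/person/identifier"}
        ]
      }
    }
  ]
}
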