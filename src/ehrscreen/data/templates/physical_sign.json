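{
  "template_id": "t_physical_sign",
  "concept_set_name": "physical_sign",
  "composition_id": "composition.physical_sign.v1",
  "archetypes": [
    {
      "archetype_id": "openEHR-EHR-OBSERVATION.physical_sign.v1",
      "root": {
        "node_id": "at0000",
        "name": "Physical sign",
        "rm_type": "CLUSTER",
        "path": "/physical_sign",
        "children": [
          {"node_id": "at0001", "name": "Measurement time", "rm_type": "DV_DATE_TIME", "path": "/physical_sign/measurement_time"},
          {"node_id": "at0002", "name": "Systolic blood pressure", "rm_type": "DV_QUANTITY", "units": "mmHg", "path": "/physical_sign/systolic_blood_pressure"},
          {"node_id": "at0003", "name": "Diastolic blood pressure", "rm_type": "DV_QUANTITY", "units": "mmHg", "path": "/physical_sign/diastolic_blood_pressure"},
          {"node_id": "at0004", "name": "Heart rate", "rm_type": "DV_QUANTITY", "units": "/min", "path": "/physical_sign/heart_rate"},
          {"node_id": "at0005", "name": "Blood oxygen saturation", "rm_type": "DV_QUANTITY", "units": "%", "path": "/physical_sign/blood_oxygen_saturation"},
          {"node_id": "at0006", "name": "Body temperature", "rm_type": "DV_QUANTITY", "units": "Cel", "path": "/physical_sign/body_temperature"},
          {"node_id": "at0007", "name": "Height", "rm_type": "DV_QUANTITY", "units": "m", "path": "/physical_sign/height"},
          {"node_id": "at0008", "name": "Weight", "rm_type": "DV_QUANTITY", "units": "kg", "path": "/physical_sign/weight"},
          {"node_id": "at0009", "name": "MMSE", "rm_type": "DV_COUNT", "path": "/physical_sign/mmse"},
          {"node_id": "at0010", "name": "MoCA", "rm_type": "DV_COUNT", "path": "/physical_sign/moca"}
        ]
      }
    }
  ]
}
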