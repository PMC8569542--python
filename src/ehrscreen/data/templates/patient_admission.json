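{
  "template_id": "t_patient_admission",
  "concept_set_name": "patient_admission",
  "composition_id": "composition.patient_admission.v1",
  "archetypes": [
    {
      "archetype_id": "openEHR-EHR-ADMIN_ENTRY.Patient_Admission.v2",
      "root": {
        "node_id": "at0000",
        "name": "Patient admission",
        "rm_type": "CLUSTER",
        "path": "/patient_admission",
        "children": [
          {"node_id": "at0001", "name": "Admission ward", "rm_type": "DV_TEXT", "path": "/patient_admission/admission_ward"},
          {"node_id": "at0002", "name": "Admission time", "rm_type": "DV_DATE_TIME", "path": "/patient_admission/admission_time"},
          {"node_id": "at0003", "name": "Discharge time", "rm_type": "DV_DATE_TIME", "path": "/patient_admission/discharge_time"},
          {"node_id": "at0004", "name": "Length of stay", "rm_type": "DV_DURATION", "path": "/patient_admission/length_of_stay"},
          {"node_id": "at0005", "name": "Readmission", "rm_type": "DV_BOOLEAN", "path": "/patient_admission/readmission"}
        ]
      }
    }
  ]
}
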