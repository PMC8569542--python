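{
  "template_id": "t_imaging_examination",
  "concept_set_name": "imaging_examination",
  "composition_id": "composition.imaging_examination.v1",
  "archetypes": [
    {
      "archetype_id": "openEHR-EHR-OBSERVATION.Imaging_examination_report.v2",
      "root": {
        "node_id": "at0000",
        "name": "Imaging examination",
        "rm_type": "CLUSTER",
        "path": "/imaging_examination",
        "children": [
          {
            "node_id": "at0001",
            "name": "Examination name",
            "rm_type": "DV_CODED_TEXT",
            "path": "/imaging_examination/examination_name",
            "defining_codes": [
              ["local-img", "CTH", "CT head"],
              ["local-img", "MRB", "MRI brain"]
            ]
          },
          {"node_id": "at0002", "name": "Examination time", "rm_type": "DV_DATE_TIME", "path": "/imaging_examination/examination_time"},
          {"node_id": "at0003", "name": "Findings", "rm_type": "DV_TEXT", "path": "/imaging_examination/findings"},
          {"node_id": "at0004", "name": "Report URI", "rm_type": "DV_URI", "path": "/imaging_examination/report_uri"}
        ]
      }
    }
  ]
}
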