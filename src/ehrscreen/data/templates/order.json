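{
  "template_id": "t_order",
  "concept_set_name": "order",
  "composition_id": "composition.order.v1",
  "archetypes": [
    {
      "archetype_id": "openEHR-EHR-INSTRUCTION.order.v1",
      "root": {
        "node_id": "at0000",
        "name": "Order",
        "rm_type": "CLUSTER",
        "path": "/order",
        "children": [
          {
            "node_id": "at0001",
            "name": "Order item",
            "rm_type": "DV_CODED_TEXT",
            "path": "/order/order_item",
            "defining_codes": [
              ["local-rx", "ASA", "Aspirin"],
              ["local-rx", "CLO", "Clopidogrel"],
              ["local-rx", "HEP", "Heparin"],
              ["local-rx", "SUL", "Sulpiride"],
              ["local-rx", "RIS", "Risperidone"],
              ["local-rx", "ALT", "Altretamine"],
              ["local-rx", "BEN", "Bendamustine"],
              ["local-proc", "EVAC", "Evacuation of intracerebral hematoma"],
              ["local-proc", "THROMB", "Thrombectomy"]
            ]
          },
          {"node_id": "at0002", "name": "Dose", "rm_type": "DV_QUANTITY", "units": "mg", "path": "/order/dose"},
          {"node_id": "at0003", "name": "Order start time", "rm_type": "DV_DATE_TIME", "path": "/order/order_start_time"},
          {"node_id": "at0004", "name": "Order stop time", "rm_type": "DV_DATE_TIME", "path": "/order/order_stop_time"},
          {"node_id": "at0005", "name": "Narrative", "rm_type": "DV_TEXT", "path": "/order/narrative"}
        ]
      }
    }
  ]
}
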