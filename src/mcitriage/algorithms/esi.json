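{
  "name": "ESI",
  "role": "secondary",
  "root": "e01",
  "provenance": "Emergency severity index v4. Synthetic reconstruction of decision points A (immediate life-saving intervention -> level 1), B (should-not-wait criteria -> level 2), C (expected resource count) and D (danger-zone vital signs); levels 1/2 map to T1/T2 and levels 3-5 collapse to T3. Gated by the structural check: the level-1 (T1) leaf sits at step 1.",
  "nodes": {
    "e01": {"kind": "binary_query", "query": "requires_immediate_lifesaving", "branches": {"yes": "leaf_l1", "no": "e02"}},
    "e02": {"kind": "binary_query", "query": "high_risk_situation", "branches": {"yes": "leaf_l2", "no": "e03"}},
    "e03": {"kind": "binary_query", "query": "confused_lethargic_disoriented", "branches": {"yes": "leaf_l2", "no": "e04"}},
    "e04": {"kind": "binary_query", "query": "severe_pain_distress", "branches": {"yes": "leaf_l2", "no": "e05"}},
    "e05": {"kind": "resource_query", "query": "esi_resources", "branches": {"0": "leaf_l5", "1": "leaf_l4", "2": "e06"}},
    "e06": {"kind": "binary_query", "query": "danger_zone_vitals", "branches": {"yes": "leaf_l2_vitals", "no": "leaf_l3"}},
    "leaf_l1": {"kind": "leaf", "esi_level": 1},
    "leaf_l2": {"kind": "leaf", "esi_level": 2},
    "leaf_l2_vitals": {"kind": "leaf", "esi_level": 2},
    "leaf_l3": {"kind": "leaf", "esi_level": 3},
    "leaf_l4": {"kind": "leaf", "esi_level": 4},
    "leaf_l5": {"kind": "leaf", "esi_level": 5}
  }
}
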