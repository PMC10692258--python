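{
  "name": "BER",
  "role": "secondary",
  "root": "b01",
  "provenance": "Berlin secondary triage algorithm. Synthetic reconstruction of the published flow (8 red discriminants followed by 9 yellow discriminants; the yellow list was expanded from 5 to 9 during the algorithm's validation); gated by structural checks: longest root-to-leaf path = 17 queries, ending at the T3 leaf.",
  "nodes": {
    "b01": {"kind": "binary_query", "query": "severe_external_hemorrhage", "branches": {"yes": "leaf_t1", "no": "b02"}},
    "b02": {"kind": "binary_query", "query": "airway_obstruction", "branches": {"yes": "leaf_t1", "no": "b03"}},
    "b03": {"kind": "binary_query", "query": "spontaneous_breathing", "branches": {"no": "leaf_t1", "yes": "b04"}},
    "b04": {"kind": "binary_query", "query": "rr_gt_29", "branches": {"yes": "leaf_t1", "no": "b05"}},
    "b05": {"kind": "binary_query", "query": "radial_pulse_absent", "branches": {"yes": "leaf_t1", "no": "b06"}},
    "b06": {"kind": "binary_query", "query": "obeys_commands", "branches": {"no": "leaf_t1", "yes": "b07"}},
    "b07": {"kind": "binary_query", "query": "fast_performed_positive", "branches": {"yes": "leaf_t1", "no": "b08"}},
    "b08": {"kind": "binary_query", "query": "penetrating_torso_injury", "branches": {"yes": "leaf_t1", "no": "b09"}},
    "b09": {"kind": "binary_query", "query": "pelvic_fracture", "branches": {"yes": "leaf_t2", "no": "b10"}},
    "b10": {"kind": "binary_query", "query": "open_fracture", "branches": {"yes": "leaf_t2", "no": "b11"}},
    "b11": {"kind": "binary_query", "query": "long_bone_fracture", "branches": {"yes": "leaf_t2", "no": "b12"}},
    "b12": {"kind": "binary_query", "query": "amputation", "branches": {"yes": "leaf_t2", "no": "b13"}},
    "b13": {"kind": "binary_query", "query": "burns_gt_15pct", "branches": {"yes": "leaf_t2", "no": "b14"}},
    "b14": {"kind": "binary_query", "query": "blunt_abdominal_trauma", "branches": {"yes": "leaf_t2", "no": "b15"}},
    "b15": {"kind": "binary_query", "query": "spine_injury_with_deficit", "branches": {"yes": "leaf_t2", "no": "b16"}},
    "b16": {"kind": "binary_query", "query": "head_injury_moderate", "branches": {"yes": "leaf_t2", "no": "b17"}},
    "b17": {"kind": "binary_query", "query": "persistent_pain_severe", "branches": {"yes": "leaf_t2", "no": "leaf_t3"}},
    "leaf_t1": {"kind": "leaf", "outcome": "T1"},
    "leaf_t2": {"kind": "leaf", "outcome": "T2"},
    "leaf_t3": {"kind": "leaf", "outcome": "T3"}
  }
}
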