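{
  "name": "JorD",
  "role": "secondary",
  "root": "j01",
  "provenance": "Jordanian-German project hospital algorithm. Synthetic reconstruction (8 immediate-threat discriminants, then 3 yellow discriminants); gated by structural checks: a T1 leaf at step 1 and longest root-to-leaf path = 11 queries, ending at the T3 leaf.",
  "nodes": {
    "j01": {"kind": "binary_query", "query": "airway_obstruction", "branches": {"yes": "leaf_t1", "no": "j02"}},
    "j02": {"kind": "binary_query", "query": "spontaneous_breathing", "branches": {"no": "leaf_t1", "yes": "j03"}},
    "j03": {"kind": "binary_query", "query": "rr_gt_29", "branches": {"yes": "leaf_t1", "no": "j04"}},
    "j04": {"kind": "binary_query", "query": "radial_pulse_absent", "branches": {"yes": "leaf_t1", "no": "j05"}},
    "j05": {"kind": "binary_query", "query": "fast_performed_positive", "branches": {"yes": "leaf_t1", "no": "j06"}},
    "j06": {"kind": "binary_query", "query": "obeys_commands", "branches": {"no": "leaf_t1", "yes": "j07"}},
    "j07": {"kind": "binary_query", "query": "penetrating_torso_injury", "branches": {"yes": "leaf_t1", "no": "j08"}},
    "j08": {"kind": "binary_query", "query": "severe_external_hemorrhage", "branches": {"yes": "leaf_t1", "no": "j09"}},
    "j09": {"kind": "binary_query", "query": "pelvic_fracture", "branches": {"yes": "leaf_t2", "no": "j10"}},
    "j10": {"kind": "binary_query", "query": "long_bone_fracture", "branches": {"yes": "leaf_t2", "no": "j11"}},
    "j11": {"kind": "binary_query", "query": "burns_gt_15pct", "branches": {"yes": "leaf_t2", "no": "leaf_t3"}},
    "leaf_t1": {"kind": "leaf", "outcome": "T1"},
    "leaf_t2": {"kind": "leaf", "outcome": "T2"},
    "leaf_t3": {"kind": "leaf", "outcome": "T3"}
  }
}
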