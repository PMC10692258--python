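{
  "name": "PETRA",
  "role": "primary",
  "root": "p1",
  "provenance": "Prehospital emergency triage rapid algorithm (PETRA). Synthetic reconstruction: walkers -> T3 at step 1; non-walkers receive a full vital-sign assessment (breathing, respiratory rate, radial pulse, command response, catastrophic hemorrhage) before any red decision, so every T1 leaf sits at exactly 6 steps as published; apnoea persisting after airway opening -> deceased; injury-pattern yellow discriminants close the tree at step 8.",
  "nodes": {
    "p1": {"kind": "binary_query", "query": "can_walk", "branches": {"yes": "leaf_t3", "no": "p2"}},
    "p2": {"kind": "binary_query", "query": "spontaneous_breathing", "branches": {"no": "p3a", "yes": "p3b"}},
    "p3a": {"kind": "binary_query", "query": "breathing_after_airway_opening", "branches": {"no": "leaf_dead", "yes": "p4a"}},
    "p4a": {"kind": "binary_query", "query": "rr_gt_29", "branches": {"yes": "p5a", "no": "p5a"}},
    "p5a": {"kind": "binary_query", "query": "radial_pulse_absent", "branches": {"yes": "p6a", "no": "p6a"}},
    "p6a": {"kind": "binary_query", "query": "obeys_commands", "branches": {"yes": "leaf_t1", "no": "leaf_t1"}},
    "p3b": {"kind": "binary_query", "query": "rr_gt_29", "branches": {"yes": "p4b", "no": "p4c"}},
    "p4b": {"kind": "binary_query", "query": "radial_pulse_absent", "branches": {"yes": "p5b", "no": "p5b"}},
    "p5b": {"kind": "binary_query", "query": "obeys_commands", "branches": {"yes": "p6b", "no": "p6b"}},
    "p6b": {"kind": "binary_query", "query": "severe_external_hemorrhage", "branches": {"yes": "leaf_t1", "no": "leaf_t1"}},
    "p4c": {"kind": "binary_query", "query": "radial_pulse_absent", "branches": {"yes": "p5c", "no": "p5d"}},
    "p5c": {"kind": "binary_query", "query": "obeys_commands", "branches": {"yes": "p6c", "no": "p6c"}},
    "p6c": {"kind": "binary_query", "query": "severe_external_hemorrhage", "branches": {"yes": "leaf_t1", "no": "leaf_t1"}},
    "p5d": {"kind": "binary_query", "query": "obeys_commands", "branches": {"no": "p6d", "yes": "p6e"}},
    "p6d": {"kind": "binary_query", "query": "severe_external_hemorrhage", "branches": {"yes": "leaf_t1", "no": "leaf_t1"}},
    "p6e": {"kind": "binary_query", "query": "severe_external_hemorrhage", "branches": {"yes": "leaf_t1", "no": "p7"}},
    "p7": {"kind": "binary_query", "query": "long_bone_fracture", "branches": {"yes": "p8a", "no": "p8b"}},
    "p8a": {"kind": "binary_query", "query": "burns_gt_15pct", "branches": {"yes": "leaf_t2", "no": "leaf_t2"}},
    "p8b": {"kind": "binary_query", "query": "pelvic_fracture", "branches": {"yes": "leaf_t2", "no": "leaf_t3_late"}},
    "leaf_t1": {"kind": "leaf", "outcome": "T1"},
    "leaf_t2": {"kind": "leaf", "outcome": "T2"},
    "leaf_t3": {"kind": "leaf", "outcome": "T3"},
    "leaf_t3_late": {"kind": "leaf", "outcome": "T3"},
    "leaf_dead": {"kind": "leaf", "outcome": "DECEASED"}
  }
}
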