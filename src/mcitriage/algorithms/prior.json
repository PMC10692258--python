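{
  "name": "PRIOR",
  "role": "primary",
  "root": "r01",
  "provenance": "Primary ranking for initial orientation in rescue (PRIOR). Synthetic reconstruction of the item list with the ability-to-walk query at the END of the algorithm (the ordering the method is known for); vital-threat items first (T1), then yellow discriminants, then walking -> T3 at step 8.",
  "nodes": {
    "r01": {"kind": "binary_query", "query": "spontaneous_breathing", "branches": {"no": "leaf_t1", "yes": "r02"}},
    "r02": {"kind": "binary_query", "query": "rr_gt_29", "branches": {"yes": "leaf_t1", "no": "r03"}},
    "r03": {"kind": "binary_query", "query": "radial_pulse_absent", "branches": {"yes": "leaf_t1", "no": "r04"}},
    "r04": {"kind": "binary_query", "query": "obeys_commands", "branches": {"no": "leaf_t1", "yes": "r05"}},
    "r05": {"kind": "binary_query", "query": "severe_external_hemorrhage", "branches": {"yes": "leaf_t2", "no": "r06"}},
    "r06": {"kind": "binary_query", "query": "long_bone_fracture", "branches": {"yes": "leaf_t2", "no": "r07"}},
    "r07": {"kind": "binary_query", "query": "burns_gt_15pct", "branches": {"yes": "leaf_t2", "no": "r08"}},
    "r08": {"kind": "binary_query", "query": "can_walk", "branches": {"yes": "leaf_t3", "no": "leaf_t2_nowalk"}},
    "leaf_t1": {"kind": "leaf", "outcome": "T1"},
    "leaf_t2": {"kind": "leaf", "outcome": "T2"},
    "leaf_t2_nowalk": {"kind": "leaf", "outcome": "T2"},
    "leaf_t3": {"kind": "leaf", "outcome": "T3"}
  }
}
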