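{
  "name": "MTS_MCI",
  "role": "secondary",
  "root": "m01",
  "provenance": "Manchester triage system, mass-casualty (MCI) module. Synthetic reconstruction of the sieve-style module (walkers to green first, then airway/breathing/circulation red discriminants, then yellow discriminants); gated by the structural check: a T3 leaf at step 1.",
  "nodes": {
    "m01": {"kind": "binary_query", "query": "can_walk", "branches": {"yes": "leaf_t3", "no": "m02"}},
    "m02": {"kind": "binary_query", "query": "airway_obstruction", "branches": {"yes": "leaf_t1", "no": "m03"}},
    "m03": {"kind": "binary_query", "query": "rr_gt_29", "branches": {"yes": "leaf_t1", "no": "m04"}},
    "m04": {"kind": "binary_query", "query": "radial_pulse_absent", "branches": {"yes": "leaf_t1", "no": "m05"}},
    "m05": {"kind": "binary_query", "query": "long_bone_fracture", "branches": {"yes": "leaf_t2", "no": "m06"}},
    "m06": {"kind": "binary_query", "query": "persistent_pain_severe", "branches": {"yes": "leaf_t2", "no": "leaf_t3_late"}},
    "leaf_t1": {"kind": "leaf", "outcome": "T1"},
    "leaf_t2": {"kind": "leaf", "outcome": "T2"},
    "leaf_t3": {"kind": "leaf", "outcome": "T3"},
    "leaf_t3_late": {"kind": "leaf", "outcome": "T3"}
  }
}
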