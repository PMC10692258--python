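{
  "name": "mSTaRT",
  "role": "primary",
  "root": "s01",
  "provenance": "Modified simple triage and rapid treatment (mSTaRT). Synthetic reconstruction of the sieve: walkers -> T3 at step 1; severe external hemorrhage -> T1; apnoea persisting after airway opening -> deceased; then respiratory rate, radial pulse and obeying commands as red discriminants; remaining stretcher cases -> T2 at step 6.",
  "nodes": {
    "s01": {"kind": "binary_query", "query": "can_walk", "branches": {"yes": "leaf_t3", "no": "s02"}},
    "s02": {"kind": "binary_query", "query": "severe_external_hemorrhage", "branches": {"yes": "leaf_t1", "no": "s03"}},
    "s03": {"kind": "binary_query", "query": "spontaneous_breathing", "branches": {"no": "s03b", "yes": "s04"}},
    "s03b": {"kind": "binary_query", "query": "breathing_after_airway_opening", "branches": {"no": "leaf_dead", "yes": "leaf_t1"}},
    "s04": {"kind": "binary_query", "query": "rr_gt_29", "branches": {"yes": "leaf_t1", "no": "s05"}},
    "s05": {"kind": "binary_query", "query": "radial_pulse_absent", "branches": {"yes": "leaf_t1", "no": "s06"}},
    "s06": {"kind": "binary_query", "query": "obeys_commands", "branches": {"no": "leaf_t1", "yes": "leaf_t2"}},
    "leaf_t1": {"kind": "leaf", "outcome": "T1"},
    "leaf_t2": {"kind": "leaf", "outcome": "T2"},
    "leaf_t3": {"kind": "leaf", "outcome": "T3"},
    "leaf_dead": {"kind": "leaf", "outcome": "DECEASED"}
  }
}
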