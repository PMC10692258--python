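"""Canonical query vocabulary shared by all triage algorithms.

All seven algorithms are phrased over one flat namespace of query ids so a
single vignette row serves every algorithm.  Queries that different
algorithms phrase slightly differently but that probe the same finding are
merged through the alias table (e.g. ``unstable_pelvis`` and
``pelvic_fracture`` both resolve to ``pelvic_fracture``; respiratory-rate
thresholds of 29/min and 30/min are merged into ``rr_gt_29``).

Answers are coded as strings: ``"1"`` = the query is answered "yes",
``"0"`` = "no", ``"n"`` = the result cannot be derived from the vignette.
The ESI resource query ``esi_resources`` additionally admits ``"2"``
(0 = no resources, 1 = one resource, 2 = many resources).
"""

from __future__ import annotations

from .errors import VocabularyError

__all__ = [
    "CANONICAL_QUERIES",
    "RESOURCE_QUERY",
    "ALIASES",
    "canonical_query",
    "valid_codes",
]

#: The one query with a three-way answer (ESI expected resource count).
RESOURCE_QUERY = "esi_resources"

#: Canonical query ids.  Binary unless noted otherwise.
CANONICAL_QUERIES = frozenset(
    {
        # mobility / responsiveness
        "can_walk",
        "obeys_commands",
        "confused_lethargic_disoriented",
        # airway / breathing
        "airway_obstruction",
        "spontaneous_breathing",
        "breathing_after_airway_opening",
        "rr_gt_29",
        # circulation
        "radial_pulse_absent",
        "severe_external_hemorrhage",
        # focused diagnostics
        "fast_performed_positive",
        "danger_zone_vitals",
        # injury pattern discriminants
        "penetrating_torso_injury",
        "pelvic_fracture",
        "open_fracture",
        "long_bone_fracture",
        "amputation",
        "burns_gt_15pct",
        "blunt_abdominal_trauma",
        "spine_injury_with_deficit",
        "head_injury_moderate",
        "persistent_pain_severe",
        # ESI decision points
        "requires_immediate_lifesaving",
        "high_risk_situation",
        "severe_pain_distress",
        RESOURCE_QUERY,
    }
)

#: Algorithm-specific phrasings → canonical id.
ALIASES: dict[str, str] = {
    "unstable_pelvis": "pelvic_fracture",
    "rr_gt_30": "rr_gt_29",
    "respiratory_rate_gt_29": "rr_gt_29",
    "respiratory_rate_gt_30": "rr_gt_29",
    "fast_positive": "fast_performed_positive",
    "fast": "fast_performed_positive",
    "walking": "can_walk",
    "ability_to_walk": "can_walk",
    "no_radial_pulse": "radial_pulse_absent",
    "gcs_reduced": "confused_lethargic_disoriented",
    "resources_expected": RESOURCE_QUERY,
}


def canonical_query(query_id: str, extra_aliases: dict[str, str] | None = None) -> str:
    """Resolve a (possibly algorithm-specific) query id to its canonical id.

    Raises :class:`VocabularyError` for ids outside the vocabulary.
    """
    qid = query_id.strip()
    if extra_aliases and qid in extra_aliases:
        qid = extra_aliases[qid]
    qid = ALIASES.get(qid, qid)
    if qid not in CANONICAL_QUERIES:
        raise VocabularyError(f"unknown query id {query_id!r}")
    return qid


def valid_codes(query_id: str) -> frozenset[str]:
    """Admissible answer codes for a canonical query id."""
    if query_id == RESOURCE_QUERY:
        return frozenset({"0", "1", "2", "n"})
    return frozenset({"0", "1", "n"})
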