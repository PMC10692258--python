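"""Synthetic vignette sets and expert panels.

The original 210-vignette reference database is not deposited, so every
stage of the pipeline is exercised on generated data with the same
statistical shape: latent triage categories with a configurable mix
(default 49/45/116 over T1/T2/T3, the composition of the reference set),
per-category probabilities for every canonical query answer (with a small
rate of ``"n"`` codes to exercise the n-policy), and a simulated expert
panel whose ordinal ratings scatter around the latent truth.

Features are sampled independently given the category; a short, documented
consistency pass then removes clinically incoherent combinations (walking
casualties with absent vitals).  The generator defines *plausible* coded
casualties, not an estimate of any real casualty population — results on
synthetic sets demonstrate the machinery, not field performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .categories import REFERENCE_CATEGORIES, TriageCategory
from .errors import ModelError
from .consensus import PanelRatings
from .vignettes import Vignette, VignetteSet
from .vocabulary import CANONICAL_QUERIES, RESOURCE_QUERY

__all__ = [
    "FeatureModel",
    "RaterErrorModel",
    "DEFAULT_MIX",
    "default_feature_model",
    "generate_vignettes",
    "simulate_panel",
    "largest_remainder_allocation",
]

#: Reference-set composition of the validation study (49/45/116 of 210).
DEFAULT_MIX = {
    TriageCategory.T1: 49 / 210,
    TriageCategory.T2: 45 / 210,
    TriageCategory.T3: 116 / 210,
}


@dataclass
class FeatureModel:
    """Per-category answer probabilities for every canonical query.

    ``p_yes[query][cat]`` is P(answer "1"), ``p_n[query][cat]`` is
    P(answer "n"); the remainder is "0".  ``resource_dist[cat]`` is the
    distribution over {0, 1, 2} expected ESI resources.
    """

    p_yes: dict[str, dict[TriageCategory, float]]
    p_n: dict[str, dict[TriageCategory, float]] = field(default_factory=dict)
    resource_dist: dict[TriageCategory, tuple[float, float, float]] = field(
        default_factory=dict
    )

    def validate(self) -> None:
        for query, per_cat in self.p_yes.items():
            if query == RESOURCE_QUERY:
                raise ModelError("the resource query is modelled by resource_dist")
            if query not in CANONICAL_QUERIES:
                raise ModelError(f"feature model covers unknown query {query!r}")
            for cat in REFERENCE_CATEGORIES:
                p1 = per_cat[cat]
                pn = self.p_n.get(query, {}).get(cat, 0.0)
                if not (0.0 <= p1 <= 1.0 and 0.0 <= pn <= 1.0 and p1 + pn <= 1.0):
                    raise ModelError(
                        f"{query}/{cat.value}: need 0 ≤ P(1), P(n) and "
                        f"P(1)+P(n) ≤ 1, got {p1}, {pn}"
                    )
        for cat in REFERENCE_CATEGORIES:
            dist = self.resource_dist[cat]
            if len(dist) != 3 or any(p < 0 for p in dist) or abs(sum(dist) - 1) > 1e-9:
                raise ModelError(f"resource distribution for {cat.value} must sum to 1")

    @property
    def queries(self) -> list[str]:
        return sorted(self.p_yes) + [RESOURCE_QUERY]


@dataclass
class RaterErrorModel:
    """Ordinal rating error around the latent truth.

    ``adjacent_error`` is the probability of rating one category off (split
    evenly toward each neighbour where two exist); ``extreme_error`` is the
    probability of a two-step error (T1↔T3), applicable only where a
    two-step neighbour exists.
    """

    adjacent_error: float = 0.0
    extreme_error: float = 0.0

    def validate(self) -> None:
        e, e2 = self.adjacent_error, self.extreme_error
        if not (0 <= e <= 1 and 0 <= e2 <= 1 and e + e2 <= 1):
            raise ModelError(f"need e, e2 ≥ 0 with e + e2 ≤ 1, got {e}, {e2}")


# (p_yes | T1, T2, T3) per canonical binary query.  T1 rows carry
# vital-threat findings with high probability, T3 rows walk; "n" appears at
# a low base rate (higher for FAST, which is often simply not performed).
_DEFAULT_P_YES: dict[str, tuple[float, float, float]] = {
    "can_walk":                      (0.02, 0.25, 0.92),
    "obeys_commands":                (0.45, 0.92, 0.99),
    "confused_lethargic_disoriented": (0.40, 0.10, 0.01),
    "airway_obstruction":            (0.15, 0.01, 0.00),
    "spontaneous_breathing":         (0.75, 0.99, 1.00),
    "breathing_after_airway_opening": (0.85, 1.00, 1.00),
    "rr_gt_29":                      (0.45, 0.08, 0.01),
    "radial_pulse_absent":           (0.40, 0.04, 0.00),
    "severe_external_hemorrhage":    (0.25, 0.05, 0.01),
    "fast_performed_positive":       (0.45, 0.06, 0.01),
    "danger_zone_vitals":            (0.70, 0.25, 0.03),
    "penetrating_torso_injury":      (0.20, 0.04, 0.00),
    "pelvic_fracture":               (0.15, 0.18, 0.01),
    "open_fracture":                 (0.10, 0.15, 0.02),
    "long_bone_fracture":            (0.15, 0.40, 0.05),
    "amputation":                    (0.05, 0.06, 0.00),
    "burns_gt_15pct":                (0.08, 0.10, 0.01),
    "blunt_abdominal_trauma":        (0.15, 0.20, 0.05),
    "spine_injury_with_deficit":     (0.05, 0.08, 0.00),
    "head_injury_moderate":          (0.10, 0.25, 0.05),
    "persistent_pain_severe":        (0.30, 0.55, 0.10),
    "requires_immediate_lifesaving": (0.85, 0.02, 0.00),
    "high_risk_situation":           (0.25, 0.35, 0.05),
    "severe_pain_distress":          (0.30, 0.40, 0.08),
}

_DEFAULT_P_N: dict[str, tuple[float, float, float]] = {
    "fast_performed_positive": (0.10, 0.30, 0.40),
    "danger_zone_vitals": (0.02, 0.05, 0.05),
    "blunt_abdominal_trauma": (0.05, 0.05, 0.05),
    "head_injury_moderate": (0.03, 0.03, 0.03),
}

_DEFAULT_RESOURCES: dict[TriageCategory, tuple[float, float, float]] = {
    TriageCategory.T1: (0.02, 0.08, 0.90),
    TriageCategory.T2: (0.05, 0.25, 0.70),
    TriageCategory.T3: (0.55, 0.35, 0.10),
}


def default_feature_model() -> FeatureModel:
    """The shipped feature table over the full canonical vocabulary."""
    cats = REFERENCE_CATEGORIES
    fm = FeatureModel(
        p_yes={q: dict(zip(cats, p)) for q, p in _DEFAULT_P_YES.items()},
        p_n={q: dict(zip(cats, p)) for q, p in _DEFAULT_P_N.items()},
        resource_dist=dict(_DEFAULT_RESOURCES),
    )
    fm.validate()
    return fm


def largest_remainder_allocation(n: int, fractions: dict[TriageCategory, float]) -> dict[TriageCategory, int]:
    """Integer allocation of n across categories: floor each quota, then
    hand remaining units to the largest fractional remainders (ties broken
    by urgency)."""
    quotas = {c: n * f for c, f in fractions.items()}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    remaining = n - sum(counts.values())
    order = sorted(
        fractions, key=lambda c: (-(quotas[c] - counts[c]), c.urgency_rank)
    )
    for c in order[:remaining]:
        counts[c] += 1
    return counts


# Consistency pass: clinically incoherent answer combinations are repaired
# after independent sampling.  The rules, in order:
#   1. absent breathing, absent radial pulse, airway obstruction or not
#      obeying commands force can_walk = 0;
#   2. a walking casualty needs no immediate life-saving intervention;
#   3. breathing_after_airway_opening is only meaningful when spontaneous
#      breathing is absent; otherwise it is fixed to 1.
def _apply_consistency(answers: dict[str, str]) -> dict[str, str]:
    threat = (
        answers.get("spontaneous_breathing") == "0"
        or answers.get("radial_pulse_absent") == "1"
        or answers.get("airway_obstruction") == "1"
        or answers.get("obeys_commands") == "0"
    )
    if threat:
        answers["can_walk"] = "0"
    if answers.get("can_walk") == "1":
        answers["requires_immediate_lifesaving"] = "0"
    if answers.get("spontaneous_breathing") != "0":
        answers["breathing_after_airway_opening"] = "1"
    return answers


def generate_vignettes(
    n: int,
    distribution: dict[TriageCategory, float] | None = None,
    fm: FeatureModel | None = None,
    seed: int = 0,
    apply_consistency: bool = True,
) -> VignetteSet:
    """Generate ``n`` vignettes with latent true categories as references.

    Category counts follow the largest-remainder allocation of the requested
    mix; answers are sampled independently per cell from the feature model;
    everything is reproducible from the integer seed.
    """
    distribution = dict(DEFAULT_MIX) if distribution is None else dict(distribution)
    total = sum(distribution.values())
    if set(distribution) - set(REFERENCE_CATEGORIES) or abs(total - 1.0) > 1e-9:
        raise ModelError(
            f"distribution must cover T1/T2/T3 and sum to 1 (got {total:.4f})"
        )
    fm = default_feature_model() if fm is None else fm
    fm.validate()

    rng = np.random.default_rng(seed)
    counts = largest_remainder_allocation(n, distribution)
    categories = [c for c in REFERENCE_CATEGORIES for _ in range(counts.get(c, 0))]
    rng.shuffle(categories)

    width = max(3, len(str(n)))
    vignettes = []
    binary_queries = sorted(fm.p_yes)
    for i, cat in enumerate(categories):
        answers: dict[str, str] = {}
        for query in binary_queries:
            p1 = fm.p_yes[query][cat]
            pn = fm.p_n.get(query, {}).get(cat, 0.0)
            u = rng.random()
            answers[query] = "1" if u < p1 else ("n" if u < p1 + pn else "0")
        answers[RESOURCE_QUERY] = str(rng.choice(3, p=fm.resource_dist[cat]))
        if apply_consistency:
            answers = _apply_consistency(answers)
        vignettes.append(
            Vignette(id=f"v{i + 1:0{width}d}", answers=answers, reference_category=cat)
        )
    vset = VignetteSet(
        vignettes=vignettes,
        provenance={
            "generator": "mcitriage.synthetic.generate_vignettes",
            "seed": int(seed),
            "n": int(n),
            "distribution": {c.value: distribution[c] for c in distribution},
            "consistency_pass": bool(apply_consistency),
        },
    )
    vset.validate()
    return vset


def simulate_panel(
    truth: VignetteSet,
    n_raters: int = 36,
    em: RaterErrorModel | None = None,
    seed: int = 0,
) -> PanelRatings:
    """Simulate an expert panel rating every vignette independently.

    Each rating is the latent true rank perturbed by the error model's
    kernel: one step toward a neighbour with probability ``adjacent_error``
    (split evenly when two neighbours exist), two steps (T1↔T3) with
    probability ``extreme_error``.
    """
    if n_raters < 1:
        raise ModelError("need at least one rater")
    em = RaterErrorModel() if em is None else em
    em.validate()
    if not truth.has_references():
        raise ModelError("truth set must carry reference categories")

    true_ranks = np.array([v.reference_category.urgency_rank for v in truth])
    rng = np.random.default_rng(seed)
    u = rng.random((n_raters, len(true_ranks)))
    ranks = np.broadcast_to(true_ranks, (n_raters, len(true_ranks))).copy()

    e, e2 = em.adjacent_error, em.extreme_error
    middle = true_ranks == 2
    # middle rank: adjacent errors split evenly, no two-step neighbour
    ranks[:, middle] = np.where(
        u[:, middle] < e / 2, 1, np.where(u[:, middle] < e, 3, 2)
    )
    for true_rank, adj, extreme in ((1, 2, 3), (3, 2, 1)):
        edge = true_ranks == true_rank
        ranks[:, edge] = np.where(
            u[:, edge] < e,
            adj,
            np.where(u[:, edge] < e + e2, extreme, true_rank),
        )
    return PanelRatings(vignette_ids=list(truth.ids), ratings=ranks)
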