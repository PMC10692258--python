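"""Published benchmark values for the seven algorithms.

The original validation study scored all seven algorithms against a
210-vignette expert reference set (49 × T1, 45 × T2, 116 × T3) that is not
publicly deposited.  What *is* public are the printed test-quality tables
(sensitivity, specificity, PPV, NPV, Youden index, mistriage percentages,
rounded to two decimals / one decimal) and the triage-time scenarios.  This
module ships those printed values as input data and provides an exact
integer *back-solver* that reconstructs the underlying one-vs-rest
confusion-matrix cells: with the category denominators known, the printed
cells over-determine the integer (TP, TN) pair, so the reconstruction is a
computation, not a transcription.
"""

from __future__ import annotations

import math

from .categories import TriageCategory
from .errors import TriageError
from .evaluation import ConfusionMatrix

__all__ = [
    "CATEGORY_N",
    "PUBLISHED_QUALITY",
    "TIME_SCENARIOS",
    "round_half_up",
    "reconstruct_confusion",
]

#: Reference-set composition: back-solved from the printed mistriage
#: percentages (e.g. 42.9% = 21/49, 35.6% = 16/45, 2.6% = 3/116) and
#: consistent with the set size 49 + 45 + 116 = 210.
CATEGORY_N = {TriageCategory.T1: 49, TriageCategory.T2: 45, TriageCategory.T3: 116}

#: Printed test-quality values per category and algorithm.
#: Keys: sens, spec, ppv, npv, youden (2 dp); over_pct, under_pct (1 dp,
#: absent where structurally zero).
PUBLISHED_QUALITY: dict[str, dict[str, dict[str, float]]] = {
    "T1": {
        "BER":    {"sens": 1.00, "spec": 0.89, "ppv": 0.73, "npv": 1.00, "youden": 0.89, "under_pct": 0.0},
        "ESI":    {"sens": 0.80, "spec": 0.89, "ppv": 0.70, "npv": 0.94, "youden": 0.69, "under_pct": 20.4},
        "MTS_MCI": {"sens": 0.57, "spec": 0.99, "ppv": 0.97, "npv": 0.88, "youden": 0.57, "under_pct": 42.9},
        "JorD":   {"sens": 1.00, "spec": 0.88, "ppv": 0.71, "npv": 1.00, "youden": 0.88, "under_pct": 0.0},
        "PETRA":  {"sens": 0.73, "spec": 0.99, "ppv": 0.95, "npv": 0.92, "youden": 0.72, "under_pct": 26.5},
        "PRIOR":  {"sens": 1.00, "spec": 0.67, "ppv": 0.48, "npv": 1.00, "youden": 0.67, "under_pct": 0.0},
        "mSTaRT": {"sens": 0.92, "spec": 0.92, "ppv": 0.78, "npv": 0.97, "youden": 0.84, "under_pct": 8.2},
    },
    "T2": {
        "BER":    {"sens": 0.38, "spec": 0.90, "ppv": 0.52, "npv": 0.84, "youden": 0.28, "over_pct": 35.6, "under_pct": 26.7},
        "ESI":    {"sens": 0.22, "spec": 0.78, "ppv": 0.21, "npv": 0.79, "youden": 0.00, "over_pct": 33.3, "under_pct": 44.4},
        "MTS_MCI": {"sens": 0.16, "spec": 0.73, "ppv": 0.14, "npv": 0.76, "youden": -0.11, "over_pct": 2.2, "under_pct": 82.2},
        "JorD":   {"sens": 0.11, "spec": 0.99, "ppv": 0.83, "npv": 0.80, "youden": 0.11, "over_pct": 40.0, "under_pct": 48.9},
        "PETRA":  {"sens": 0.27, "spec": 0.75, "ppv": 0.22, "npv": 0.79, "youden": 0.01, "over_pct": 4.4, "under_pct": 68.9},
        "PRIOR":  {"sens": 0.02, "spec": 0.99, "ppv": 0.33, "npv": 0.79, "youden": 0.01, "over_pct": 51.1, "under_pct": 46.7},
        "mSTaRT": {"sens": 0.13, "spec": 0.81, "ppv": 0.16, "npv": 0.77, "youden": -0.06, "over_pct": 24.4, "under_pct": 62.2},
    },
    "T3": {
        "BER":    {"sens": 0.84, "spec": 0.87, "ppv": 0.89, "npv": 0.82, "youden": 0.72, "over_pct": 15.5},
        "ESI":    {"sens": 0.74, "spec": 0.78, "ppv": 0.80, "npv": 0.71, "youden": 0.52, "over_pct": 25.9},
        "MTS_MCI": {"sens": 0.72, "spec": 0.51, "ppv": 0.65, "npv": 0.60, "youden": 0.23, "over_pct": 27.6},
        "JorD":   {"sens": 0.97, "spec": 0.77, "ppv": 0.84, "npv": 0.96, "youden": 0.74, "over_pct": 2.6},
        "PETRA":  {"sens": 0.68, "spec": 0.59, "ppv": 0.67, "npv": 0.60, "youden": 0.27, "over_pct": 31.9},
        "PRIOR":  {"sens": 0.72, "spec": 0.78, "ppv": 0.80, "npv": 0.70, "youden": 0.50, "over_pct": 27.6},
        "mSTaRT": {"sens": 0.72, "spec": 0.67, "ppv": 0.73, "npv": 0.66, "youden": 0.39, "over_pct": 28.4},
    },
}

#: Published per-patient triage durations (seconds, from a timed evaluation
#: of the two primary algorithms) and cohort category distributions used in
#: the time-projection scenarios.
TIME_SCENARIOS = {
    "durations_s": {
        "PRIOR": {"T1": 27.0, "T2": 28.0, "T3": 42.0},
        "mSTaRT": {"T1": 35.0, "T2": 20.0, "T3": 10.0},
    },
    "distributions": {
        # drill-scale scenario with a dead stratum
        "drill": {"T1": 0.15, "T2": 0.20, "T3": 0.60, "dead": 0.05},
        # aggregate German MCI category distribution
        "german_mci": {"T1": 0.07, "T2": 0.19, "T3": 0.74},
    },
    "cohort": 100,
}


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal rounding with halves away from zero (print convention)."""
    factor = 10.0**digits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def reconstruct_confusion(category: TriageCategory, algorithm: str) -> ConfusionMatrix:
    """Reconstruct the one-vs-rest confusion cells behind the printed values.

    Enumerates every integer (TP, TN) with 0 ≤ TP ≤ n_pos, 0 ≤ TN ≤ n_neg
    and keeps the pairs whose full-precision sensitivity, specificity, PPV,
    NPV, Youden index and mistriage percentage all round (half-up) to the
    printed cells.  Raises if no pair or inconsistent pairs survive.

    The result is returned as a 3×k matrix with the off-category mass placed
    on a single neighbouring category; only the one-vs-rest collapse
    (TP/FP/TN/FN) is determined by the printed data, which is all the
    quality metrics need.
    """
    printed = PUBLISHED_QUALITY[category.value][algorithm]
    n_pos = CATEGORY_N[category]
    n_neg = sum(CATEGORY_N.values()) - n_pos

    candidates: list[tuple[int, int]] = []
    for tp in range(n_pos + 1):
        sens = tp / n_pos
        if round_half_up(sens) != printed["sens"]:
            continue
        for tn in range(n_neg + 1):
            spec = tn / n_neg
            if round_half_up(spec) != printed["spec"]:
                continue
            fp, fn = n_neg - tn, n_pos - tp
            ppv = tp / (tp + fp) if tp + fp else None
            npv = tn / (tn + fn) if tn + fn else None
            if ppv is None or round_half_up(ppv) != printed["ppv"]:
                continue
            if npv is None or round_half_up(npv) != printed["npv"]:
                continue
            if round_half_up(sens + spec - 1) != printed["youden"]:
                continue
            if category == TriageCategory.T1 and "under_pct" in printed:
                if round_half_up(100 * fn / n_pos, 1) != printed["under_pct"]:
                    continue
            if category == TriageCategory.T3 and "over_pct" in printed:
                if round_half_up(100 * fn / n_pos, 1) != printed["over_pct"]:
                    continue
            candidates.append((tp, tn))
    if not candidates:
        raise TriageError(
            f"printed values for {algorithm}/{category.value} admit no integer "
            "confusion matrix"
        )
    tps = {c[0] for c in candidates}
    tns = {c[1] for c in candidates}
    if len(tps) > 1 or len(tns) > 1:
        raise TriageError(
            f"printed values for {algorithm}/{category.value} are ambiguous: "
            f"{sorted(candidates)}"
        )
    tp, tn = candidates[0]
    fp, fn = n_neg - tn, n_pos - tp

    # place the collapsed off-diagonal mass on fixed neighbours
    other = [c for c in CATEGORY_N if c != category]
    cells: dict[tuple[TriageCategory, TriageCategory], int] = {
        (category, category): tp,
        (category, other[0]): fn,
        (other[0], category): min(fp, CATEGORY_N[other[0]]),
        (other[1], category): max(0, fp - CATEGORY_N[other[0]]),
    }
    # remaining negatives stay on their own diagonal (true negatives)
    placed = {c: cells.get((c, category), 0) for c in other}
    for c in other:
        cells[(c, c)] = CATEGORY_N[c] - placed[c]
    return ConfusionMatrix.from_cells(cells, algorithm=algorithm)
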