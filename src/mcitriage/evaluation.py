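"""Diagnostic-quality and decision-cost statistics.

For each algorithm and each reference category c ∈ {T1, T2, T3} the problem
is collapsed one-vs-rest: a vignette is *positive* when its expert reference
is c and *test-positive* when the algorithm assigned c.  Special outcomes
(T4, DECEASED) count as negatives of every reference category and rank
below T3 on the urgency scale, so a red patient assigned DECEASED is both a
false negative for T1 and an undertriage.

Mistriage is structural on the ordinal scale: among reference-c patients,
*overtriage* is assignment to a strictly more urgent category and
*undertriage* to a strictly less urgent one — hence T1 patients can only be
undertriaged and T3 patients only overtriaged.

Step statistics (median and quartiles of the number of queries evaluated)
use linear interpolation between order statistics; with small strata other
quantile conventions give different printed bounds, so the rule is part of
the report metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .categories import REFERENCE_CATEGORIES, TriageCategory
from .errors import CoverageError, ModelError, TriageError
from .vignettes import VignetteSet

__all__ = [
    "ASSIGNED_OUTCOMES",
    "ConfusionMatrix",
    "QualityMetrics",
    "MistriageRates",
    "StepStats",
    "TimeModel",
    "confusion",
    "test_quality",
    "mistriage",
    "classify_outcome",
    "step_stats",
    "time_projection",
    "quality_report",
    "QualityReport",
]

#: Column order of the confusion matrix (everything an algorithm can assign).
ASSIGNED_OUTCOMES = (
    TriageCategory.T1,
    TriageCategory.T2,
    TriageCategory.T3,
    TriageCategory.T4,
    TriageCategory.DECEASED,
)

Stratum = Literal["correct", "overtriage", "undertriage", "overall"]


@dataclass
class ConfusionMatrix:
    """Counts indexed by (reference category) × (assigned outcome)."""

    counts: pd.DataFrame  # index T1..T3, columns ASSIGNED_OUTCOMES values
    algorithm: str = ""

    def __post_init__(self) -> None:
        idx = [c.value for c in REFERENCE_CATEGORIES]
        cols = [c.value for c in ASSIGNED_OUTCOMES]
        self.counts = self.counts.reindex(index=idx, columns=cols, fill_value=0).astype(
            np.int64
        )
        if (self.counts.to_numpy() < 0).any():
            raise TriageError("confusion counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_total(self, category: TriageCategory) -> int:
        return int(self.counts.loc[category.value].sum())

    @classmethod
    def from_cells(
        cls, cells: dict[tuple[TriageCategory, TriageCategory], int], algorithm: str = ""
    ) -> "ConfusionMatrix":
        frame = pd.DataFrame(
            0,
            index=[c.value for c in REFERENCE_CATEGORIES],
            columns=[c.value for c in ASSIGNED_OUTCOMES],
        )
        for (ref, assigned), n in cells.items():
            frame.loc[ref.value, assigned.value] += int(n)
        return cls(frame, algorithm=algorithm)


@dataclass(frozen=True)
class QualityMetrics:
    """One-vs-rest diagnostic quality for a single category.

    Metrics whose denominator is empty are ``None`` (explicitly undefined),
    never silently 0.  ``youden`` is sensitivity + specificity − 1 exactly.
    """

    category: TriageCategory
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    youden: float | None


@dataclass(frozen=True)
class MistriageRates:
    """Fractions of reference-c patients correctly triaged, over- and
    undertriaged (sum to 1)."""

    category: TriageCategory
    n: int
    correct: float
    overtriage: float
    undertriage: float
    counts: tuple[int, int, int] = (0, 0, 0)  # (correct, over, under)


@dataclass(frozen=True)
class StepStats:
    """Median and quartiles of algorithm steps for one stratum; an empty
    stratum is reported with ``median is None`` and renders as "None"."""

    stratum: str
    count: int
    median: float | None
    q1: float | None
    q3: float | None

    def __str__(self) -> str:
        if self.count == 0:
            return "None"
        return f"{_fmt_step(self.median)} [{_fmt_step(self.q1)}–{_fmt_step(self.q3)}]"


def _fmt_step(x: float) -> str:
    return f"{x:g}"


def confusion(
    ref: VignetteSet, results: pd.DataFrame, algorithm: str
) -> ConfusionMatrix:
    """Tally the (reference × assigned) matrix for one algorithm from the
    long result table.  Every vignette must carry a reference and exactly
    one result row for the algorithm."""
    if not ref.has_references():
        raise CoverageError("vignette set has vignettes without reference categories")
    sub = results[results["algorithm"] == algorithm]
    assigned = dict(zip(sub["vignette_id"], sub["assigned"]))
    missing = [v.id for v in ref if v.id not in assigned]
    if missing:
        raise CoverageError(
            f"no {algorithm} result for vignettes {missing[:10]}"
            + ("…" if len(missing) > 10 else "")
        )
    frame = pd.DataFrame(
        0,
        index=[c.value for c in REFERENCE_CATEGORIES],
        columns=[c.value for c in ASSIGNED_OUTCOMES],
    )
    for v in ref:
        frame.loc[v.reference_category.value, assigned[v.id]] += 1
    return ConfusionMatrix(frame, algorithm=algorithm)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def test_quality(cm: ConfusionMatrix, category: TriageCategory) -> QualityMetrics:
    """Sensitivity, specificity, PPV, NPV and Youden index for one category
    (one-vs-rest collapse of the confusion matrix)."""
    if category not in REFERENCE_CATEGORIES:
        raise TriageError(f"test quality is defined for T1/T2/T3, not {category}")
    c = category.value
    tp = int(cm.counts.loc[c, c])
    fn = cm.row_total(category) - tp
    fp = int(cm.counts[c].sum()) - tp
    tn = cm.n_total - tp - fn - fp
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    return QualityMetrics(
        category=category,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        youden=None if sens is None or spec is None else sens + spec - 1,
    )


def classify_outcome(
    reference: TriageCategory, assigned: TriageCategory
) -> Literal["correct", "overtriage", "undertriage"]:
    """Ordinal mistriage classification of a single triage decision."""
    if assigned == reference:
        return "correct"
    return "overtriage" if assigned.urgency_rank < reference.urgency_rank else "undertriage"


def mistriage(cm: ConfusionMatrix, category: TriageCategory) -> MistriageRates:
    """Correct / overtriage / undertriage fractions among reference-c
    patients."""
    n = cm.row_total(category)
    if n == 0:
        raise TriageError(f"no reference-{category.value} patients in the matrix")
    correct = over = under = 0
    for outcome in ASSIGNED_OUTCOMES:
        k = int(cm.counts.loc[category.value, outcome.value])
        if k == 0:
            continue
        kind = classify_outcome(category, outcome)
        if kind == "correct":
            correct += k
        elif kind == "overtriage":
            over += k
        else:
            under += k
    return MistriageRates(
        category=category,
        n=n,
        correct=correct / n,
        overtriage=over / n,
        undertriage=under / n,
        counts=(correct, over, under),
    )


def step_stats(
    results: pd.DataFrame,
    ref: VignetteSet,
    algorithm: str,
    category: TriageCategory,
    stratum: Stratum,
) -> StepStats:
    """Quartile summary of step counts for reference-c vignettes in one
    mistriage stratum (or overall).  Quartiles use linear interpolation."""
    refs = {v.id: v.reference_category for v in ref}
    sub = results[results["algorithm"] == algorithm]
    steps = []
    for vid, assigned, n_steps in zip(sub["vignette_id"], sub["assigned"], sub["steps"]):
        if vid not in refs or refs[vid] != category:
            continue
        kind = classify_outcome(category, TriageCategory(assigned))
        if stratum == "overall" or kind == stratum:
            steps.append(int(n_steps))
    if not steps:
        return StepStats(stratum=stratum, count=0, median=None, q1=None, q3=None)
    arr = np.asarray(steps, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return StepStats(
        stratum=stratum, count=len(steps), median=float(med), q1=float(q1), q3=float(q3)
    )


@dataclass
class TimeModel:
    """Projection of total triage time for a cohort.

    ``durations_s`` gives seconds per patient per living category;
    ``distribution`` gives the cohort's category fractions (it may include a
    ``"dead"`` stratum which accrues no triage time); ``cohort`` is the
    number of patients.
    """

    durations_s: dict[str, float]
    distribution: dict[str, float]
    cohort: int = 100

    def validate(self) -> None:
        if self.cohort <= 0:
            raise ModelError("cohort size must be positive")
        total = sum(self.distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ModelError(f"category distribution sums to {total}, not 1")
        for cat, dur in self.durations_s.items():
            if dur <= 0:
                raise ModelError(f"duration for {cat} must be > 0, got {dur}")
        for cat in self.distribution:
            if cat != "dead" and cat not in self.durations_s:
                raise ModelError(f"no duration supplied for category {cat!r}")


def time_projection(tm: TimeModel) -> pd.DataFrame:
    """Total triage time per category (minutes) and each category's share of
    the cohort's total triage time (percent).  The dead stratum is excluded
    from time accrual."""
    tm.validate()
    rows = []
    totals: dict[str, float] = {}
    for cat, frac in tm.distribution.items():
        if cat == "dead":
            continue
        totals[cat] = tm.cohort * frac * tm.durations_s[cat] / 60.0
    grand = sum(totals.values())
    for cat, minutes in totals.items():
        rows.append(
            {
                "category": cat,
                "patients": tm.cohort * tm.distribution[cat],
                "total_minutes": minutes,
                "share_pct": 100.0 * minutes / grand if grand > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["category", "patients", "total_minutes", "share_pct"])


@dataclass
class QualityReport:
    """Per-category report tables plus the T1 ROC-style scatter table."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scatter_t1: pd.DataFrame | None = None
    full_precision: dict = field(default_factory=dict)


_STRATA_BY_CATEGORY: dict[str, tuple[str, ...]] = {
    "T1": ("correct", "undertriage", "overall"),
    "T2": ("correct", "overtriage", "undertriage", "overall"),
    "T3": ("correct", "overtriage", "overall"),
}


def quality_report(
    vset: VignetteSet, results: pd.DataFrame, algorithms: list[str]
) -> QualityReport:
    """Build the full report: one table per category (rows = metrics and
    step strata, columns = algorithms), the T1 scatter table
    (1−specificity vs sensitivity), and a machine-readable dictionary of all
    full-precision values."""
    report = QualityReport()
    full: dict = {}
    for category in REFERENCE_CATEGORIES:
        cols: dict[str, dict[str, str]] = {}
        for algo in algorithms:
            cm = confusion(vset, results, algo)
            qm = test_quality(cm, category)
            mr = mistriage(cm, category)
            cell: dict[str, str] = {}
            for label, value in (
                ("sensitivity", qm.sensitivity),
                ("specificity", qm.specificity),
                ("ppv", qm.ppv),
                ("npv", qm.npv),
                ("youden", qm.youden),
            ):
                cell[label] = "undefined" if value is None else f"{value:.2f}"
            if category != TriageCategory.T1:
                cell["overtriage_pct"] = f"{100 * mr.overtriage:.1f}"
            if category != TriageCategory.T3:
                cell["undertriage_pct"] = f"{100 * mr.undertriage:.1f}"
            for stratum in _STRATA_BY_CATEGORY[category.value]:
                cell[f"steps_{stratum}"] = str(
                    step_stats(results, vset, algo, category, stratum)
                )
            cols[algo] = cell
            full.setdefault(category.value, {})[algo] = {
                "sensitivity": qm.sensitivity,
                "specificity": qm.specificity,
                "ppv": qm.ppv,
                "npv": qm.npv,
                "youden": qm.youden,
                "correct": mr.correct,
                "overtriage": mr.overtriage,
                "undertriage": mr.undertriage,
                "n": mr.n,
            }
        report.tables[category.value] = pd.DataFrame(cols)
    scatter_rows = []
    for algo in algorithms:
        qm = test_quality(confusion(vset, results, algo), TriageCategory.T1)
        scatter_rows.append(
            {
                "algorithm": algo,
                "one_minus_specificity": None
                if qm.specificity is None
                else 1 - qm.specificity,
                "sensitivity": qm.sensitivity,
            }
        )
    report.scatter_t1 = pd.DataFrame(scatter_rows)
    report.full_precision = full
    return report
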