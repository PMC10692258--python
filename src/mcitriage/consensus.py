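"""Expert-panel consensus: the median ordinal rating as gold standard.

The reference category of each vignette is the median of the panel's
ordinal ratings on the urgency scale T1 < T2 < T3 (ranks 1 < 2 < 3).  With
an even panel the sample median can land between two ranks; such ties are
rounded toward the *more urgent* category — the safety-conservative choice
in triage doctrine, where overtriage is preferred to undertriage — and every
tie-rounded vignette is flagged in the agreement summary so downstream
sensitivity to the rule can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .categories import REFERENCE_CATEGORIES, TriageCategory, category_from_rank
from .errors import PanelError
from .vignettes import VignetteSet

__all__ = [
    "PanelRatings",
    "ConsensusResult",
    "median_category",
    "build_reference",
    "load_panel",
    "save_panel",
]


@dataclass
class PanelRatings:
    """Complete R×V rating matrix: ``ratings[r, v]`` is rater r's urgency
    rank (1..3) for vignette ``vignette_ids[v]``.  No missing cells."""

    vignette_ids: list[str]
    ratings: np.ndarray  # shape (R, V), integer ranks in {1, 2, 3}

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=np.int64)
        if self.ratings.ndim != 2:
            raise PanelError("ratings must be a 2-D rater × vignette matrix")
        if self.ratings.shape[0] < 1:
            raise PanelError("panel needs at least one rater")
        if self.ratings.shape[1] != len(self.vignette_ids):
            raise PanelError(
                f"{self.ratings.shape[1]} rating columns but "
                f"{len(self.vignette_ids)} vignette ids"
            )
        if not np.isin(self.ratings, (1, 2, 3)).all():
            raise PanelError("ratings must be urgency ranks in {1, 2, 3} (T1/T2/T3)")

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_vignettes(self) -> int:
        return self.ratings.shape[1]

    @property
    def n_ratings(self) -> int:
        """Total triage processes consumed (raters × vignettes)."""
        return self.ratings.size

    @classmethod
    def from_categories(
        cls, vignette_ids: Sequence[str], rows: Sequence[Sequence[TriageCategory]]
    ) -> "PanelRatings":
        matrix = [[_as_rank(c) for c in row] for row in rows]
        return cls(list(vignette_ids), np.array(matrix, dtype=np.int64))


@dataclass
class ConsensusResult:
    """Per-vignette reference plus an agreement summary.

    ``agreement`` has one row per vignette: the median category, the fraction
    of raters matching it, and whether the median required tie rounding.
    """

    references: dict[str, TriageCategory]
    agreement: pd.DataFrame
    n_ratings: int

    @property
    def n_tie_rounded(self) -> int:
        return int(self.agreement["tie_rounded"].sum())


def _as_rank(category: TriageCategory) -> int:
    if category not in REFERENCE_CATEGORIES:
        raise PanelError(
            f"panel rating {category.value} outside the reference categories T1/T2/T3"
        )
    return category.urgency_rank


def _median_ranks(ratings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column medians on the rank scale with urgency-conservative tie
    rounding.  Returns (integer median ranks, tie flags)."""
    med = np.median(ratings, axis=0)
    tie = med != np.floor(med)
    # half-integer medians (x.5) round down = toward the more urgent rank
    return np.floor(med).astype(np.int64), tie


def median_category(ratings: Sequence[TriageCategory]) -> TriageCategory:
    """Median of an ordinal rating list; half-integer medians round toward
    the more urgent category."""
    if len(ratings) == 0:
        raise ValueError("median of an empty rating list is undefined")
    ranks = np.array([[_as_rank(c)] for c in ratings], dtype=np.int64)
    med, _ = _median_ranks(ranks)
    return category_from_rank(int(med[0]))


def build_reference(
    panel: PanelRatings, vignettes: VignetteSet | None = None
) -> ConsensusResult:
    """Form the gold standard from a complete panel.

    If a :class:`VignetteSet` is supplied its ids must match the panel's
    columns (a dimension/id mismatch raises :class:`PanelError`); attach the
    result with ``VignetteSet.with_references``.
    """
    if vignettes is not None:
        if len(vignettes) != panel.n_vignettes or set(vignettes.ids) != set(
            panel.vignette_ids
        ):
            raise PanelError(
                f"panel covers {panel.n_vignettes} vignettes but the set has "
                f"{len(vignettes)} (or ids differ)"
            )
    med, tie = _median_ranks(panel.ratings)
    frac = (panel.ratings == med[None, :]).mean(axis=0)
    references = {
        vid: category_from_rank(r) for vid, r in zip(panel.vignette_ids, med)
    }
    agreement = pd.DataFrame(
        {
            "vignette_id": panel.vignette_ids,
            "median_category": [references[v].value for v in panel.vignette_ids],
            "fraction_matching_median": frac,
            "tie_rounded": tie,
        }
    )
    return ConsensusResult(
        references=references, agreement=agreement, n_ratings=panel.n_ratings
    )


def load_panel(path: str | Path) -> PanelRatings:
    """Read a panel CSV: one row per rater, one column per vignette id,
    cells in {T1, T2, T3}."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.isin(("",)).any().any():
        raise PanelError(f"panel {path} has empty cells; a complete matrix is required")
    try:
        rows = [
            [TriageCategory(cell.strip()) for cell in frame.iloc[r]]
            for r in range(len(frame))
        ]
    except ValueError as exc:
        raise PanelError(f"panel {path}: {exc}") from None
    return PanelRatings.from_categories(list(frame.columns), rows)


def save_panel(panel: PanelRatings, path: str | Path) -> None:
    cats = np.vectorize(lambda r: category_from_rank(r).value)(panel.ratings)
    pd.DataFrame(cats, columns=panel.vignette_ids).to_csv(path, index=False)
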