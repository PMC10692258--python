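"""Triage categories and their urgency ordering.

Categories follow the red/yellow/green convention of mass-casualty triage:
T1 (red, immediate vital threat) is the most urgent, T2 (yellow, urgent) next,
T3 (green, minor) least urgent among the admission categories.  T4 (blue,
expectant) and DECEASED are special outcomes some primary algorithms can
emit; they are never valid reference categories for hospital entrance triage
and both rank below T3 for mistriage accounting.
"""

from __future__ import annotations

from enum import Enum

__all__ = [
    "TriageCategory",
    "REFERENCE_CATEGORIES",
    "category_from_rank",
]


class TriageCategory(str, Enum):
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"
    T4 = "T4"
    DECEASED = "DECEASED"

    @property
    def urgency_rank(self) -> int:
        """Ordinal urgency: 1 (most urgent) … 4. T4 and DECEASED share rank 4."""
        return _RANKS[self]

    @property
    def is_reference(self) -> bool:
        """Whether this category may serve as a gold-standard reference."""
        return self in REFERENCE_CATEGORIES

    def __str__(self) -> str:  # keep CSV round-trips clean
        return self.value


_RANKS = {
    TriageCategory.T1: 1,
    TriageCategory.T2: 2,
    TriageCategory.T3: 3,
    TriageCategory.T4: 4,
    TriageCategory.DECEASED: 4,
}

#: Only red/yellow/green may be assigned at hospital entrance triage.
REFERENCE_CATEGORIES = (TriageCategory.T1, TriageCategory.T2, TriageCategory.T3)

_FROM_RANK = {1: TriageCategory.T1, 2: TriageCategory.T2, 3: TriageCategory.T3}


def category_from_rank(rank: int) -> TriageCategory:
    """Inverse of ``urgency_rank`` on the reference categories {1, 2, 3}."""
    try:
        return _FROM_RANK[int(rank)]
    except KeyError:
        raise ValueError(f"no reference category with urgency rank {rank!r}") from None
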