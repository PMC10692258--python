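"""Coded patient vignettes: data model and CSV I/O.

A vignette is one simulated casualty, reduced to the coded answers every
triage query would receive ("0"/"1"/"n", plus "2" for the ESI resource
query).  A :class:`VignetteSet` is the tabular database the decision-tree
engine runs on; its optional ``reference_category`` column carries the
expert-consensus gold standard.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .categories import REFERENCE_CATEGORIES, TriageCategory
from .errors import (
    CodedValueError,
    ReferenceRestrictionError,
    TriageError,
    UniquenessError,
)
from .vocabulary import canonical_query, valid_codes

__all__ = ["Vignette", "VignetteSet", "load_vignettes", "save_vignettes", "category_counts"]

_ID_COL = "id"
_REF_COL = "reference_category"


@dataclass(frozen=True)
class Vignette:
    """One casualty: unique id plus coded answers per canonical query id."""

    id: str
    answers: dict[str, str]
    reference_category: TriageCategory | None = None

    def validate(self) -> None:
        if not self.id:
            raise TriageError("vignette id must be nonempty")
        for query_id, code in self.answers.items():
            qid = canonical_query(query_id)
            if code not in valid_codes(qid):
                raise CodedValueError(
                    f"vignette {self.id!r}, query {query_id!r}: "
                    f"invalid code {code!r} (expected one of "
                    f"{sorted(valid_codes(qid))})",
                    row=self.id,
                    column=query_id,
                )
        if self.reference_category is not None and not self.reference_category.is_reference:
            raise ReferenceRestrictionError(
                f"vignette {self.id!r}: reference category must be one of "
                f"T1/T2/T3, got {self.reference_category.value}"
            )


@dataclass
class VignetteSet:
    """Ordered collection of vignettes with free-form provenance metadata."""

    vignettes: list[Vignette] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.vignettes)

    def __iter__(self):
        return iter(self.vignettes)

    def __getitem__(self, i):
        return self.vignettes[i]

    @property
    def ids(self) -> list[str]:
        return [v.id for v in self.vignettes]

    @property
    def query_ids(self) -> list[str]:
        """Canonical query columns of the set (lexicographic)."""
        if not self.vignettes:
            return []
        return sorted(self.vignettes[0].answers)

    def has_references(self) -> bool:
        return bool(self.vignettes) and all(
            v.reference_category is not None for v in self.vignettes
        )

    def validate(self) -> None:
        seen: set[str] = set()
        for v in self.vignettes:
            v.validate()
            if v.id in seen:
                raise UniquenessError(f"duplicate vignette id {v.id!r}")
            seen.add(v.id)
        # one tabular schema per set: every row answers the same queries
        if self.vignettes:
            keys0 = set(self.vignettes[0].answers)
            for v in self.vignettes[1:]:
                if set(v.answers) != keys0:
                    raise TriageError(
                        f"vignette {v.id!r} answers a different query set than "
                        f"{self.vignettes[0].id!r}; a set must be tabular"
                    )

    def with_references(self, references: dict[str, TriageCategory]) -> "VignetteSet":
        """Return a copy whose reference categories are taken from a mapping."""
        missing = [v.id for v in self.vignettes if v.id not in references]
        if missing:
            raise TriageError(f"no reference supplied for vignettes {missing[:5]}")
        out = VignetteSet(
            vignettes=[
                Vignette(v.id, dict(v.answers), references[v.id]) for v in self.vignettes
            ],
            provenance=dict(self.provenance),
        )
        out.validate()
        return out


def category_counts(vset: VignetteSet) -> dict[TriageCategory, int]:
    """Reference-category tally; requires every vignette to carry a reference."""
    counts: Counter[TriageCategory] = Counter()
    for v in vset:
        if v.reference_category is None:
            raise TriageError(f"vignette {v.id!r} has no reference category")
        if not v.reference_category.is_reference:
            raise ReferenceRestrictionError(
                f"vignette {v.id!r}: reference {v.reference_category.value} "
                "outside T1/T2/T3"
            )
        counts[v.reference_category] += 1
    return {c: counts.get(c, 0) for c in REFERENCE_CATEGORIES}


def load_vignettes(path: str | Path) -> VignetteSet:
    """Read a vignette CSV (header: ``id``, optional ``reference_category``,
    then query columns).  Column names are normalized through the alias
    table; invalid codes raise :class:`CodedValueError` naming row and
    column; duplicate ids raise :class:`UniquenessError`.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    query_cols: dict[str, str] = {}
    for col in frame.columns:
        if col in (_ID_COL, _REF_COL):
            continue
        query_cols[col] = canonical_query(col)

    vignettes: list[Vignette] = []
    for idx, row in frame.iterrows():
        vid = row[_ID_COL] if _ID_COL in frame.columns else f"row{idx + 1}"
        ref: TriageCategory | None = None
        if _REF_COL in frame.columns:
            raw = row[_REF_COL].strip()
            if raw:
                try:
                    ref = TriageCategory(raw)
                except ValueError:
                    raise ReferenceRestrictionError(
                        f"row {vid!r}: unknown reference category {raw!r}"
                    ) from None
        answers = {}
        for col, qid in query_cols.items():
            code = row[col].strip()
            if code not in valid_codes(qid):
                raise CodedValueError(
                    f"row {vid!r}, column {col!r}: invalid code {code!r}",
                    row=vid,
                    column=col,
                )
            answers[qid] = code
        vignettes.append(Vignette(id=str(vid), answers=answers, reference_category=ref))

    vset = VignetteSet(vignettes=vignettes, provenance={"source": str(path)})
    vset.validate()

    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    if sidecar.exists():
        vset.provenance.update(json.loads(sidecar.read_text()))
    return vset


def save_vignettes(vset: VignetteSet, path: str | Path, provenance_sidecar: bool = False) -> None:
    """Write a vignette CSV with deterministic column order: ``id``,
    ``reference_category`` (when any reference is set), then query ids in
    lexicographic order.  "n" codes are written literally."""
    vset.validate()
    path = Path(path)
    any_ref = any(v.reference_category is not None for v in vset)
    columns = [_ID_COL] + ([_REF_COL] if any_ref else []) + vset.query_ids
    rows = []
    for v in vset:
        row: dict[str, str] = {_ID_COL: v.id}
        if any_ref:
            row[_REF_COL] = v.reference_category.value if v.reference_category else ""
        row.update({q: v.answers[q] for q in vset.query_ids})
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns, dtype=str)
    frame.to_csv(path, index=False)
    if provenance_sidecar and vset.provenance:
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(vset.provenance, indent=2, sort_keys=True) + "\n")
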