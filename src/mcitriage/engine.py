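"""Declarative decision-tree representation and stepwise execution.

Each triage algorithm is a rooted tree (DAGs with shared sub-branches are
allowed) of predicate nodes over the canonical query vocabulary:

* ``binary_query`` nodes branch on yes/no,
* the single ``resource_query`` kind (ESI expected-resource count) branches
  three ways on 0/1/2,
* ``leaf`` nodes carry the assigned triage category, or an ESI level 1–5
  which is mapped onto T1/T2/T3 (levels 3–5 collapse to green).

A traversal's *step count* is the number of query nodes evaluated before the
leaf — the package's surrogate for triage duration.  Vignette answers coded
``"n"`` (not derivable) are resolved by a configurable policy; the default
treats them as "no", on the reasoning that a finding that cannot be derived
cannot trigger a discriminant.  Every such resolution is counted in
``TraversalResult.n_policy_hits`` so runs remain auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .categories import REFERENCE_CATEGORIES, TriageCategory
from .errors import (
    AlgorithmReferenceError,
    AlgorithmStructureError,
    TriageError,
    VocabularyError,
)
from .vignettes import Vignette, VignetteSet
from .vocabulary import RESOURCE_QUERY, canonical_query

__all__ = [
    "DecisionNode",
    "AlgorithmDefinition",
    "TraversalResult",
    "NPolicy",
    "load_algorithm",
    "bundled_algorithm_names",
    "load_bundled_algorithm",
    "load_all_bundled",
    "resolve_query",
    "esi_level_to_category",
    "triage",
    "run_all",
    "path_length_profile",
]

NPolicy = Literal["no", "yes", "error"]

ALGORITHM_NAMES = ("BER", "JorD", "MTS_MCI", "ESI", "PETRA", "PRIOR", "mSTaRT")

_BINARY_ANSWERS = ("yes", "no")
_RESOURCE_ANSWERS = ("0", "1", "2")


@dataclass(frozen=True)
class DecisionNode:
    node_id: str
    kind: Literal["binary_query", "resource_query", "leaf"]
    query_id: str | None = None
    branches: dict[str, str] = field(default_factory=dict)
    outcome: TriageCategory | None = None
    esi_level: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.kind == "leaf"

    @property
    def admissible_answers(self) -> tuple[str, ...]:
        return _RESOURCE_ANSWERS if self.kind == "resource_query" else _BINARY_ANSWERS


@dataclass
class AlgorithmDefinition:
    """A validated triage decision tree."""

    name: str
    role: Literal["primary", "secondary"]
    root: str
    nodes: dict[str, DecisionNode]
    alias_overrides: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def node(self, node_id: str) -> DecisionNode:
        return self.nodes[node_id]

    def query_vocabulary(self) -> set[str]:
        """Canonical query ids this algorithm can evaluate."""
        return {
            canonical_query(n.query_id, self.alias_overrides)
            for n in self.nodes.values()
            if not n.is_leaf
        }

    def validate(self) -> None:
        _validate_definition(self)


@dataclass(frozen=True)
class TraversalResult:
    vignette_id: str
    algorithm: str
    assigned: TriageCategory
    steps: int
    path: tuple[str, ...]
    n_policy_hits: int
    esi_level: int | None = None


def esi_level_to_category(level: int) -> TriageCategory:
    """ESI level → triage category: 1→T1, 2→T2, levels 3–5 collapse to T3."""
    if level not in (1, 2, 3, 4, 5):
        raise ValueError(f"ESI level must be in 1..5, got {level!r}")
    if level == 1:
        return TriageCategory.T1
    if level == 2:
        return TriageCategory.T2
    return TriageCategory.T3


def _validate_definition(algo: AlgorithmDefinition) -> None:
    if algo.role not in ("primary", "secondary"):
        raise AlgorithmStructureError(f"{algo.name}: unknown role {algo.role!r}")
    if algo.root not in algo.nodes:
        raise AlgorithmReferenceError(f"{algo.name}: root {algo.root!r} is undefined")
    for nid, node in algo.nodes.items():
        if node.is_leaf:
            if node.branches:
                raise AlgorithmStructureError(f"{algo.name}: leaf {nid!r} has branches")
            if (node.outcome is None) == (node.esi_level is None):
                raise AlgorithmStructureError(
                    f"{algo.name}: leaf {nid!r} needs exactly one of a category "
                    "outcome or an ESI level"
                )
            if node.esi_level is not None:
                esi_level_to_category(node.esi_level)  # range check
            elif algo.role == "secondary" and node.outcome not in REFERENCE_CATEGORIES:
                raise AlgorithmStructureError(
                    f"{algo.name}: secondary-algorithm leaf {nid!r} may only "
                    f"assign T1/T2/T3, got {node.outcome}"
                )
            continue
        if node.kind == "resource_query" and algo.name != "ESI":
            raise AlgorithmStructureError(
                f"{algo.name}: resource_query nodes are only permitted in ESI"
            )
        if node.query_id is None:
            raise AlgorithmStructureError(f"{algo.name}: node {nid!r} has no query id")
        canonical_query(node.query_id, algo.alias_overrides)  # vocabulary check
        missing = set(node.admissible_answers) - set(node.branches)
        extra = set(node.branches) - set(node.admissible_answers)
        if missing or extra:
            raise AlgorithmStructureError(
                f"{algo.name}: node {nid!r} branches {sorted(node.branches)} "
                f"do not cover exactly {node.admissible_answers}"
            )
        for answer, target in node.branches.items():
            if target not in algo.nodes:
                raise AlgorithmReferenceError(
                    f"{algo.name}: node {nid!r} branch {answer!r} points to "
                    f"undefined node {target!r}"
                )
    _check_acyclic_and_reachable(algo)


def _check_acyclic_and_reachable(algo: AlgorithmDefinition) -> None:
    # iterative DFS with colour marks: detects cycles, collects reachable set
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {nid: WHITE for nid in algo.nodes}
    stack: list[tuple[str, bool]] = [(algo.root, False)]
    while stack:
        nid, done = stack.pop()
        if done:
            colour[nid] = BLACK
            continue
        if colour[nid] == GREY:
            continue
        if colour[nid] == BLACK:
            continue
        colour[nid] = GREY
        stack.append((nid, True))
        node = algo.nodes[nid]
        for target in node.branches.values():
            if colour[target] == GREY:
                raise AlgorithmStructureError(
                    f"{algo.name}: cycle through node {target!r}"
                )
            if colour[target] == WHITE:
                stack.append((target, False))
    unreachable = sorted(nid for nid, c in colour.items() if c == WHITE)
    if unreachable:
        raise AlgorithmStructureError(
            f"{algo.name}: unreachable nodes {unreachable}"
        )


def load_algorithm(path: str | Path) -> AlgorithmDefinition:
    """Load and validate a JSON algorithm definition.

    Layout: ``{"name", "role", "root", "nodes": {id: {"kind", "query",
    "branches"} | {"kind": "leaf", "outcome"|"esi_level"}}, "aliases"?,
    "provenance"?}``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        return _definition_from_dict(json.load(fh), source=str(path))


def _definition_from_dict(raw: dict, source: str = "<dict>") -> AlgorithmDefinition:
    try:
        nodes = {}
        for nid, spec in raw["nodes"].items():
            kind = spec["kind"]
            if kind == "leaf":
                outcome = spec.get("outcome")
                nodes[nid] = DecisionNode(
                    node_id=nid,
                    kind="leaf",
                    outcome=TriageCategory(outcome) if outcome is not None else None,
                    esi_level=spec.get("esi_level"),
                )
            else:
                nodes[nid] = DecisionNode(
                    node_id=nid,
                    kind=kind,
                    query_id=spec["query"],
                    branches={str(k): str(v) for k, v in spec["branches"].items()},
                )
        algo = AlgorithmDefinition(
            name=raw["name"],
            role=raw["role"],
            root=raw["root"],
            nodes=nodes,
            alias_overrides=dict(raw.get("aliases", {})),
            provenance=raw.get("provenance", ""),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise AlgorithmStructureError(f"{source}: malformed definition ({exc})") from exc
    algo.validate()
    return algo


def bundled_algorithm_names() -> tuple[str, ...]:
    return ALGORITHM_NAMES


def load_bundled_algorithm(name: str) -> AlgorithmDefinition:
    """Load one of the seven shipped algorithm definitions by name."""
    if name not in ALGORITHM_NAMES:
        raise TriageError(f"no bundled algorithm {name!r}; know {ALGORITHM_NAMES}")
    ref = resources.files("mcitriage").joinpath(f"algorithms/{name.lower()}.json")
    return _definition_from_dict(json.loads(ref.read_text(encoding="utf-8")), source=name)


def load_all_bundled() -> list[AlgorithmDefinition]:
    return [load_bundled_algorithm(n) for n in ALGORITHM_NAMES]


class _HitCounter:
    __slots__ = ("hits",)

    def __init__(self) -> None:
        self.hits = 0


def resolve_query(
    vignette: Vignette,
    query_id: str,
    n_policy: NPolicy = "no",
    aliases: dict[str, str] | None = None,
    _counter: _HitCounter | None = None,
) -> str:
    """Answer one query from a vignette's coded answers.

    Returns ``"yes"``/``"no"`` for binary queries and ``"0"``/``"1"``/``"2"``
    for the ESI resource query.  A ``"n"`` code is resolved per the policy
    ("no" → negative / zero resources, "yes" → positive / many resources,
    "error" → raise), and the resolution is tallied on the counter.
    """
    qid = canonical_query(query_id, aliases)
    try:
        code = vignette.answers[qid]
    except KeyError:
        raise VocabularyError(
            f"vignette {vignette.id!r} has no answer for query {qid!r}"
        ) from None
    if code == "n":
        if n_policy == "error":
            raise TriageError(
                f"vignette {vignette.id!r}: query {qid!r} is not derivable "
                "and the n-policy is 'error'"
            )
        if _counter is not None:
            _counter.hits += 1
        if qid == RESOURCE_QUERY:
            return "2" if n_policy == "yes" else "0"
        return n_policy
    if qid == RESOURCE_QUERY:
        return code
    return "yes" if code == "1" else "no"


def triage(
    vignette: Vignette, algo: AlgorithmDefinition, n_policy: NPolicy = "no"
) -> TraversalResult:
    """Run one vignette through one algorithm; deterministic in (answers,
    definition, n-policy)."""
    counter = _HitCounter()
    path: list[str] = []
    node = algo.node(algo.root)
    guard = len(algo.nodes) + 1
    while not node.is_leaf:
        path.append(node.node_id)
        if len(path) > guard:  # unreachable on validated definitions
            raise AlgorithmStructureError(f"{algo.name}: traversal exceeded node count")
        answer = resolve_query(
            vignette, node.query_id, n_policy, algo.alias_overrides, counter
        )
        node = algo.node(node.branches[answer])
    path.append(node.node_id)
    if node.esi_level is not None:
        assigned = esi_level_to_category(node.esi_level)
    else:
        assigned = node.outcome
    return TraversalResult(
        vignette_id=vignette.id,
        algorithm=algo.name,
        assigned=assigned,
        steps=len(path) - 1,
        path=tuple(path),
        n_policy_hits=counter.hits,
        esi_level=node.esi_level,
    )


def run_all(
    vset: VignetteSet,
    algos: Iterable[AlgorithmDefinition],
    n_policy: NPolicy = "no",
) -> pd.DataFrame:
    """Cross product of vignettes × algorithms as a tidy long table
    (vignette-major order).  Per-vignette failures are aggregated into one
    error naming the offending ids."""
    algos = list(algos)
    rows = []
    failures: list[str] = []
    for v in vset:
        for algo in algos:
            try:
                r = triage(v, algo, n_policy)
            except TriageError as exc:
                failures.append(f"{v.id}/{algo.name}: {exc}")
                continue
            rows.append(
                {
                    "vignette_id": r.vignette_id,
                    "algorithm": r.algorithm,
                    "assigned": r.assigned.value,
                    "steps": r.steps,
                    "n_policy_hits": r.n_policy_hits,
                    "path": ";".join(r.path),
                }
            )
    if failures:
        raise TriageError(
            f"{len(failures)} traversal(s) failed: " + "; ".join(failures[:10])
        )
    return pd.DataFrame(
        rows,
        columns=["vignette_id", "algorithm", "assigned", "steps", "n_policy_hits", "path"],
    )


def path_length_profile(
    algo: AlgorithmDefinition,
) -> dict[TriageCategory, tuple[int, int]]:
    """Shortest and longest root-to-leaf step counts per outcome category,
    by exhaustive path enumeration (the trees are small; brute force is
    exact)."""
    profile: dict[TriageCategory, tuple[int, int]] = {}

    def walk(node_id: str, depth: int) -> None:
        node = algo.node(node_id)
        if node.is_leaf:
            cat = (
                esi_level_to_category(node.esi_level)
                if node.esi_level is not None
                else node.outcome
            )
            lo, hi = profile.get(cat, (depth, depth))
            profile[cat] = (min(lo, depth), max(hi, depth))
            return
        for target in node.branches.values():
            walk(target, depth + 1)

    walk(algo.root, 0)
    return profile
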