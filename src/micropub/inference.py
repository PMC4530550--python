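"""Rule semantics over micropublication relation sets.

Two rules drive everything here:

* ``supports`` is transitive — the stored edges are the asserted base
  relation and :func:`supports_closure` computes the smallest transitive
  superset;
* a representation *challenges* another if it directly challenges it, or
  indirectly challenges it by *undercutting* — directly challenging some
  representation that supports it.

By default undercutting is read over the transitive supports closure, so
attacking any ancestor supporter of a claim challenges the claim itself;
a strict one-step mode is available.  Challenges are never chained over
themselves (no "challenger of my challenger" inference).

Support and challenge graphs are views instantiated by query, never
stored in the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Union

from .model import (
    Micropublication,
    Relation,
    RelKind,
    RepKind,
    Representation,
    is_a,
    validate,
)

Pair = tuple[str, str]


class InvalidMicropublicationError(ValueError):
    """Raised when an operation requires a valid micropublication."""

    def __init__(self, report):
        codes = ", ".join(v.code.value for v in report.violations)
        super().__init__(f"{report.subject} fails validation: {codes}")
        self.report = report


def _pairs(relations: Iterable[Union[Relation, Pair]], kind: RelKind) -> set[Pair]:
    out: set[Pair] = set()
    for rel in relations:
        if isinstance(rel, Relation):
            if rel.rel_kind == kind:
                out.add(rel.pair)
        elif kind == RelKind.SUPPORTS:
            out.add(tuple(rel))  # bare pairs are read as supports edges
    return out


def _reachable(adj: Mapping[str, set[str]], start: str) -> set[str]:
    """Nodes reachable from `start` by at least one edge (may include start)."""
    seen: set[str] = set()
    stack = list(adj.get(start, ()))
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        stack.extend(adj.get(node, ()))
    return seen


@dataclass(frozen=True)
class RelationClosure:
    base: frozenset[Pair]
    closed: frozenset[Pair]
    rel_kind: RelKind = RelKind.SUPPORTS

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.closed


def supports_closure(relations: Iterable[Union[Relation, Pair]]) -> RelationClosure:
    """Smallest transitive superset of the supports pairs in `relations`.

    Cyclic input (possible in merged cross-publication networks, which the
    per-MP DAG invariant does not forbid) yields reflexive pairs in the
    closure; callers may flag them.
    """
    base = _pairs(relations, RelKind.SUPPORTS)
    adj: dict[str, set[str]] = {}
    for s, t in base:
        adj.setdefault(s, set()).add(t)
    closed = {
        (u, v) for u in adj for v in _reachable(adj, u)
    }
    return RelationClosure(base=frozenset(base), closed=frozenset(closed))


def infer_challenges(
    relations: Iterable[Union[Relation, Pair]], mode: str = "transitive"
) -> set[Pair]:
    """Direct plus undercutting challenges.

    indirect(x, z) holds iff directlyChallenges(x, y) for some y with
    (y, z) in the supports closure (`mode="transitive"`) or in the base
    supports relation (`mode="one_step"`).  The result is not closed
    over itself.
    """
    if mode not in ("transitive", "one_step"):
        raise ValueError(f"mode must be 'transitive' or 'one_step', got {mode!r}")
    relations = list(relations)
    direct = _pairs(relations, RelKind.DIRECTLY_CHALLENGES)
    if not direct:
        return set()
    if mode == "transitive":
        sup = supports_closure(relations).closed
    else:
        sup = _pairs(relations, RelKind.SUPPORTS)
    inferred = set(direct)
    for x, y in direct:
        for s, z in sup:
            if s == y:
                inferred.add((x, z))
    return inferred


@dataclass(frozen=True)
class GraphView:
    """A support or challenge graph, instantiated by query."""

    root: str
    nodes: frozenset[str]
    edges: tuple[Relation, ...]
    view_kind: str  # "support_graph" | "challenge_graph"


def _require_valid(mp: Micropublication) -> None:
    report = validate(mp)
    if not report.is_valid:
        raise InvalidMicropublicationError(report)


def support_graph(mp: Micropublication) -> GraphView:
    """Phi+ — every element with a supports path to the claim.

    Edges include all relations among the members and the claim, so a
    directlyChallenges edge between two members (the quoted-conflict
    pattern) is part of the support graph: the conflict is exactly what
    such a micropublication argues.
    """
    _require_valid(mp)
    closure = supports_closure(mp.relations)
    nodes = {e for e in mp.phi if e != mp.claim and (e, mp.claim) in closure}
    scope = nodes | {mp.claim}
    edges = tuple(
        r for r in mp.relations if r.source in scope and r.target in scope
    )
    return GraphView(
        root=mp.claim, nodes=frozenset(nodes), edges=edges, view_kind="support_graph"
    )


def challenge_graph(mp: Micropublication) -> GraphView:
    """Elements of Phi with an inferred challenges path to the claim."""
    _require_valid(mp)
    challenges = infer_challenges(mp.relations)
    nodes = {e for e in mp.phi if e != mp.claim and (e, mp.claim) in challenges}
    edges = tuple(r for r in mp.relations if r.source in nodes)
    return GraphView(
        root=mp.claim, nodes=frozenset(nodes), edges=edges, view_kind="challenge_graph"
    )


def derived_flags(
    statement: str,
    relations: Iterable[Union[Relation, Pair]],
    reps: Mapping[str, Representation],
    *,
    use_closure: bool = True,
) -> dict[str, bool]:
    """supportedByData / supportedByMethod flags for a statement or datum.

    If data supports a statement, the statement is supportedByData; data
    is supportedByMethod if a method (procedure or material) supports it.
    With ``use_closure`` (default) support is read transitively; the
    strict variant considers direct edges only.
    """
    if statement not in reps:
        raise KeyError(f"unknown representation {statement}")
    relations = list(relations)
    sup = (
        supports_closure(relations).closed
        if use_closure
        else _pairs(relations, RelKind.SUPPORTS)
    )

    def supporters_of(node: str, kind_test) -> set[str]:
        return {
            s
            for s, t in sup
            if t == node and s in reps and kind_test(reps[s].rep_kind)
        }

    is_data = lambda k: k == RepKind.DATA  # noqa: E731
    is_method = lambda k: is_a(k, RepKind.METHOD)  # noqa: E731

    if reps[statement].rep_kind == RepKind.DATA:
        return {
            "supportedByData": bool(supporters_of(statement, is_data)),
            "supportedByMethod": bool(supporters_of(statement, is_method)),
        }
    data_supporters = supporters_of(statement, is_data)
    by_method = any(supporters_of(d, is_method) for d in data_supporters)
    return {
        "supportedByData": bool(data_supporters),
        "supportedByMethod": by_method,
    }


__all__ = [
    "GraphView",
    "InvalidMicropublicationError",
    "RelationClosure",
    "challenge_graph",
    "derived_flags",
    "infer_challenges",
    "support_graph",
    "supports_closure",
]
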