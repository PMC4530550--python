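"""Core domain model for micropublications.

A micropublication formalizes one argument from the scientific literature:
a single principal Claim together with the graph of representations
(statements, data, methods, references, attributions) that support or
challenge it.  Formally an argument text ``a`` is modelled as

    MP_a = <A_mpa, c, A_c, Phi, R>

where ``A_mpa`` is the attribution of the formalization itself, ``c`` the
principal claim, ``A_c`` the claim's attribution, ``Phi`` a finite non-empty
set of representation elements (partitioned into *asserted* and *quoted*),
and ``R`` a set of typed relations partitioned into supports (R+) and
directlyChallenges (R-) edges.  Within one micropublication the supports
edges form a DAG whose greatest element is the claim.

This module owns the types, the builder API and :func:`validate`, which
checks every formal invariant and reports violations rather than raising.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

DEFAULT_BASE = "http://example.org/micropub"


class RepKind(str, Enum):
    """Representation kinds, forming a small subsumption hierarchy."""

    SENTENCE = "sentence"
    STATEMENT = "statement"
    CLAIM = "claim"
    QUALIFIER = "qualifier"
    REFERENCE = "reference"
    SEMANTIC_QUALIFIER = "semantic_qualifier"
    DATA = "data"
    METHOD = "method"  # abstract: never instantiated directly
    PROCEDURE = "procedure"
    MATERIAL = "material"
    ARTICLE_TEXT = "article_text"
    ATTRIBUTION = "attribution"


# claim < statement < sentence; reference, semantic_qualifier < qualifier < sentence;
# procedure, material < method (abstract).
_PARENT: dict[RepKind, RepKind] = {
    RepKind.CLAIM: RepKind.STATEMENT,
    RepKind.STATEMENT: RepKind.SENTENCE,
    RepKind.QUALIFIER: RepKind.SENTENCE,
    RepKind.REFERENCE: RepKind.QUALIFIER,
    RepKind.SEMANTIC_QUALIFIER: RepKind.QUALIFIER,
    RepKind.PROCEDURE: RepKind.METHOD,
    RepKind.MATERIAL: RepKind.METHOD,
}

ABSTRACT_KINDS = frozenset({RepKind.METHOD})


def is_a(kind: RepKind, ancestor: RepKind) -> bool:
    """Subsumption test on representation kinds (reflexive, transitive)."""
    k: Optional[RepKind] = kind
    while k is not None:
        if k == ancestor:
            return True
        k = _PARENT.get(k)
    return False


def sentence_family(kind: RepKind) -> bool:
    return is_a(kind, RepKind.SENTENCE)


def method_family(kind: RepKind) -> bool:
    return is_a(kind, RepKind.METHOD)


class AgentKind(str, Enum):
    PERSON = "person"
    ORGANIZATION = "organization"


class RelKind(str, Enum):
    SUPPORTS = "supports"
    DIRECTLY_CHALLENGES = "directlyChallenges"


class Role(str, Enum):
    AUTHOR = "author"
    CURATOR = "curator"
    ANNOTATOR = "annotator"


class ViolationCode(str, Enum):
    EMPTY_PHI = "EMPTY_PHI"
    NO_CLAIM = "NO_CLAIM"
    CLAIM_NOT_ELEMENT = "CLAIM_NOT_ELEMENT"
    DANGLING_ENDPOINT = "DANGLING_ENDPOINT"
    SUPPORT_CYCLE = "SUPPORT_CYCLE"
    CLAIM_NOT_GREATEST = "CLAIM_NOT_GREATEST"
    MISSING_CLAIM_ATTRIBUTION = "MISSING_CLAIM_ATTRIBUTION"
    KIND_VIOLATION = "KIND_VIOLATION"
    DUAL_EDGE = "DUAL_EDGE"


class MicropubError(ValueError):
    """Builder-level rejection carrying a violation code."""

    def __init__(self, code: ViolationCode, message: str):
        super().__init__(f"{code.value}: {message}")
        self.code = code


@dataclass(frozen=True)
class Agent:
    id: str
    name: str
    agent_kind: AgentKind = AgentKind.PERSON


@dataclass(frozen=True)
class Attribution:
    """Attribution of a statement or of a micropublication to an agent.

    The minimal level of support for any statement is its attribution,
    so claim attributions participate in supports edges as ordinary
    elements of Phi.
    """

    id: str
    agent: str  # Agent IRI (attributionOfAgent)
    role: Optional[Role] = None
    timestamp: Optional[str] = None  # ISO-8601 instant; never compared


@dataclass(frozen=True)
class Media:
    media_type: str
    locator: str


@dataclass(frozen=True)
class Representation:
    """Any element of an argument.

    ``text`` is required for the sentence family, ``target`` for
    references (a DOI / PubMed ID / IRI), ``term`` for semantic
    qualifiers (an ontology-term IRI), ``media`` describes data /
    procedure / material payloads, and ``attribution`` carries the
    agent link when ``rep_kind`` is ``attribution``.
    """

    id: str
    rep_kind: RepKind
    text: Optional[str] = None
    media: Optional[Media] = None
    target: Optional[str] = None
    term: Optional[str] = None
    attribution: Optional[Attribution] = None


@dataclass(frozen=True)
class Relation:
    source: str
    rel_kind: RelKind
    target: str
    asserted_by: str

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class Violation:
    code: ViolationCode
    detail: str
    offending_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class ValidationReport:
    subject: str
    violations: tuple[Violation, ...]

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def as_dict(self) -> dict:
        return {
            "subject": self.subject,
            "is_valid": self.is_valid,
            "violations": [
                {
                    "code": v.code.value,
                    "detail": v.detail,
                    "offending_ids": list(v.offending_ids),
                }
                for v in self.violations
            ],
        }


@dataclass
class Micropublication:
    """The argument container: one claim plus its typed relation graph."""

    id: str
    attribution: Attribution  # A_mpa
    claim: Optional[str] = None  # c, a Representation IRI of kind claim
    asserted: dict[str, Representation] = field(default_factory=dict)
    quoted: dict[str, Representation] = field(default_factory=dict)
    relations: list[Relation] = field(default_factory=list)
    qualifications: set[tuple[str, str]] = field(default_factory=set)
    source_document: Optional[str] = None  # the ArticleText `a` was drawn from
    agents: dict[str, Agent] = field(default_factory=dict)
    annotation: bool = False  # resolution / curation MPs; excluded from publication tallies
    extra_triples: tuple = ()  # foreign-namespace RDF preserved for round-tripping

    @property
    def phi(self) -> set[str]:
        """Phi = asserted ∪ quoted element IRIs."""
        return set(self.asserted) | set(self.quoted)

    @property
    def elements(self) -> dict[str, Representation]:
        merged = dict(self.quoted)
        merged.update(self.asserted)
        return merged

    def supports_pairs(self) -> set[tuple[str, str]]:
        return {r.pair for r in self.relations if r.rel_kind == RelKind.SUPPORTS}


# ---------------------------------------------------------------------------
# builder API


def _slug(text: str) -> str:
    return hashlib.sha1(text.encode("utf-8")).hexdigest()[:10]


def mint_iri(base: str, mp_local: str, element_local: str = "") -> str:
    if element_local:
        return f"{base}/{mp_local}#{element_local}"
    return f"{base}/{mp_local}"


def _check_representation(rep: Representation) -> Optional[str]:
    """Return a kind-violation message for a malformed representation, or None."""
    if rep.rep_kind in ABSTRACT_KINDS:
        return f"kind {rep.rep_kind.value} is abstract; instantiate procedure or material"
    if sentence_family(rep.rep_kind) and rep.rep_kind not in (
        RepKind.REFERENCE,
        RepKind.SEMANTIC_QUALIFIER,
    ):
        if not (rep.text and rep.text.strip()):
            return f"{rep.rep_kind.value} representation requires non-empty text"
    if rep.rep_kind == RepKind.REFERENCE and not (rep.target and rep.target.strip()):
        return "reference requires a non-empty target"
    if rep.rep_kind == RepKind.SEMANTIC_QUALIFIER and not (rep.term and rep.term.strip()):
        return "semantic_qualifier requires a non-empty term"
    if rep.rep_kind == RepKind.ATTRIBUTION and rep.attribution is None:
        return "attribution representation requires an attribution payload"
    return None


def make_micropublication(
    claim_text: str,
    claim_attribution_agent: Agent,
    mp_attribution_agent: Agent,
    *,
    base: str = DEFAULT_BASE,
    mp_id: Optional[str] = None,
    claim_local: str = "claim",
    source_document: Optional[str] = None,
) -> Micropublication:
    """Build a valid minimal micropublication: a claim and its attribution.

    The result has asserted = {c, A_c}, relations = {supports(A_c, c)} and
    an MP-level attribution A_mpa; it always passes :func:`validate`.
    """
    if not claim_text or not claim_text.strip():
        raise MicropubError(ViolationCode.NO_CLAIM, "claim text must be non-empty")
    local = mp_id or f"mp-{_slug(claim_text)}"
    mp_iri = mint_iri(base, local)
    claim_iri = mint_iri(base, local, claim_local)
    a_c = Attribution(
        id=mint_iri(base, local, f"A_{claim_local}"),
        agent=claim_attribution_agent.id,
        role=Role.AUTHOR,
    )
    a_mpa = Attribution(
        id=mint_iri(base, local, "attr-mp"),
        agent=mp_attribution_agent.id,
        role=Role.CURATOR,
    )
    mp = Micropublication(
        id=mp_iri,
        attribution=a_mpa,
        claim=claim_iri,
        source_document=source_document,
        agents={
            claim_attribution_agent.id: claim_attribution_agent,
            mp_attribution_agent.id: mp_attribution_agent,
        },
    )
    add_element(mp, Representation(id=claim_iri, rep_kind=RepKind.CLAIM, text=claim_text))
    add_element(
        mp,
        Representation(id=a_c.id, rep_kind=RepKind.ATTRIBUTION, attribution=a_c),
    )
    add_relation(mp, a_c.id, RelKind.SUPPORTS, claim_iri)
    return mp


def add_element(
    mp: Micropublication, rep: Representation, mode: str = "asserts"
) -> Micropublication:
    """Add a representation to Phi, either asserted or quoted."""
    if mode not in ("asserts", "quotes"):
        raise ValueError(f"mode must be 'asserts' or 'quotes', got {mode!r}")
    if rep.id in mp.phi:
        raise MicropubError(
            ViolationCode.KIND_VIOLATION,
            f"element {rep.id} already in Phi (dual membership forbidden)",
        )
    msg = _check_representation(rep)
    if msg is not None:
        raise MicropubError(ViolationCode.KIND_VIOLATION, msg)
    if mode == "asserts":
        mp.asserted[rep.id] = rep
    else:
        mp.quoted[rep.id] = rep
    return mp


def _would_cycle(pairs: Iterable[tuple[str, str]], new: tuple[str, str]) -> bool:
    """True if adding `new` to the supports pairs closes a cycle (DFS from target)."""
    adj: dict[str, set[str]] = {}
    for s, t in pairs:
        adj.setdefault(s, set()).add(t)
    src, tgt = new
    stack, seen = [tgt], set()
    while stack:
        node = stack.pop()
        if node == src:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(adj.get(node, ()))
    return False


def add_relation(
    mp: Micropublication, source: str, rel_kind: RelKind, target: str
) -> Micropublication:
    """Append a typed relation asserted by this micropublication.

    Supports edges are checked eagerly against the per-MP DAG constraint;
    graphs arriving through deserialization are checked lazily by
    :func:`validate` instead.
    """
    rel_kind = RelKind(rel_kind)
    if source == target:
        raise MicropubError(
            ViolationCode.SUPPORT_CYCLE, f"reflexive edge on {source} forbidden"
        )
    phi = mp.phi
    for endpoint in (source, target):
        if endpoint not in phi:
            raise MicropubError(
                ViolationCode.DANGLING_ENDPOINT, f"{endpoint} is not an element of Phi"
            )
    existing = {(r.source, r.target): r.rel_kind for r in mp.relations}
    if (source, target) in existing and existing[(source, target)] != rel_kind:
        raise MicropubError(
            ViolationCode.DUAL_EDGE,
            f"({source}, {target}) already carries {existing[(source, target)].value}",
        )
    if rel_kind == RelKind.SUPPORTS and source == mp.claim:
        raise MicropubError(
            ViolationCode.CLAIM_NOT_GREATEST,
            "the claim must be the greatest element of the supports order",
        )
    if rel_kind == RelKind.SUPPORTS and _would_cycle(
        mp.supports_pairs(), (source, target)
    ):
        raise MicropubError(
            ViolationCode.SUPPORT_CYCLE,
            f"supports({source}, {target}) would close a cycle",
        )
    rel = Relation(source=source, rel_kind=rel_kind, target=target, asserted_by=mp.id)
    if rel not in mp.relations:
        mp.relations.append(rel)
    return mp


def add_qualification(mp: Micropublication, statement: str, qualifier: str) -> Micropublication:
    """Record a qualifiedBy link; carries no inference semantics."""
    phi = mp.phi
    for endpoint in (statement, qualifier):
        if endpoint not in phi:
            raise MicropubError(
                ViolationCode.DANGLING_ENDPOINT, f"{endpoint} is not an element of Phi"
            )
    mp.qualifications.add((statement, qualifier))
    return mp


def elements_of(mp: Micropublication) -> set[Representation]:
    """Phi as a set of representations (asserted ∪ quoted)."""
    return set(mp.elements.values())


# ---------------------------------------------------------------------------
# validation


def _find_cycle(pairs: Iterable[tuple[str, str]]) -> Optional[list[str]]:
    """Depth-first search for a directed cycle; returns one cycle's nodes."""
    adj: dict[str, list[str]] = {}
    for s, t in pairs:
        adj.setdefault(s, []).append(t)
    WHITE, GREY, BLACK = 0, 1, 2
    color: dict[str, int] = {}
    parent: dict[str, str] = {}

    def visit(u: str) -> Optional[list[str]]:
        color[u] = GREY
        for v in adj.get(u, ()):  # noqa: B007
            c = color.get(v, WHITE)
            if c == GREY:
                cycle = [v, u]
                node = u
                while node != v and node in parent:
                    node = parent[node]
                    cycle.append(node)
                return cycle
            if c == WHITE:
                parent[v] = u
                found = visit(v)
                if found:
                    return found
        color[u] = BLACK
        return None

    for node in list(adj):
        if color.get(node, WHITE) == WHITE:
            found = visit(node)
            if found:
                return found
    return None


def _reaches(pairs: set[tuple[str, str]], start: str, goal: str) -> bool:
    adj: dict[str, set[str]] = {}
    for s, t in pairs:
        adj.setdefault(s, set()).add(t)
    stack, seen = [start], set()
    while stack:
        node = stack.pop()
        if node == goal:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(adj.get(node, ()))
    return False


def support_closure_elements(mp: Micropublication) -> set[str]:
    """Phi+ : the elements of Phi with a supports path to the claim."""
    if mp.claim is None:
        return set()
    pairs = mp.supports_pairs()
    return {e for e in mp.phi if e != mp.claim and _reaches(pairs, e, mp.claim)}


def validate(mp: Micropublication) -> ValidationReport:
    """Check every formal invariant; violations are report entries, not errors."""
    violations: list[Violation] = []
    phi = mp.phi

    if not phi:
        violations.append(
            Violation(ViolationCode.EMPTY_PHI, "Phi must be finite and non-empty")
        )
    dual = set(mp.asserted) & set(mp.quoted)
    if dual:
        violations.append(
            Violation(
                ViolationCode.KIND_VIOLATION,
                "elements both asserted and quoted",
                tuple(sorted(dual)),
            )
        )
    if mp.claim is None:
        violations.append(
            Violation(ViolationCode.NO_CLAIM, "micropublication argues no claim")
        )
    else:
        if mp.claim not in phi:
            violations.append(
                Violation(
                    ViolationCode.CLAIM_NOT_ELEMENT,
                    f"claim {mp.claim} is not an element of Phi",
                    (mp.claim,),
                )
            )
        else:
            claim_rep = mp.elements[mp.claim]
            if not is_a(claim_rep.rep_kind, RepKind.CLAIM):
                violations.append(
                    Violation(
                        ViolationCode.KIND_VIOLATION,
                        f"claim element has kind {claim_rep.rep_kind.value}",
                        (mp.claim,),
                    )
                )

    for rep in mp.elements.values():
        msg = _check_representation(rep)
        if msg is not None:
            violations.append(
                Violation(ViolationCode.KIND_VIOLATION, msg, (rep.id,))
            )

    for rel in mp.relations:
        for endpoint in (rel.source, rel.target):
            if endpoint not in phi:
                violations.append(
                    Violation(
                        ViolationCode.DANGLING_ENDPOINT,
                        f"relation endpoint {endpoint} not in Phi",
                        (endpoint,),
                    )
                )
    for stmt, qual in mp.qualifications:
        for endpoint in (stmt, qual):
            if endpoint not in phi:
                violations.append(
                    Violation(
                        ViolationCode.DANGLING_ENDPOINT,
                        f"qualification endpoint {endpoint} not in Phi",
                        (endpoint,),
                    )
                )

    kinds_by_pair: dict[tuple[str, str], set[RelKind]] = {}
    for rel in mp.relations:
        kinds_by_pair.setdefault(rel.pair, set()).add(rel.rel_kind)
    for pair, kinds in sorted(kinds_by_pair.items()):
        if len(kinds) > 1:
            violations.append(
                Violation(
                    ViolationCode.DUAL_EDGE,
                    f"({pair[0]}, {pair[1]}) carries both supports and directlyChallenges",
                    pair,
                )
            )

    pairs = mp.supports_pairs()
    reflexive = sorted(s for s, t in pairs if s == t)
    if reflexive:
        violations.append(
            Violation(
                ViolationCode.SUPPORT_CYCLE,
                "reflexive supports edge",
                tuple(reflexive),
            )
        )
    cycle = _find_cycle(pairs)
    if cycle and not reflexive:
        violations.append(
            Violation(
                ViolationCode.SUPPORT_CYCLE,
                "supports edges contain a directed cycle",
                tuple(cycle),
            )
        )

    if mp.claim is not None and mp.claim in phi and cycle is None:
        # c must be the greatest element of the supports order over Phi+.
        outgoing = sorted(t for s, t in pairs if s == mp.claim)
        if outgoing:
            violations.append(
                Violation(
                    ViolationCode.CLAIM_NOT_GREATEST,
                    f"claim supports {', '.join(outgoing)}; it must be maximal",
                    (mp.claim, *outgoing),
                )
            )
        has_attr_support = any(
            (a, mp.claim) in pairs
            and mp.elements.get(a) is not None
            and mp.elements[a].rep_kind == RepKind.ATTRIBUTION
            for a in phi
        )
        if not has_attr_support:
            violations.append(
                Violation(
                    ViolationCode.MISSING_CLAIM_ATTRIBUTION,
                    "minimal form requires supports(A_c, c) with A_c an attribution",
                    (mp.claim,),
                )
            )

    return ValidationReport(subject=mp.id, violations=tuple(violations))


__all__ = [
    "DEFAULT_BASE",
    "Agent",
    "AgentKind",
    "Attribution",
    "Media",
    "Micropublication",
    "MicropubError",
    "RepKind",
    "Relation",
    "RelKind",
    "Representation",
    "Role",
    "ValidationReport",
    "Violation",
    "ViolationCode",
    "add_element",
    "add_qualification",
    "add_relation",
    "elements_of",
    "is_a",
    "make_micropublication",
    "mint_iri",
    "sentence_family",
    "method_family",
    "support_closure_elements",
    "validate",
]
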