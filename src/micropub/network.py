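"""Cross-publication claim networks.

Merging micropublications yields a claim network in which every element
keeps exactly one asserting micropublication (localization of
responsibility) while any number of others may quote it.  On top of the
merged graph this module provides:

* reference resolution — turning a document-level citation into a
  claim-level supports edge, minted as a new annotation micropublication;
* claim lineages — chains of citing/cited claims across publications;
* empirical-grounding reports — does a claim's support ancestry reach
  data obtained by a reusable method, or is it citation distortion
  ("ultimately based on no evidence at all")?;
* challenged-claim listing via the challenge-inference rules;
* similarity groups — a representative (holotype) claim standing for a
  set of similogs, materialized as a micropublication.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .inference import infer_challenges, supports_closure
from .model import (
    Agent,
    Attribution,
    Micropublication,
    MicropubError,
    Relation,
    RelKind,
    RepKind,
    Representation,
    Role,
    ViolationCode,
    add_element,
    add_relation,
    is_a,
    mint_iri,
    validate,
)


class MergeConflictError(ValueError):
    """Two micropublications claim to originally assert the same element."""


@dataclass
class NodeEntry:
    representation: Representation
    asserted_by: Optional[str]  # None marks an external stub
    quoted_by: set[str] = field(default_factory=set)

    @property
    def is_stub(self) -> bool:
        return self.asserted_by is None


@dataclass
class PublicationEntry:
    label: str
    references: set[str] = field(default_factory=set)  # reference-rep IRIs resolving here


@dataclass
class ClaimNetwork:
    micropublications: dict[str, Micropublication] = field(default_factory=dict)
    nodes: dict[str, NodeEntry] = field(default_factory=dict)
    edges: list[Relation] = field(default_factory=list)
    publications: dict[str, PublicationEntry] = field(default_factory=dict)
    agents: dict[str, Agent] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    notices: list[str] = field(default_factory=list)
    base: str = "http://example.org/micropub"

    def claims(self) -> list[str]:
        return sorted(
            iri
            for iri, entry in self.nodes.items()
            if is_a(entry.representation.rep_kind, RepKind.CLAIM)
        )

    def supports_pairs(self) -> set[tuple[str, str]]:
        return {r.pair for r in self.edges if r.rel_kind == RelKind.SUPPORTS}

    def relations_asserted_by(self, mp_id: str) -> set[Relation]:
        return {r for r in self.edges if r.asserted_by == mp_id}


def _register_publication(net: ClaimNetwork, doc: str, label: str = "") -> PublicationEntry:
    entry = net.publications.get(doc)
    if entry is None:
        entry = PublicationEntry(label=label or doc)
        net.publications[doc] = entry
    elif label and entry.label == doc:
        entry.label = label
    return entry


def merge(mps: Iterable[Micropublication]) -> ClaimNetwork:
    """Merge individually valid micropublications into one network.

    Elements are deduplicated by IRI; each keeps its single asserting MP.
    Quoted IRIs that no MP in the batch asserts become stub nodes with a
    warning.  Two MPs asserting the same IRI is a conflict error.
    """
    mps = list(mps)
    net = ClaimNetwork()
    if mps:
        net.base = mps[0].id.rsplit("/", 1)[0]
    for mp in mps:
        report = validate(mp)
        if not report.is_valid:
            codes = ", ".join(v.code.value for v in report.violations)
            raise MicropubError(
                report.violations[0].code, f"cannot merge invalid {mp.id}: {codes}"
            )
        if mp.id in net.micropublications:
            raise MergeConflictError(f"duplicate micropublication id {mp.id}")
        net.micropublications[mp.id] = mp
        net.agents.update(mp.agents)
        for iri, rep in mp.asserted.items():
            existing = net.nodes.get(iri)
            if existing is not None and existing.asserted_by is not None:
                raise MergeConflictError(
                    f"{iri} asserted by both {existing.asserted_by} and {mp.id}"
                )
            if existing is None:
                net.nodes[iri] = NodeEntry(representation=rep, asserted_by=mp.id)
            else:  # was a stub or quoted-first; claim assertion provenance
                existing.representation = rep
                existing.asserted_by = mp.id
        for iri, rep in mp.quoted.items():
            entry = net.nodes.get(iri)
            if entry is None:
                entry = NodeEntry(representation=rep, asserted_by=None)
                net.nodes[iri] = entry
            entry.quoted_by.add(mp.id)
        for rel in mp.relations:
            if rel not in net.edges:
                net.edges.append(rel)
        if mp.source_document and not mp.annotation:
            _register_publication(net, mp.source_document)
        for rep in mp.elements.values():
            if rep.rep_kind == RepKind.REFERENCE and rep.target:
                _register_publication(net, rep.target).references.add(rep.id)
    for iri, entry in sorted(net.nodes.items()):
        if entry.is_stub:
            net.warnings.append(
                f"quoted element {iri} has no asserting micropublication; kept as stub"
            )
    return net


# ---------------------------------------------------------------------------
# reference resolution


def resolve_reference(
    net: ClaimNetwork,
    citing_statement: str,
    cited_claim: str,
    attribution: Attribution,
    *,
    into: Optional[str] = None,
) -> ClaimNetwork:
    """Resolve a document-level citation to a claim-level supports edge.

    Mints (or extends, via ``into``) an annotation micropublication that
    quotes both endpoints and asserts supports(cited_claim,
    citing_statement).  Idempotent per (citing, cited) pair.  The original
    document-level reference nodes are retained and linked by supports to
    the cited document's stub when that document is known.
    """
    for iri in (citing_statement, cited_claim):
        if iri not in net.nodes:
            raise KeyError(f"{iri} is not a node of the network")
    cited_rep = net.nodes[cited_claim].representation
    if not is_a(cited_rep.rep_kind, RepKind.CLAIM):
        raise MicropubError(
            ViolationCode.KIND_VIOLATION,
            f"cited element {cited_claim} has kind {cited_rep.rep_kind.value}; must be a claim",
        )
    wanted = (cited_claim, citing_statement)
    if wanted in net.supports_pairs():
        net.notices.append(
            f"supports({cited_claim}, {citing_statement}) already asserted; no-op"
        )
        return net

    if into is not None and into in net.micropublications:
        res = net.micropublications[into]
    else:
        local = into.rsplit("/", 1)[-1] if into else f"resolution-{len(net.micropublications) + 1}"
        mp_iri = into or mint_iri(net.base, local)
        claim_iri = mint_iri(net.base, local, "claim")
        claim_text = (
            "Resolution of document-level citations to claim-level support "
            f"for statements of {citing_statement.rsplit('/', 1)[-1].split('#')[0]}"
        )
        a_c = Attribution(
            id=mint_iri(net.base, local, "attr-claim"),
            agent=attribution.agent,
            role=attribution.role or Role.CURATOR,
            timestamp=attribution.timestamp,
        )
        res = Micropublication(id=mp_iri, attribution=attribution, claim=claim_iri,
                               annotation=True)
        add_element(res, Representation(id=claim_iri, rep_kind=RepKind.CLAIM, text=claim_text))
        add_element(res, Representation(id=a_c.id, rep_kind=RepKind.ATTRIBUTION, attribution=a_c))
        add_relation(res, a_c.id, RelKind.SUPPORTS, claim_iri)
        net.micropublications[res.id] = res
        for iri, rep in res.asserted.items():
            net.nodes[iri] = NodeEntry(representation=rep, asserted_by=res.id)
        for rel in res.relations:
            net.edges.append(rel)

    for iri in (citing_statement, cited_claim):
        if iri not in res.phi:
            add_element(res, net.nodes[iri].representation, mode="quotes")
            net.nodes[iri].quoted_by.add(res.id)
    add_relation(res, cited_claim, RelKind.SUPPORTS, citing_statement)
    new_edge = Relation(cited_claim, RelKind.SUPPORTS, citing_statement, res.id)
    if new_edge not in net.edges:
        net.edges.append(new_edge)

    # Retain the document-level reference: link references backing the citing
    # statement to the cited document's stub, when the cited MP names one.
    cited_mp_id = net.nodes[cited_claim].asserted_by
    cited_mp = net.micropublications.get(cited_mp_id) if cited_mp_id else None
    cited_doc = cited_mp.source_document if cited_mp else None
    if cited_doc:
        _register_publication(net, cited_doc)
        for s, t in sorted(net.supports_pairs()):
            if t == citing_statement and s in net.nodes:
                ref = net.nodes[s].representation
                if ref.rep_kind != RepKind.REFERENCE:
                    continue
                if ref.target and ref.target != cited_doc:
                    continue  # a document-level reference to some other work
                if (ref.id, cited_doc) in net.supports_pairs():
                    continue
                if cited_doc not in net.nodes:
                    net.nodes[cited_doc] = NodeEntry(
                        representation=Representation(
                            id=cited_doc, rep_kind=RepKind.ARTICLE_TEXT
                        ),
                        asserted_by=None,
                    )
                for iri in (ref.id, cited_doc):
                    if iri not in res.phi:
                        add_element(res, net.nodes[iri].representation, mode="quotes")
                        net.nodes[iri].quoted_by.add(res.id)
                add_relation(res, ref.id, RelKind.SUPPORTS, cited_doc)
                net.edges.append(Relation(ref.id, RelKind.SUPPORTS, cited_doc, res.id))
    return net


# ---------------------------------------------------------------------------
# lineages


@dataclass(frozen=True)
class LineageLink:
    citing_statement: str
    reference: Optional[str]
    cited_claim: str
    via_mp: str


@dataclass
class Lineage:
    root: str
    links: list[LineageLink]
    terminal_nodes: set[str]
    cycles: list[list[str]]

    def as_dict(self) -> dict:
        return {
            "root": self.root,
            "links": [
                {
                    "citing_statement": l.citing_statement,
                    "reference": l.reference,
                    "cited_claim": l.cited_claim,
                    "via_mp": l.via_mp,
                }
                for l in self.links
            ],
            "terminal_nodes": sorted(self.terminal_nodes),
            "cycles": self.cycles,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)

    def to_dot(self) -> str:
        """Graphviz DOT rendering of the claim-to-claim chain."""
        lines = ["digraph lineage {", "  rankdir=BT;"]
        seen = set()

        def short(iri: str) -> str:
            return iri.rsplit("#", 1)[-1].rsplit("/", 1)[-1]

        def node(iri: str) -> str:
            label = short(iri)
            if iri not in seen:
                seen.add(iri)
                lines.append(f'  "{label}";')
            return label

        node(self.root)
        for link in self.links:
            cited = node(link.cited_claim)
            citing = node(link.citing_statement)
            via = short(link.via_mp)
            lines.append(f'  "{cited}" -> "{citing}" [label="{via}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def claim_lineage(net: ClaimNetwork, claim: str) -> Lineage:
    """Chains of citing/cited claims below `claim`, cycle-safe.

    Descends the supports edges depth-first from the claim; every hop
    whose supporter is itself a claim is recorded as a lineage link, with
    the asserting (usually resolution) micropublication as provenance and
    the document-level reference backing the citing statement, if any.
    """
    if claim not in net.nodes:
        raise KeyError(f"{claim} is not a node of the network")
    incoming: dict[str, list[Relation]] = {}
    for rel in net.edges:
        if rel.rel_kind == RelKind.SUPPORTS:
            incoming.setdefault(rel.target, []).append(rel)

    def reference_for(statement: str) -> Optional[str]:
        for rel in incoming.get(statement, []):
            rep = net.nodes.get(rel.source)
            if rep and rep.representation.rep_kind == RepKind.REFERENCE:
                return rel.source
        return None

    links: list[LineageLink] = []
    terminal: set[str] = set()
    cycles: list[list[str]] = []
    visited: set[str] = set()
    stack_path: list[str] = []

    def visit(node: str) -> None:
        if node in stack_path:
            cycles.append(stack_path[stack_path.index(node):] + [node])
            return
        if node in visited:
            return
        visited.add(node)
        stack_path.append(node)
        supporters = sorted(incoming.get(node, []), key=lambda r: r.source)
        if not supporters:
            terminal.add(node)
        for rel in supporters:
            src_entry = net.nodes.get(rel.source)
            if src_entry and is_a(src_entry.representation.rep_kind, RepKind.CLAIM):
                links.append(
                    LineageLink(
                        citing_statement=rel.target,
                        reference=reference_for(rel.target),
                        cited_claim=rel.source,
                        via_mp=rel.asserted_by,
                    )
                )
            visit(rel.source)
        stack_path.pop()

    visit(claim)
    return Lineage(root=claim, links=links, terminal_nodes=terminal, cycles=cycles)


# ---------------------------------------------------------------------------
# grounding


@dataclass(frozen=True)
class DistortionFlag:
    code: str  # NO_EVIDENCE_AT_ROOT | UNRESOLVED_REFERENCE | SELF_CITATION_CHAIN
    detail: str


@dataclass
class GroundingReport:
    claim: str
    grounded_by_data: bool
    grounded_by_method: bool
    evidence_paths: list[list[str]]
    ungrounded_leaves: set[str]
    distortion_flags: list[DistortionFlag]

    def as_dict(self) -> dict:
        return {
            "claim": self.claim,
            "grounded_by_data": self.grounded_by_data,
            "grounded_by_method": self.grounded_by_method,
            "evidence_paths": self.evidence_paths,
            "ungrounded_leaves": sorted(self.ungrounded_leaves),
            "distortion_flags": [
                {"code": f.code, "detail": f.detail} for f in self.distortion_flags
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)


def _shortest_path(
    pairs: set[tuple[str, str]], start: str, goal: str
) -> Optional[list[str]]:
    adj: dict[str, set[str]] = {}
    for s, t in pairs:
        adj.setdefault(s, set()).add(t)
    frontier = [[start]]
    seen = {start}
    while frontier:
        path = frontier.pop(0)
        if path[-1] == goal:
            return path
        for nxt in sorted(adj.get(path[-1], ())):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(path + [nxt])
    return None


def grounding_report(
    net: ClaimNetwork,
    claim: str,
    require_method: bool = True,
    *,
    self_citation_check: bool = False,
) -> GroundingReport:
    """Trace a claim's support ancestry to empirical data and methods.

    A claim is grounded by data iff some data node has a supports path to
    it; grounded by method iff every such data node in the ancestry is
    itself supported by a method (procedure or material).  Claims whose
    lineage reaches no data at all — the citation-distortion pattern —
    are flagged NO_EVIDENCE_AT_ROOT.
    """
    if claim not in net.nodes:
        raise KeyError(f"{claim} is not a node of the network")
    closure = supports_closure(net.edges).closed
    pairs = net.supports_pairs()
    ancestry = {s for s, t in closure if t == claim}

    def kind(iri: str) -> Optional[RepKind]:
        entry = net.nodes.get(iri)
        return entry.representation.rep_kind if entry else None

    data_nodes = sorted(n for n in ancestry if kind(n) == RepKind.DATA)
    evidence_paths = []
    for d in data_nodes:
        path = _shortest_path(pairs, d, claim)
        if path:
            evidence_paths.append(path)
    grounded_by_data = bool(evidence_paths)
    if require_method:
        grounded_by_method = grounded_by_data and all(
            any(
                (m, d) in closure and kind(m) is not None and is_a(kind(m), RepKind.METHOD)
                for m in ancestry
            )
            for d in data_nodes
        )
    else:
        grounded_by_method = grounded_by_data

    sources_with_support = {t for _, t in pairs}
    ungrounded_leaves = {
        n
        for n in ancestry
        if n not in sources_with_support
        and kind(n) is not None
        and (is_a(kind(n), RepKind.STATEMENT) or kind(n) == RepKind.REFERENCE)
    }

    flags: list[DistortionFlag] = []
    if not grounded_by_data:
        flags.append(
            DistortionFlag(
                "NO_EVIDENCE_AT_ROOT",
                f"no data node in the support ancestry of {claim}",
            )
        )
    for n in sorted(ancestry):
        if kind(n) == RepKind.REFERENCE:
            cited_statements = {
                t
                for s, t in pairs
                if s == n and kind(t) is not None and is_a(kind(t), RepKind.STATEMENT)
            }
            for stmt in sorted(cited_statements):
                has_claim_backing = any(
                    s
                    for s, t in pairs
                    if t == stmt and kind(s) is not None and is_a(kind(s), RepKind.CLAIM)
                )
                if not has_claim_backing:
                    flags.append(
                        DistortionFlag(
                            "UNRESOLVED_REFERENCE",
                            f"reference {n} backs {stmt} at document level only",
                        )
                    )
    if self_citation_check:
        lineage = claim_lineage(net, claim)

        def agent_of(mp_id: Optional[str]) -> Optional[str]:
            mp = net.micropublications.get(mp_id) if mp_id else None
            return mp.attribution.agent if mp else None

        chain_agents = [
            agent_of(net.nodes[l.cited_claim].asserted_by) for l in lineage.links
        ]
        for i in range(len(chain_agents) - 1):
            a, b = chain_agents[i], chain_agents[i + 1]
            if a is not None and a == b:
                flags.append(
                    DistortionFlag(
                        "SELF_CITATION_CHAIN",
                        f"consecutive lineage hops attributed to agent {a}",
                    )
                )
                break
    return GroundingReport(
        claim=claim,
        grounded_by_data=grounded_by_data,
        grounded_by_method=grounded_by_method,
        evidence_paths=evidence_paths,
        ungrounded_leaves=ungrounded_leaves,
        distortion_flags=flags,
    )


# ---------------------------------------------------------------------------
# challenges


def challenged_claims(net: ClaimNetwork, mode: str = "transitive") -> list[dict]:
    """Every claim-kind node with at least one inferred challenger.

    Each record labels the derivation: `direct` when a directlyChallenges
    edge targets the claim itself, `undercut` when the challenge is
    inferred from an attack on a supporter.
    """
    inferred = infer_challenges(net.edges, mode=mode)
    direct_pairs = {
        r.pair for r in net.edges if r.rel_kind == RelKind.DIRECTLY_CHALLENGES
    }
    out: list[dict] = []
    for claim in net.claims():
        challengers = {x for x, y in inferred if y == claim}
        if not challengers:
            continue
        direct = {x for x in challengers if (x, claim) in direct_pairs}
        undercut = challengers - direct
        if direct:
            out.append({"claim": claim, "challengers": direct, "via": "direct"})
        if undercut:
            out.append({"claim": claim, "challengers": undercut, "via": "undercut"})
    return out


# ---------------------------------------------------------------------------
# similarity groups


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def token_set_jaccard(a: str, b: str) -> float:
    """Default similog comparator: Jaccard index of lower-cased token sets.

    Symmetric, range [0, 1], self-score 1.0 on any non-empty text.
    """
    ta = set(_TOKEN_RE.findall(a.lower()))
    tb = set(_TOKEN_RE.findall(b.lower()))
    if not ta and not tb:
        return 1.0 if a == b else 0.0
    union = ta | tb
    if not union:
        return 0.0
    return len(ta & tb) / len(union)


@dataclass
class SimilarityGroup:
    holotype: str
    members: set[str]
    scores: dict[str, float]
    threshold: float
    as_micropublication: Micropublication
    attribution: Attribution
    rejected: dict[str, float] = field(default_factory=dict)


def _claim_text(net: ClaimNetwork, iri: str) -> str:
    entry = net.nodes.get(iri)
    if entry is None:
        raise KeyError(f"{iri} is not a node of the network")
    rep = entry.representation
    if not is_a(rep.rep_kind, RepKind.CLAIM):
        raise MicropubError(
            ViolationCode.KIND_VIOLATION,
            f"{iri} has kind {rep.rep_kind.value}; similarity groups hold claims only",
        )
    return rep.text or ""


def build_similarity_group(
    net: ClaimNetwork,
    holotype: str,
    members: Iterable[str],
    attribution: Attribution,
    comparator: Callable[[str, str], float] = token_set_jaccard,
    threshold: float = 0.5,
    *,
    group_id: Optional[str] = None,
) -> SimilarityGroup:
    """Materialize a similarity group as a micropublication.

    The holotype is the group's claim; every accepted member (score vs
    the holotype >= threshold, star topology) is quoted and supports the
    holotype.  Members failing the threshold are rejected with their
    scores reported.  Explicit curator membership — e.g. translations —
    is expressed by passing threshold 0.
    """
    members = set(members)
    if holotype in members:
        raise MicropubError(
            ViolationCode.KIND_VIOLATION, "holotype must not be listed among members"
        )
    holo_text = _claim_text(net, holotype)
    scores: dict[str, float] = {}
    rejected: dict[str, float] = {}
    accepted: set[str] = set()
    for m in sorted(members):
        score = comparator(holo_text, _claim_text(net, m))
        scores[m] = score
        if score >= threshold:
            accepted.add(m)
        else:
            rejected[m] = score

    local = group_id or f"similarity-group-{holotype.rsplit('/', 1)[-1].replace('#', '-')}"
    mp_iri = mint_iri(net.base, local)
    # the curator's attribution doubles as the holotype claim's attribution
    # element, so the judgement "these are similogs" is itself attributed
    a_h = attribution
    group_mp = Micropublication(
        id=mp_iri, attribution=attribution, claim=holotype, annotation=True
    )
    add_element(group_mp, net.nodes[holotype].representation, mode="quotes")
    add_element(
        group_mp,
        Representation(id=a_h.id, rep_kind=RepKind.ATTRIBUTION, attribution=a_h),
    )
    add_relation(group_mp, a_h.id, RelKind.SUPPORTS, holotype)
    for m in sorted(accepted):
        add_element(group_mp, net.nodes[m].representation, mode="quotes")
        add_relation(group_mp, m, RelKind.SUPPORTS, holotype)
    return SimilarityGroup(
        holotype=holotype,
        members=accepted,
        scores=scores,
        threshold=threshold,
        as_micropublication=group_mp,
        attribution=attribution,
        rejected=rejected,
    )


def suggest_similogs(
    net: ClaimNetwork,
    claim: str,
    comparator: Callable[[str, str], float] = token_set_jaccard,
    threshold: float = 0.5,
) -> list[tuple[str, float]]:
    """Score every other claim in the network against `claim`.

    Returns (iri, score) pairs with score >= threshold, sorted by
    descending score; ties break on IRI lexicographic order.
    """
    text = _claim_text(net, claim)
    scored = []
    for other in net.claims():
        if other == claim:
            continue
        score = comparator(text, _claim_text(net, other))
        if score >= threshold:
            scored.append((other, score))
    return sorted(scored, key=lambda item: (-item[1], item[0]))


__all__ = [
    "ClaimNetwork",
    "DistortionFlag",
    "GroundingReport",
    "Lineage",
    "LineageLink",
    "MergeConflictError",
    "NodeEntry",
    "PublicationEntry",
    "SimilarityGroup",
    "build_similarity_group",
    "challenged_claims",
    "claim_lineage",
    "grounding_report",
    "merge",
    "resolve_reference",
    "suggest_similogs",
    "token_set_jaccard",
]
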