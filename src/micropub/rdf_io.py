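"""RDF serialization of micropublications and claim networks.

The vocabulary lives in the mp namespace (http://purl.org/mp#); class and
property spellings follow the model's camel-case names (Micropublication,
Claim, Statement, Data, Procedure, Material, Attribution; argues,
supports, directlyChallenges, qualifiedBy, asserts, quotes,
attributionOfAgent, hasSupportGraphElement, hasChallengeGraphElement).
Any respelling against the published vocabulary file is confined to the
single TERMS table below.

Provenance is expressed with flat asserts/quotes property triples, not
named graphs.  Every relation is additionally reified as a deterministic
content-addressed rdf:Statement node carrying assertedBy, so that merged
networks round-trip losslessly and challenge edges quoted by another
micropublication can themselves be elements of Phi.  No blank nodes are
emitted anywhere, and output triples are sorted by subject, predicate,
object — identical input gives byte-identical output.

Text anchoring follows the Open Annotation model: an exact-quote selector
with a fixed-width prefix/suffix context window.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import XSD

from . import inference
from .model import (
    Agent,
    AgentKind,
    Attribution,
    Media,
    Micropublication,
    MicropubError,
    RelKind,
    Relation,
    RepKind,
    Representation,
    Role,
    validate,
)
from .network import ClaimNetwork, merge

MP = Namespace("http://purl.org/mp#")
OA = Namespace("http://www.w3.org/ns/oa#")

# Single point of correction against the published vocabulary file.
TERMS = {
    "Micropublication": MP.Micropublication,
    "argues": MP.argues,
    "asserts": MP.asserts,
    "quotes": MP.quotes,
    "supports": MP.supports,
    "directlyChallenges": MP.directlyChallenges,
    "qualifiedBy": MP.qualifiedBy,
    "attributionOfAgent": MP.attributionOfAgent,
    "hasAttribution": MP.hasAttribution,
    "hasSupportGraphElement": MP.hasSupportGraphElement,
    "hasChallengeGraphElement": MP.hasChallengeGraphElement,
    "assertedBy": MP.assertedBy,
    "sourceDocument": MP.sourceDocument,
    "role": MP.role,
    "attributedAt": MP.attributedAt,
    "refersTo": MP.refersTo,
    "hasTerm": MP.hasTerm,
    "mediaType": MP.mediaType,
    "locator": MP.locator,
}

_KIND_CLASS = {
    RepKind.SENTENCE: MP.Sentence,
    RepKind.STATEMENT: MP.Statement,
    RepKind.CLAIM: MP.Claim,
    RepKind.QUALIFIER: MP.Qualifier,
    RepKind.REFERENCE: MP.Reference,
    RepKind.SEMANTIC_QUALIFIER: MP.SemanticQualifier,
    RepKind.DATA: MP.Data,
    RepKind.PROCEDURE: MP.Procedure,
    RepKind.MATERIAL: MP.Material,
    RepKind.ARTICLE_TEXT: MP.ArticleText,
    RepKind.ATTRIBUTION: MP.Attribution,
}
_CLASS_KIND = {v: k for k, v in _KIND_CLASS.items()}

_AGENT_CLASS = {
    AgentKind.PERSON: MP.Person,
    AgentKind.ORGANIZATION: MP.Organization,
}
_CLASS_AGENT = {v: k for k, v in _AGENT_CLASS.items()}

_REL_PRED = {
    RelKind.SUPPORTS: MP.supports,
    RelKind.DIRECTLY_CHALLENGES: MP.directlyChallenges,
}
_PRED_REL = {v: k for k, v in _REL_PRED.items()}

_PREFIXES = {
    "mp": str(MP),
    "oa": str(OA),
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "xsd": str(XSD),
}


@dataclass(frozen=True)
class RdfDocument:
    syntax: str  # "turtle" | "jsonld"
    content: str
    base_namespace: str


@dataclass(frozen=True)
class TextAnchor:
    """Open-Annotation exact-quote anchor for a representation."""

    annotated: str
    source_document: str
    exact: str
    prefix: str = ""
    suffix: str = ""
    attribution: Optional[Attribution] = None
    verified: Optional[bool] = None  # None: no document text supplied


def anchor(
    rep: str,
    document: str,
    exact: str,
    context_window: int = 32,
    *,
    document_text: Optional[str] = None,
    attribution: Optional[Attribution] = None,
) -> TextAnchor:
    """Anchor a representation to a verbatim text span of a document.

    When ``document_text`` is supplied the quote is searched for and the
    prefix/suffix context of ``context_window`` characters is captured;
    a quote absent from the document yields ``verified=False`` rather
    than an error.
    """
    if not exact:
        raise ValueError("anchor requires non-empty exact text")
    prefix = suffix = ""
    verified: Optional[bool] = None
    if document_text is not None:
        pos = document_text.find(exact)
        if pos < 0:
            verified = False
        else:
            verified = True
            prefix = document_text[max(0, pos - context_window):pos]
            suffix = document_text[pos + len(exact): pos + len(exact) + context_window]
    return TextAnchor(
        annotated=rep,
        source_document=document,
        exact=exact,
        prefix=prefix,
        suffix=suffix,
        attribution=attribution,
        verified=verified,
    )


# ---------------------------------------------------------------------------
# emission


def _edge_iri(base: str, rel: Relation) -> URIRef:
    key = f"{rel.source}|{rel.rel_kind.value}|{rel.target}|{rel.asserted_by}"
    digest = hashlib.sha1(key.encode("utf-8")).hexdigest()[:12]
    return URIRef(f"{base}/edge#{digest}")


def _emit_representation(g: Graph, rep: Representation) -> None:
    node = URIRef(rep.id)
    g.add((node, RDF.type, _KIND_CLASS[rep.rep_kind]))
    if rep.text is not None:
        g.add((node, RDF.value, Literal(rep.text)))
    if rep.target is not None:
        g.add((node, TERMS["refersTo"], Literal(rep.target)))
    if rep.term is not None:
        g.add((node, TERMS["hasTerm"], URIRef(rep.term)))
    if rep.media is not None:
        g.add((node, TERMS["mediaType"], Literal(rep.media.media_type)))
        g.add((node, TERMS["locator"], Literal(rep.media.locator)))
    if rep.attribution is not None:
        _emit_attribution(g, node, rep.attribution, typed=False)


def _emit_attribution(
    g: Graph, node: URIRef, attr: Attribution, *, typed: bool = True
) -> None:
    if typed:
        g.add((node, RDF.type, MP.Attribution))
    g.add((node, TERMS["attributionOfAgent"], URIRef(attr.agent)))
    if attr.role is not None:
        g.add((node, TERMS["role"], Literal(attr.role.value)))
    if attr.timestamp is not None:
        g.add((node, TERMS["attributedAt"], Literal(attr.timestamp, datatype=XSD.dateTime)))


def _emit_agent(g: Graph, agent: Agent) -> None:
    node = URIRef(agent.id)
    g.add((node, RDF.type, _AGENT_CLASS[agent.agent_kind]))
    g.add((node, RDFS.label, Literal(agent.name)))


def _emit_mp(g: Graph, mp: Micropublication, base: str, materialize_views: bool) -> None:
    node = URIRef(mp.id)
    g.add((node, RDF.type, MP.Micropublication))
    if mp.claim is not None:
        g.add((node, TERMS["argues"], URIRef(mp.claim)))
    attr_node = URIRef(mp.attribution.id)
    g.add((node, TERMS["hasAttribution"], attr_node))
    _emit_attribution(g, attr_node, mp.attribution)
    if mp.source_document is not None:
        g.add((node, TERMS["sourceDocument"], URIRef(mp.source_document)))
    for iri, rep in mp.asserted.items():
        g.add((node, TERMS["asserts"], URIRef(iri)))
        _emit_representation(g, rep)
    for iri, rep in mp.quoted.items():
        g.add((node, TERMS["quotes"], URIRef(iri)))
        _emit_representation(g, rep)
    for agent in mp.agents.values():
        _emit_agent(g, agent)
    for stmt, qual in mp.qualifications:
        g.add((URIRef(stmt), TERMS["qualifiedBy"], URIRef(qual)))
    for rel in mp.relations:
        g.add((URIRef(rel.source), _REL_PRED[rel.rel_kind], URIRef(rel.target)))
        edge = _edge_iri(base, rel)
        g.add((edge, RDF.type, RDF.Statement))
        g.add((edge, RDF.subject, URIRef(rel.source)))
        g.add((edge, RDF.predicate, _REL_PRED[rel.rel_kind]))
        g.add((edge, RDF.object, URIRef(rel.target)))
        g.add((edge, TERMS["assertedBy"], URIRef(rel.asserted_by)))
    for s, p, o in mp.extra_triples:
        g.add((URIRef(s), URIRef(p), _parse_object(o)))
    if materialize_views:
        for view_fn, prop in (
            (inference.support_graph, TERMS["hasSupportGraphElement"]),
            (inference.challenge_graph, TERMS["hasChallengeGraphElement"]),
        ):
            for member in view_fn(mp).nodes:
                g.add((node, prop, URIRef(member)))


def _parse_object(o: str):
    if o.startswith('"'):
        return Literal(json.loads(o))
    return URIRef(o)


def _emit_anchor(g: Graph, a: TextAnchor, base: str) -> None:
    key = f"{a.annotated}|{a.source_document}|{a.exact}"
    ann = URIRef(f"{base}/annotation#{hashlib.sha1(key.encode()).hexdigest()[:12]}")
    target = URIRef(str(ann) + "-target")
    selector = URIRef(str(ann) + "-selector")
    g.add((ann, RDF.type, OA.Annotation))
    g.add((ann, OA.hasBody, URIRef(a.annotated)))
    g.add((ann, OA.hasTarget, target))
    g.add((target, OA.hasSource, URIRef(a.source_document)))
    g.add((target, OA.hasSelector, selector))
    g.add((selector, RDF.type, OA.TextQuoteSelector))
    g.add((selector, OA.exact, Literal(a.exact)))
    if a.prefix:
        g.add((selector, OA.prefix, Literal(a.prefix)))
    if a.suffix:
        g.add((selector, OA.suffix, Literal(a.suffix)))
    if a.attribution is not None:
        attr_node = URIRef(a.attribution.id)
        g.add((ann, TERMS["hasAttribution"], attr_node))
        _emit_attribution(g, attr_node, a.attribution)


def _qname(term, prefixes: dict[str, str]) -> str:
    s = str(term)
    for prefix, ns in prefixes.items():
        if s.startswith(ns):
            local = s[len(ns):]
            if local and all(c.isalnum() or c in "_-." for c in local):
                return f"{prefix}:{local}"
    return f"<{s}>"


def _canonical_turtle(g: Graph) -> str:
    lines = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(_PREFIXES.items())]
    lines.append("")
    triples = sorted(
        (
            _qname(s, _PREFIXES) if isinstance(s, URIRef) else s.n3(),
            _qname(p, _PREFIXES),
            _qname(o, _PREFIXES) if isinstance(o, URIRef) else o.n3(),
        )
        for s, p, o in g
    )
    lines.extend(f"{s} {p} {o} ." for s, p, o in triples)
    return "\n".join(lines) + "\n"


def _canonical_jsonld(g: Graph) -> str:
    # Expanded JSON-LD, one object per subject, keys and subjects sorted.
    by_subject: dict[str, dict] = {}
    for s, p, o in g:
        subj = by_subject.setdefault(str(s), {"@id": str(s)})
        pred = str(p)
        if pred == str(RDF.type):
            subj.setdefault("@type", []).append(str(o))
            continue
        if isinstance(o, Literal):
            value: dict = {"@value": str(o)}
            if o.datatype is not None:
                value["@type"] = str(o.datatype)
        else:
            value = {"@id": str(o)}
        subj.setdefault(pred, []).append(value)
    doc = []
    for subj in sorted(by_subject):
        obj = by_subject[subj]
        for key, vals in obj.items():
            if isinstance(vals, list):
                obj[key] = sorted(vals, key=json.dumps)
        doc.append({k: obj[k] for k in sorted(obj)})
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def to_rdf(
    subject: Union[Micropublication, ClaimNetwork],
    syntax: str = "turtle",
    materialize_views: bool = False,
    *,
    anchors: Iterable[TextAnchor] = (),
) -> RdfDocument:
    """Serialize a micropublication or claim network, deterministically.

    Output triples are sorted by subject, predicate, object; identical
    input yields byte-identical output.  ``materialize_views`` adds the
    hasSupportGraphElement / hasChallengeGraphElement triples computed by
    the inference module (the views remain query-derived on load).
    """
    if syntax not in ("turtle", "jsonld"):
        raise ValueError(f"syntax must be 'turtle' or 'jsonld', got {syntax!r}")
    if isinstance(subject, Micropublication):
        mps = [subject]
        base = subject.id.rsplit("/", 1)[0]
        stubs: list[Representation] = []
    else:
        mps = [subject.micropublications[k] for k in sorted(subject.micropublications)]
        base = subject.base
        stubs = [
            entry.representation
            for iri, entry in sorted(subject.nodes.items())
            if entry.is_stub and not any(iri in mp.phi for mp in mps)
        ]
    for mp in mps:
        report = validate(mp)
        if not report.is_valid:
            codes = ", ".join(v.code.value for v in report.violations)
            raise MicropubError(
                report.violations[0].code,
                f"refusing to serialize invalid {mp.id}: {codes}",
            )
    g = Graph()
    for mp in mps:
        _emit_mp(g, mp, base, materialize_views)
    for rep in stubs:
        _emit_representation(g, rep)
    for a in anchors:
        _emit_anchor(g, a, base)
    content = _canonical_turtle(g) if syntax == "turtle" else _canonical_jsonld(g)
    return RdfDocument(syntax=syntax, content=content, base_namespace=base)


# ---------------------------------------------------------------------------
# parsing


_KNOWN_NAMESPACES = tuple(_PREFIXES.values())

_VIEW_PREDICATES = {TERMS["hasSupportGraphElement"], TERMS["hasChallengeGraphElement"]}


def _load_graph(doc: Union[RdfDocument, str], syntax: str = "turtle") -> Graph:
    g = Graph()
    if isinstance(doc, RdfDocument):
        data, fmt = doc.content, doc.syntax
    else:
        data, fmt = doc, syntax
    g.parse(data=data, format="json-ld" if fmt == "jsonld" else "turtle")
    return g


def from_rdf(doc: Union[RdfDocument, str], syntax: str = "turtle") -> list[Micropublication]:
    """Reconstruct model objects from an RDF document.

    Materialized view triples are ignored (views are query-derived);
    triples in unknown namespaces whose subject is an element of some
    micropublication are preserved in that object's opaque side-store
    and re-emitted on serialization.
    """
    g = _load_graph(doc, syntax)

    reps: dict[str, Representation] = {}
    attributions: dict[str, Attribution] = {}
    for node in set(g.subjects(RDF.type, None)):
        types = set(g.objects(node, RDF.type))
        kinds = [_CLASS_KIND[t] for t in types if t in _CLASS_KIND]
        if not kinds:
            continue
        kind = kinds[0]
        text = g.value(node, RDF.value)
        target = g.value(node, TERMS["refersTo"])
        term = g.value(node, TERMS["hasTerm"])
        media = None
        mt, loc = g.value(node, TERMS["mediaType"]), g.value(node, TERMS["locator"])
        if mt is not None and loc is not None:
            media = Media(media_type=str(mt), locator=str(loc))
        attr = None
        agent_iri = g.value(node, TERMS["attributionOfAgent"])
        if agent_iri is not None:
            role = g.value(node, TERMS["role"])
            ts = g.value(node, TERMS["attributedAt"])
            attr = Attribution(
                id=str(node),
                agent=str(agent_iri),
                role=Role(str(role)) if role is not None else None,
                timestamp=str(ts) if ts is not None else None,
            )
            attributions[str(node)] = attr
        reps[str(node)] = Representation(
            id=str(node),
            rep_kind=kind,
            text=str(text) if text is not None else None,
            media=media,
            target=str(target) if target is not None else None,
            term=str(term) if term is not None else None,
            attribution=attr if kind == RepKind.ATTRIBUTION else None,
        )

    agents: dict[str, Agent] = {}
    for cls, akind in _CLASS_AGENT.items():
        for node in g.subjects(RDF.type, cls):
            name = g.value(node, RDFS.label)
            agents[str(node)] = Agent(
                id=str(node), name=str(name) if name else str(node), agent_kind=akind
            )

    # relations: reified statements are authoritative for provenance
    reified: dict[tuple[str, RelKind, str], str] = {}
    for stmt in g.subjects(RDF.type, RDF.Statement):
        s = g.value(stmt, RDF.subject)
        p = g.value(stmt, RDF.predicate)
        o = g.value(stmt, RDF.object)
        by = g.value(stmt, TERMS["assertedBy"])
        if s is None or p is None or o is None or p not in _PRED_REL:
            continue
        if by is not None:
            reified[(str(s), _PRED_REL[p], str(o))] = str(by)

    flat: list[tuple[str, RelKind, str]] = []
    for pred, rk in _PRED_REL.items():
        for s, o in g.subject_objects(pred):
            if isinstance(s, URIRef):
                flat.append((str(s), rk, str(o)))

    qualifications = [
        (str(s), str(o)) for s, o in g.subject_objects(TERMS["qualifiedBy"])
    ]

    mps: list[Micropublication] = []
    mp_nodes = sorted(str(n) for n in g.subjects(RDF.type, MP.Micropublication))
    asserted_in: dict[str, str] = {}
    for mp_iri in mp_nodes:
        node = URIRef(mp_iri)
        attr_node = g.value(node, TERMS["hasAttribution"])
        if attr_node is not None and str(attr_node) in attributions:
            mp_attr = attributions[str(attr_node)]
        elif attr_node is not None:
            agent_iri = g.value(attr_node, TERMS["attributionOfAgent"])
            mp_attr = Attribution(id=str(attr_node), agent=str(agent_iri or ""))
        else:
            mp_attr = Attribution(id=mp_iri + "#attr", agent="")
        claim = g.value(node, TERMS["argues"])
        source_doc = g.value(node, TERMS["sourceDocument"])
        mp = Micropublication(
            id=mp_iri,
            attribution=mp_attr,
            claim=str(claim) if claim is not None else None,
            source_document=str(source_doc) if source_doc is not None else None,
        )
        for o in g.objects(node, TERMS["asserts"]):
            iri = str(o)
            if iri in reps:
                mp.asserted[iri] = reps[iri]
                asserted_in[iri] = mp_iri
        for o in g.objects(node, TERMS["quotes"]):
            iri = str(o)
            if iri in reps and iri not in mp.asserted:
                mp.quoted[iri] = reps[iri]
        mps.append(mp)

    for mp in mps:
        phi = mp.phi
        for stmt, qual in qualifications:
            if stmt in phi and qual in phi:
                mp.qualifications.add((stmt, qual))
        mp.agents = {
            aid: agent
            for aid, agent in agents.items()
            if aid == mp.attribution.agent
            or any(
                rep.attribution is not None and rep.attribution.agent == aid
                for rep in mp.elements.values()
            )
        }

    by_id = {mp.id: mp for mp in mps}
    seen_edges: set[tuple[str, RelKind, str, str]] = set()

    def attach(s: str, rk: RelKind, o: str, owner: str) -> None:
        key = (s, rk, o, owner)
        if key in seen_edges or owner not in by_id:
            return
        seen_edges.add(key)
        by_id[owner].relations.append(
            Relation(source=s, rel_kind=rk, target=o, asserted_by=owner)
        )

    for (s, rk, o), owner in sorted(reified.items()):
        attach(s, rk, o, owner)
    for s, rk, o in sorted(flat):
        if (s, rk, o) in reified:
            continue
        owner = asserted_in.get(s)
        if owner is None or not (s in by_id[owner].phi and o in by_id[owner].phi):
            owner = next(
                (mp.id for mp in mps if s in mp.phi and o in mp.phi), owner
            )
        if owner is not None:
            attach(s, rk, o, owner)

    # opaque side-store for foreign-namespace triples
    for mp in mps:
        phi = mp.phi | {mp.id}
        extra = []
        for s, p, o in g:
            if str(s) in phi and not str(p).startswith(_KNOWN_NAMESPACES):
                obj = json.dumps(str(o)) if isinstance(o, Literal) else str(o)
                extra.append((str(s), str(p), obj))
        mp.extra_triples = tuple(sorted(extra))
    return mps


def network_from_rdf(doc: Union[RdfDocument, str], syntax: str = "turtle") -> ClaimNetwork:
    return merge(from_rdf(doc, syntax))


__all__ = [
    "MP",
    "OA",
    "RdfDocument",
    "TERMS",
    "TextAnchor",
    "anchor",
    "from_rdf",
    "network_from_rdf",
    "to_rdf",
]
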