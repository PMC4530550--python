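"""Worked-example fixtures and a seeded random claim-network generator.

The fixtures reconstruct, element for element, the case-study arguments
from the Alzheimer-disease literature that motivate the model: the
rapamycin/mTOR claim of Spilman et al. with its backing references, data
and methods; the cross-publication resolution network; similarity groups
with a holotype claim; a BEL-formalized claim; annotation and challenge
patterns; and the citation-distortion network (eight publications whose
foundational claims rest on hypotheses, not data).  Claim and statement
texts are the printed strings where the source prints them; elements
left unverbalized (such as image data) carry descriptive placeholders.

Every fixture passes validation; element labels (C3, S1, D1, M1, Ref5,
...) are embedded in the minted IRIs so printed structures can be checked
literally.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .model import (
    DEFAULT_BASE,
    Agent,
    AgentKind,
    Attribution,
    Media,
    Micropublication,
    RelKind,
    RepKind,
    Representation,
    Role,
    add_element,
    add_qualification,
    add_relation,
    make_micropublication,
    mint_iri,
)
from .network import (
    ClaimNetwork,
    build_similarity_group,
    merge,
    resolve_reference,
)

BASE = DEFAULT_BASE

# agents
SPILMAN = Agent(id=f"{BASE}/agent/PSpilman", name="Patricia Spilman")
HARRISON = Agent(id=f"{BASE}/agent/DHarrison", name="David Harrison")
HSIA = Agent(id=f"{BASE}/agent/AHsia", name="Albert Hsia")
BRYAN = Agent(id=f"{BASE}/agent/KBryan", name="Kathryn Bryan")
PRATT = Agent(id=f"{BASE}/agent/DPratt", name="Dexter Pratt")
NEUROSCIENTIST = Agent(id=f"{BASE}/agent/ANeuroscientist", name="A. Neuroscientist")
CURATOR = Agent(id=f"{BASE}/agent/KBCurator", name="KB Curator")
NEEDHAM = Agent(id=f"{BASE}/agent/MNeedham", name="Merrilee Needham")
ASKANAS = Agent(id=f"{BASE}/agent/VAskanas", name="Valerie Askanas")

# source documents (publication IRIs; references resolve to these)
DOC_SPILMAN = f"{BASE}/doc/spilman-2010"
DOC_HARRISON = f"{BASE}/doc/harrison-2009"
DOC_GAMES = f"{BASE}/doc/games-1995"
DOC_HSIA = f"{BASE}/doc/hsia-1999"

CLAIM_C1 = "rapamycin is an inhibitor of the mTOR pathway"
CLAIM_C3 = (
    "Inhibition of mTOR by rapamycin can slow or block AD progression "
    "in a transgenic mouse model of the disease"
)
CLAIM_C11 = (
    "PDAPP mice tend to have lower body temperatures, which may result in "
    "varying degrees of hypothermia during the MWM task, which can produce "
    "amnesia in animals"
)

CHEBI_RAPAMYCIN = "http://purl.obolibrary.org/obo/CHEBI_9168"
INO_INHIBITION = "http://purl.obolibrary.org/obo/INO_0000736"


def _rep(local_mp: str, label: str, kind: RepKind, **kw) -> Representation:
    return Representation(id=mint_iri(BASE, local_mp, label), rep_kind=kind, **kw)


def _attribution_rep(local_mp: str, label: str, agent: Agent, role: Role = Role.AUTHOR) -> Representation:
    attr = Attribution(id=mint_iri(BASE, local_mp, label), agent=agent.id, role=role)
    return Representation(id=attr.id, rep_kind=RepKind.ATTRIBUTION, attribution=attr)


def mp1_citable_claim() -> Micropublication:
    """Citable claim with supporting reference, attribution and qualifiers."""
    mp = make_micropublication(
        CLAIM_C1, SPILMAN, CURATOR, mp_id="mp1", claim_local="C1",
        source_document=DOC_SPILMAN,
    )
    ref5 = _rep("mp1", "Ref5", RepKind.REFERENCE, target=DOC_HARRISON)
    add_element(mp, ref5)
    add_relation(mp, ref5.id, RelKind.SUPPORTS, mp.claim)
    q1 = _rep("mp1", "Q1", RepKind.SEMANTIC_QUALIFIER, term=CHEBI_RAPAMYCIN)
    q2 = _rep("mp1", "Q2", RepKind.SEMANTIC_QUALIFIER, term=INO_INHIBITION)
    for q in (q1, q2):
        add_element(mp, q)
        add_qualification(mp, mp.claim, q.id)
    return mp


def _evidence(local: str) -> tuple[Representation, Representation, Representation]:
    d1 = _rep(
        local, "D1", RepKind.DATA,
        media=Media("image/composite", f"{BASE}/media/{local}-D1"),
        text="Composite image of graphs produced from the primary data",
    )
    m1 = _rep(local, "M1", RepKind.PROCEDURE,
              text="Rapamycin feeding protocol and Morris water maze protocol")
    m2 = _rep(local, "M2", RepKind.MATERIAL,
              text="PDAPP transgenic mouse strain (J20 line)")
    return d1, m1, m2


def mp2_evidence() -> Micropublication:
    """Citable claim with supporting data and reproducible methods."""
    mp = make_micropublication(
        CLAIM_C3, SPILMAN, CURATOR, mp_id="mp2", claim_local="C3",
        source_document=DOC_SPILMAN,
    )
    d1, m1, m2 = _evidence("mp2")
    for rep in (d1, m1, m2):
        add_element(mp, rep)
    add_relation(mp, d1.id, RelKind.SUPPORTS, mp.claim)
    add_relation(mp, m1.id, RelKind.SUPPORTS, d1.id)
    add_relation(mp, m2.id, RelKind.SUPPORTS, d1.id)
    return mp


def mp3_digital_abstract() -> Micropublication:
    """Computable digital summary of a publication: claim, statements, evidence."""
    mp = make_micropublication(
        CLAIM_C3, SPILMAN, CURATOR, mp_id="mp3", claim_local="C3",
        source_document=DOC_SPILMAN,
    )
    s1 = _rep("mp3", "S1", RepKind.STATEMENT,
              text="rapamycin … an inhibitor of the mTOR pathway …")
    s2 = _rep("mp3", "S2", RepKind.STATEMENT,
              text="PDAPP mice accumulate soluble and deposited Aβ and develop "
                   "AD-like synaptic deficits as well as cognitive impairment and "
                   "hippocampal atrophy")
    s3 = _rep("mp3", "S3", RepKind.STATEMENT,
              text="Rapamycin-fed PDAPP mice recovered cognitive performance in the "
                   "Morris water maze, as shown by the data in D1")
    d1, m1, m2 = _evidence("mp3")
    ref5 = _rep("mp3", "Ref5", RepKind.REFERENCE, target=DOC_HARRISON)
    ref9 = _rep("mp3", "Ref9", RepKind.REFERENCE, target=DOC_GAMES)
    ref10 = _rep("mp3", "Ref10", RepKind.REFERENCE, target=DOC_HSIA)
    for rep in (s1, s2, s3, d1, m1, m2, ref5, ref9, ref10):
        add_element(mp, rep)
    for s in (s1, s2, s3):
        add_relation(mp, s.id, RelKind.SUPPORTS, mp.claim)
    add_relation(mp, ref5.id, RelKind.SUPPORTS, s1.id)
    add_relation(mp, ref9.id, RelKind.SUPPORTS, s2.id)
    add_relation(mp, ref10.id, RelKind.SUPPORTS, s2.id)
    add_relation(mp, d1.id, RelKind.SUPPORTS, s3.id)
    add_relation(mp, m1.id, RelKind.SUPPORTS, d1.id)
    add_relation(mp, m2.id, RelKind.SUPPORTS, d1.id)
    return mp


def mp4_harrison() -> Micropublication:
    """The backing claim about rapamycin, with its own evidence."""
    mp = make_micropublication(
        "rapamycin … an inhibitor of the mTOR pathway …",
        HARRISON, CURATOR, mp_id="mp4", claim_local="C1.1",
        source_document=DOC_HARRISON,
    )
    d = _rep("mp4", "D1.1", RepKind.DATA,
             media=Media("image/figure", f"{BASE}/media/mp4-D1.1"),
             text="Survival and mTOR-signalling data from rapamycin-fed mice")
    m = _rep("mp4", "M1.1", RepKind.PROCEDURE,
             text="Encapsulated rapamycin feeding protocol")
    add_element(mp, d)
    add_element(mp, m)
    add_relation(mp, d.id, RelKind.SUPPORTS, mp.claim)
    add_relation(mp, m.id, RelKind.SUPPORTS, d.id)
    return mp


def mp5_hsia() -> Micropublication:
    """The backing claim about PDAPP mice, with its own evidence."""
    mp = make_micropublication(
        "… addition of the Swedish FAD mutation to the APP transgene in a "
        "second line of mice, further increased synaptic transmission deficits "
        "in young APP mice without plaques",
        HSIA, CURATOR, mp_id="mp5", claim_local="C2.1",
        source_document=DOC_HSIA,
    )
    d = _rep("mp5", "D2.1", RepKind.DATA,
             media=Media("image/figure", f"{BASE}/media/mp5-D2.1"),
             text="Electrophysiology data from APP transgenic mice")
    m = _rep("mp5", "M2.1", RepKind.MATERIAL,
             text="APP transgenic mouse lines carrying the Swedish FAD mutation")
    add_element(mp, d)
    add_element(mp, m)
    add_relation(mp, d.id, RelKind.SUPPORTS, mp.claim)
    add_relation(mp, m.id, RelKind.SUPPORTS, d.id)
    return mp


MP6_ID = f"{BASE}/mp6"


def example4_network() -> ClaimNetwork:
    """Claim network across three publications, connected by resolution MP6.

    MP6 quotes C3, S1, S2, C1.1 and C2.1 and asserts the new support
    relationships supports(C1.1, S1) and supports(C2.1, S2).
    """
    mp3, mp4, mp5 = mp3_digital_abstract(), mp4_harrison(), mp5_hsia()
    net = merge([mp3, mp4, mp5])
    attr = Attribution(
        id=mint_iri(BASE, "mp6", "A_MP6"), agent=CURATOR.id, role=Role.CURATOR
    )
    s1, s2 = mint_iri(BASE, "mp3", "S1"), mint_iri(BASE, "mp3", "S2")
    resolve_reference(net, s1, mp4.claim, attr, into=MP6_ID)
    resolve_reference(net, s2, mp5.claim, attr, into=MP6_ID)
    mp6 = net.micropublications[MP6_ID]
    # MP6 also quotes the claim whose argument it extends
    if mp3.claim not in mp6.phi:
        add_element(mp6, net.nodes[mp3.claim].representation, mode="quotes")
        net.nodes[mp3.claim].quoted_by.add(mp6.id)
    return net


def mp6_resolution() -> Micropublication:
    """The resolution micropublication itself, built through the network API."""
    return example4_network().micropublications[MP6_ID]


def _minimal_claim_mp(
    mp_id: str, claim_local: str, text: str, author: Agent, doc: str
) -> Micropublication:
    return make_micropublication(
        text, author, CURATOR, mp_id=mp_id, claim_local=claim_local, source_document=doc
    )


def mp7_similarity() -> Micropublication:
    """Similarity group as a micropublication, with a user-defined holotype.

    Membership here is explicit curator judgement (threshold 0), exactly
    as a knowledge-base curator would assert similog status; the group's
    claim is the holotype C4 and the members are in its support graph.
    """
    mp3, mp4 = mp3_digital_abstract(), mp4_harrison()
    c4 = _minimal_claim_mp(
        "pub-c4", "C4", "Rapamycin directly inhibits the mTOR kinase",
        Agent(id=f"{BASE}/agent/Brown", name="Brown EJ"), f"{BASE}/doc/brown-1994",
    )
    c5 = _minimal_claim_mp(
        "pub-c5", "C5", "Rapamycin blocks mTOR signalling in mammalian cells",
        Agent(id=f"{BASE}/agent/Sabers", name="Sabers CJ"), f"{BASE}/doc/sabers-1995",
    )
    c6 = _minimal_claim_mp(
        "pub-c6", "C6",
        "RAFT1 … binds FKBP12-rapamycin and mediates its inhibitory action",
        Agent(id=f"{BASE}/agent/Sabatini", name="Sabatini DM"), f"{BASE}/doc/sabatini-1994",
    )
    net = merge([mp3, mp4, c4, c5, c6])
    attr = Attribution(
        id=mint_iri(BASE, "mp7-similarity", "A_MP7"),
        agent=CURATOR.id,
        role=Role.CURATOR,
    )
    group = build_similarity_group(
        net,
        holotype=c4.claim,
        members={mp3.claim, mp4.claim, c5.claim, c6.claim},
        attribution=attr,
        threshold=0.0,
        group_id="mp7-similarity",
    )
    return group.as_micropublication


def mp7_bel() -> Micropublication:
    """A BEL-formalized claim with document-level support; BEL text is opaque."""
    mp = make_micropublication(
        "a(CHEBI:9168) =| kin(p(HGNC:FRAP1))",
        PRATT, PRATT, mp_id="mp7-bel", claim_local="C7",
        source_document=None,
    )
    ref96 = _rep("mp7-bel", "Ref96", RepKind.REFERENCE, target="PMID:12030785")
    add_element(mp, ref96)
    add_relation(mp, ref96.id, RelKind.SUPPORTS, mp.claim)
    return mp


def mp10_annotation() -> Micropublication:
    """Annotation as an independent micropublication referencing the original."""
    mp1 = mp1_citable_claim()
    mp = make_micropublication(
        "The Spilman result suggests rapamycin analogues are worth investigating "
        "as therapeutic agents for human AD",
        NEUROSCIENTIST, NEUROSCIENTIST, mp_id="mp10", claim_local="C10",
    )
    add_element(mp, mp1.elements[mp1.claim], mode="quotes")
    add_relation(mp, mp1.claim, RelKind.SUPPORTS, mp.claim)
    return mp


def _bryan_mp(mp_id: str, with_challenge: bool) -> Micropublication:
    mp = make_micropublication(
        CLAIM_C11, BRYAN, CURATOR, mp_id=mp_id, claim_local="C11",
        source_document=f"{BASE}/doc/bryan-2009",
    )
    for label, doc in (("R48", f"{BASE}/doc/r48"), ("R49", f"{BASE}/doc/r49"),
                       ("R50", f"{BASE}/doc/r50")):
        ref = _rep(mp_id, label, RepKind.REFERENCE, target=doc)
        add_element(mp, ref)
        add_relation(mp, ref.id, RelKind.SUPPORTS, mp.claim)
    if with_challenge:
        s3 = mint_iri(BASE, "mp3", "S3")
        mp3 = mp3_digital_abstract()
        add_element(mp, mp3.elements[s3], mode="quotes")
        add_relation(mp, mp.claim, RelKind.DIRECTLY_CHALLENGES, s3)
    return mp


def mp8_challenge_case1() -> ClaimNetwork:
    """Case 1: a publication's own claim challenges a statement of another.

    MP8 (Bryan et al.) quotes MP3:S3 and asserts directlyChallenges(C11, S3);
    by undercutting, C11 challenges MP3's principal claim C3 once merged.
    """
    return merge([mp3_digital_abstract(), _bryan_mp("mp8", with_challenge=True)])


def mp12_challenge_case2() -> ClaimNetwork:
    """Case 2: a third party records the disagreement as its own micropublication.

    Neither MP3 nor MP11 contains challenge relations; MP12 (a curator
    annotation) quotes S3 and C11, supports its claim C12 with both, and
    asserts the directlyChallenges edge between them — the conflict is
    precisely what MP12 argues, so both sides are in its support graph.
    """
    mp3 = mp3_digital_abstract()
    mp11 = _bryan_mp("mp11", with_challenge=False)
    mp12 = make_micropublication(
        "Bryan et al. claim that PDAPP mice tend to have lower body temperatures, "
        "which may result in varying degrees of hypothermia during the MWM task, "
        "which in turn can produce amnesia in animals. This challenges the validity "
        "of PDAPP mice as an AD model, as asserted in Hsia et al.",
        CURATOR, CURATOR, mp_id="mp12", claim_local="C12",
    )
    mp12.annotation = True
    s3 = mint_iri(BASE, "mp3", "S3")
    add_element(mp12, mp3.elements[s3], mode="quotes")
    add_element(mp12, mp11.elements[mp11.claim], mode="quotes")
    add_relation(mp12, s3, RelKind.SUPPORTS, mp12.claim)
    add_relation(mp12, mp11.claim, RelKind.SUPPORTS, mp12.claim)
    add_relation(mp12, mp11.claim, RelKind.DIRECTLY_CHALLENGES, s3)
    return merge([mp3, mp11, mp12])


# ---------------------------------------------------------------------------
# citation-distortion network


GREENBERG_HOLOTYPE_ID = f"{BASE}/greenberg-holotype"


def greenberg() -> ClaimNetwork:
    """Citation-distortion network: eight publications, no data at the root.

    A review claim (C12, stated as pure fact with no support of its own)
    is backed only through its representative claim C11, whose citation
    lineage runs through intermediate reviews from one laboratory down to
    foundational publications containing hypothesis statements — and no
    data nodes anywhere.  The holotype assertion is materialized as a
    curator micropublication so that the lineage of C12 descends through
    C11; under the star convention of similarity groups this makes C12
    the group root with C11 its (representative) member, the direction
    that lets grounding analysis traverse the distorted chain.
    """
    docs = {i: f"{BASE}/doc/greenberg-pub-{i}" for i in range(1, 9)}
    hypothesis = (
        "We hypothesize that accumulation of amyloid-beta may play a causal "
        "role in inclusion-body myositis muscle-fibre degeneration"
    )
    # foundational publications: hypothesis statements, attribution only
    g1 = _minimal_claim_mp("greenberg-pub-1", "C15", hypothesis, ASKANAS, docs[1])
    g2 = _minimal_claim_mp(
        "greenberg-pub-2", "C16",
        "Amyloid-beta is proposed as an upstream trigger of IBM pathology",
        ASKANAS, docs[2],
    )
    g3 = _minimal_claim_mp(
        "greenberg-pub-3", "C17",
        "It is suggested that APP overexpression initiates the degenerative "
        "cascade in IBM muscle fibres",
        ASKANAS, docs[3],
    )
    g4 = _minimal_claim_mp(
        "greenberg-pub-4", "C18",
        "Intracellular amyloid-beta may precede vacuolar change in IBM",
        ASKANAS, docs[4],
    )

    def review(mp_id, label, text, author, doc, cited, ref_docs):
        mp = _minimal_claim_mp(mp_id, label, text, author, doc)
        for i, rdoc in enumerate(ref_docs, start=1):
            ref = _rep(mp_id, f"R{label}-{i}", RepKind.REFERENCE, target=rdoc)
            add_element(mp, ref)
            add_relation(mp, ref.id, RelKind.SUPPORTS, mp.claim)
        for cited_mp in cited:
            add_element(mp, cited_mp.elements[cited_mp.claim], mode="quotes")
            add_relation(mp, cited_mp.claim, RelKind.SUPPORTS, mp.claim)
        return mp

    # intermediate reviews from the same laboratory, citing the foundations
    g5 = review(
        "greenberg-pub-5", "C13",
        "Abnormal accumulation of amyloid-beta precedes other pathologic "
        "changes in IBM muscle",
        ASKANAS, docs[5], [g1, g3], [docs[1], docs[3]],
    )
    g6 = review(
        "greenberg-pub-6", "C14",
        "Amyloid-beta accumulation is an early, possibly causative event in "
        "IBM muscle fibres",
        ASKANAS, docs[6], [g2, g4], [docs[2], docs[4]],
    )
    # the citing review
    g7 = review(
        "greenberg-pub-7", "C11",
        "The accumulation of APP and its fragments is often stated to precede "
        "other abnormalities in IBM muscle fibers",
        NEEDHAM, docs[7], [g5, g6], [docs[5], docs[6]],
    )
    # the claim upgraded to fact, with no support at all
    g8 = _minimal_claim_mp(
        "greenberg-pub-8", "C12",
        "Amyloid-beta deposition in IBM muscle fibres precedes other "
        "pathological changes",
        NEEDHAM, docs[8],
    )
    net = merge([g1, g2, g3, g4, g5, g6, g7, g8])
    attr = Attribution(
        id=mint_iri(BASE, "greenberg-holotype", "A_H"),
        agent=CURATOR.id,
        role=Role.CURATOR,
    )
    group = build_similarity_group(
        net,
        holotype=g8.claim,  # C12: the fact-form claim the lineage must explain
        members={g7.claim},  # C11: its representative statement
        attribution=attr,
        threshold=0.0,
        group_id="greenberg-holotype",
    )
    holo_mp = group.as_micropublication
    net.micropublications[holo_mp.id] = holo_mp
    for iri, rep in holo_mp.asserted.items():
        from .network import NodeEntry

        net.nodes[iri] = NodeEntry(representation=rep, asserted_by=holo_mp.id)
    for iri in holo_mp.quoted:
        net.nodes[iri].quoted_by.add(holo_mp.id)
    for rel in holo_mp.relations:
        if rel not in net.edges:
            net.edges.append(rel)
    return net


_FIXTURES = {
    "mp1_citable_claim": mp1_citable_claim,
    "mp2_evidence": mp2_evidence,
    "mp3_digital_abstract": mp3_digital_abstract,
    "mp4_harrison": mp4_harrison,
    "mp5_hsia": mp5_hsia,
    "mp6_resolution": mp6_resolution,
    "example4_network": example4_network,
    "mp7_similarity": mp7_similarity,
    "mp7_bel": mp7_bel,
    "mp10_annotation": mp10_annotation,
    "mp8_challenge_case1": mp8_challenge_case1,
    "mp12_challenge_case2": mp12_challenge_case2,
    "greenberg": greenberg,
}

FIXTURE_NAMES = tuple(_FIXTURES)


def example(name: str):
    """Return a named worked-example micropublication or claim network."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        valid = ", ".join(FIXTURE_NAMES)
        raise KeyError(f"unknown fixture {name!r}; valid names: {valid}") from None
    return builder()


# ---------------------------------------------------------------------------
# random generator


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the synthetic claim-network generator.

    Each publication contributes one micropublication: a claim, a sampled
    number of supporting statements, data attached to statements with
    probability ``p_data_support`` (with a method behind each datum with
    probability ``p_method_per_data``), document-level references, plus
    cross-publication reference resolutions and direct challenges.  The
    same seed always yields the identical network.
    """

    n_publications: int = 6
    statements_per_mp: tuple[int, int] = (1, 3)
    p_data_support: float = 0.7
    p_method_per_data: float = 0.8
    p_reference_resolution: float = 0.5
    p_challenge: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_publications < 1:
            raise ValueError("n_publications must be positive")
        lo, hi = self.statements_per_mp
        if not (0 <= lo <= hi):
            raise ValueError("statements_per_mp must be a non-empty range")
        for name in ("p_data_support", "p_method_per_data",
                     "p_reference_resolution", "p_challenge"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


_TOPICS = (
    "kinase inhibition slows neurodegeneration",
    "protein aggregation precedes synaptic loss",
    "transgenic models recapitulate human pathology",
    "pathway activation restores cognitive function",
    "biomarker levels track disease progression",
)


def random_network(config: NetworkConfig) -> ClaimNetwork:
    """Generate a seeded synthetic claim network; every MP is valid."""
    config.validate()
    rng = random.Random(config.seed)
    tag = f"rand{config.seed}"
    mps: list[Micropublication] = []
    statements_by_mp: list[list[Representation]] = []
    for i in range(1, config.n_publications + 1):
        local = f"{tag}-pub-{i}"
        author = Agent(id=f"{BASE}/agent/{tag}-author-{i}", name=f"Author {i}")
        topic = _TOPICS[(i - 1) % len(_TOPICS)]
        mp = make_micropublication(
            f"Publication {i} claims that {topic}",
            author, CURATOR, mp_id=local, claim_local=f"C{i}",
            source_document=f"{BASE}/doc/{tag}-pub-{i}",
        )
        lo, hi = config.statements_per_mp
        n_statements = rng.randint(lo, hi)
        statements = []
        for j in range(1, n_statements + 1):
            s = _rep(local, f"S{i}.{j}", RepKind.STATEMENT,
                     text=f"Statement {j} of publication {i}: {topic}")
            add_element(mp, s)
            add_relation(mp, s.id, RelKind.SUPPORTS, mp.claim)
            statements.append(s)
        # evidence: data under statements (or under the claim when none)
        targets = [s.id for s in statements] or [mp.claim]
        for k, target in enumerate(targets, start=1):
            if rng.random() < config.p_data_support:
                d = _rep(local, f"D{i}.{k}", RepKind.DATA,
                         text=f"Data table {k} of publication {i}")
                add_element(mp, d)
                add_relation(mp, d.id, RelKind.SUPPORTS, target)
                if rng.random() < config.p_method_per_data:
                    m = _rep(local, f"M{i}.{k}", RepKind.PROCEDURE,
                             text=f"Protocol {k} of publication {i}")
                    add_element(mp, m)
                    add_relation(mp, m.id, RelKind.SUPPORTS, d.id)
        # document-level references to earlier publications
        for j, s in enumerate(statements, start=1):
            if i > 1:
                cited = rng.randrange(1, i)
                ref = _rep(local, f"R{i}.{j}", RepKind.REFERENCE,
                           target=f"{BASE}/doc/{tag}-pub-{cited}")
                add_element(mp, ref)
                add_relation(mp, ref.id, RelKind.SUPPORTS, s.id)
        # direct challenges against an earlier statement
        if i > 1 and rng.random() < config.p_challenge:
            donor = rng.randrange(0, len(statements_by_mp))
            if statements_by_mp[donor]:
                victim = rng.choice(statements_by_mp[donor])
                add_element(mp, victim, mode="quotes")
                add_relation(mp, mp.claim, RelKind.DIRECTLY_CHALLENGES, victim.id)
        mps.append(mp)
        statements_by_mp.append(statements)

    net = merge(mps)
    # claim-level reference resolutions across publications
    for i, mp in enumerate(mps[1:], start=2):
        for s in statements_by_mp[i - 1]:
            if rng.random() < config.p_reference_resolution:
                cited_mp = mps[rng.randrange(0, i - 1)]
                attr = Attribution(
                    id=f"{BASE}/{tag}-resolution#{i}-{s.id.rsplit('#', 1)[-1]}",
                    agent=CURATOR.id,
                    role=Role.CURATOR,
                )
                resolve_reference(net, s.id, cited_mp.claim, attr)
    return net


__all__ = [
    "BASE",
    "FIXTURE_NAMES",
    "NetworkConfig",
    "example",
    "random_network",
]
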