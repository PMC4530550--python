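"""Core model: builder API, kind hierarchy and invariant validation."""

import pytest
from hypothesis import given, settings, strategies as st

from micropub import (
    Agent,
    Attribution,
    Micropublication,
    MicropubError,
    RelKind,
    Relation,
    RepKind,
    Representation,
    add_element,
    add_relation,
    elements_of,
    is_a,
    make_micropublication,
    validate,
)
from micropub.model import ViolationCode, support_closure_elements

from conftest import local


class TestMakeMicropublication:
    def test_minimal_form_is_claim_with_attribution(self, author, curator):
        """The minimal micropublication is a statement with its attribution."""
        mp = make_micropublication(
            "rapamycin is an inhibitor of the mTOR pathway", author, curator
        )
        assert validate(mp).is_valid
        assert len(mp.asserted) == 2 and not mp.quoted
        kinds = {rep.rep_kind for rep in mp.asserted.values()}
        assert kinds == {RepKind.CLAIM, RepKind.ATTRIBUTION}
        [rel] = mp.relations
        assert rel.rel_kind == RelKind.SUPPORTS and rel.target == mp.claim
        a_c = mp.elements[rel.source]
        assert a_c.attribution.agent == author.id
        assert mp.attribution.agent == curator.id

    def test_author_and_curator_may_be_one_agent(self, author):
        mp = make_micropublication("x is y", author, author)
        assert validate(mp).is_valid
        assert mp.attribution.agent == author.id

    @pytest.mark.parametrize("text", ["", "   "])
    def test_empty_claim_rejected(self, text, author):
        with pytest.raises(MicropubError) as err:
            make_micropublication(text, author, author)
        assert err.value.code == ViolationCode.NO_CLAIM


class TestAddElement:
    def test_supporting_reference(self, minimal_mp):
        ref = Representation(
            id=minimal_mp.id + "#Ref5", rep_kind=RepKind.REFERENCE, target="Harrison et al."
        )
        add_element(minimal_mp, ref)
        add_relation(minimal_mp, ref.id, RelKind.SUPPORTS, minimal_mp.claim)
        assert len(minimal_mp.phi) == 3
        assert validate(minimal_mp).is_valid

    def test_quoting_leaves_original_assertion_elsewhere(self, minimal_mp, author):
        other = make_micropublication("another finding", author, author)
        quoted = other.elements[other.claim]
        add_element(minimal_mp, quoted, mode="quotes")
        assert quoted.id in minimal_mp.quoted
        assert quoted.id in other.asserted  # original asserting MP unchanged

    def test_duplicate_rejected(self, minimal_mp):
        rep = Representation(
            id=minimal_mp.id + "#S1", rep_kind=RepKind.STATEMENT, text="s"
        )
        add_element(minimal_mp, rep)
        with pytest.raises(MicropubError):
            add_element(minimal_mp, rep)
        with pytest.raises(MicropubError):
            add_element(minimal_mp, rep, mode="quotes")

    @pytest.mark.parametrize(
        "rep",
        [
            Representation(id="urn:x", rep_kind=RepKind.STATEMENT, text=""),
            Representation(id="urn:x", rep_kind=RepKind.REFERENCE),
            Representation(id="urn:x", rep_kind=RepKind.SEMANTIC_QUALIFIER),
            Representation(id="urn:x", rep_kind=RepKind.METHOD, text="abstract"),
        ],
    )
    def test_malformed_representations_rejected(self, rep, minimal_mp):
        with pytest.raises(MicropubError) as err:
            add_element(minimal_mp, rep)
        assert err.value.code == ViolationCode.KIND_VIOLATION


class TestAddRelation:
    def test_evidence_edge_set(self, author, curator):
        """Data supported by two methods, all supporting the claim."""
        mp = make_micropublication("claim C3", author, curator, claim_local="C3")
        d1 = Representation(id=mp.id + "#D1", rep_kind=RepKind.DATA, text="data")
        m1 = Representation(id=mp.id + "#M1", rep_kind=RepKind.PROCEDURE, text="protocol")
        m2 = Representation(id=mp.id + "#M2", rep_kind=RepKind.MATERIAL, text="mouse strain")
        for rep in (d1, m1, m2):
            add_element(mp, rep)
        add_relation(mp, d1.id, RelKind.SUPPORTS, mp.claim)
        add_relation(mp, m1.id, RelKind.SUPPORTS, d1.id)
        add_relation(mp, m2.id, RelKind.SUPPORTS, d1.id)
        got = {(local(r.source), local(r.target)) for r in mp.relations}
        assert got == {("A_C3", "C3"), ("D1", "C3"), ("M1", "D1"), ("M2", "D1")}
        assert validate(mp).is_valid

    def test_reflexive_edge_rejected(self, minimal_mp):
        with pytest.raises(MicropubError) as err:
            add_relation(minimal_mp, minimal_mp.claim, RelKind.SUPPORTS, minimal_mp.claim)
        assert err.value.code == ViolationCode.SUPPORT_CYCLE

    def test_two_cycle_rejected_eagerly(self, minimal_mp):
        a = Representation(id=minimal_mp.id + "#a", rep_kind=RepKind.STATEMENT, text="a")
        b = Representation(id=minimal_mp.id + "#b", rep_kind=RepKind.STATEMENT, text="b")
        add_element(minimal_mp, a)
        add_element(minimal_mp, b)
        add_relation(minimal_mp, a.id, RelKind.SUPPORTS, b.id)
        with pytest.raises(MicropubError) as err:
            add_relation(minimal_mp, b.id, RelKind.SUPPORTS, a.id)
        assert err.value.code == ViolationCode.SUPPORT_CYCLE

    def test_dangling_endpoint_rejected(self, minimal_mp):
        with pytest.raises(MicropubError) as err:
            add_relation(minimal_mp, "urn:nowhere", RelKind.SUPPORTS, minimal_mp.claim)
        assert err.value.code == ViolationCode.DANGLING_ENDPOINT

    def test_dual_edge_rejected(self, minimal_mp):
        s = Representation(id=minimal_mp.id + "#s", rep_kind=RepKind.STATEMENT, text="s")
        add_element(minimal_mp, s)
        add_relation(minimal_mp, s.id, RelKind.SUPPORTS, minimal_mp.claim)
        with pytest.raises(MicropubError) as err:
            add_relation(minimal_mp, s.id, RelKind.DIRECTLY_CHALLENGES, minimal_mp.claim)
        assert err.value.code == ViolationCode.DUAL_EDGE


class TestValidate:
    def _raw_mp(self, **kw):
        attr = Attribution(id="urn:mp#A", agent="urn:agent")
        defaults = dict(id="urn:mp", attribution=attr)
        defaults.update(kw)
        return Micropublication(**defaults)

    def test_empty_phi(self):
        report = validate(self._raw_mp())
        assert {v.code for v in report.violations} >= {
            ViolationCode.EMPTY_PHI,
            ViolationCode.NO_CLAIM,
        }

    def test_missing_claim_attribution(self):
        claim = Representation(id="urn:mp#c", rep_kind=RepKind.CLAIM, text="c")
        mp = self._raw_mp(claim=claim.id, asserted={claim.id: claim})
        report = validate(mp)
        codes = {v.code for v in report.violations}
        assert ViolationCode.MISSING_CLAIM_ATTRIBUTION in codes

    def test_injected_support_cycle_found_lazily(self):
        """A cycle injected past the builder (as from foreign RDF) is reported."""
        attr_rep = Representation(
            id="urn:mp#A",
            rep_kind=RepKind.ATTRIBUTION,
            attribution=Attribution(id="urn:mp#A", agent="urn:agent"),
        )
        claim = Representation(id="urn:mp#c", rep_kind=RepKind.CLAIM, text="c")
        x = Representation(id="urn:mp#x", rep_kind=RepKind.STATEMENT, text="x")
        y = Representation(id="urn:mp#y", rep_kind=RepKind.STATEMENT, text="y")
        mp = self._raw_mp(
            claim=claim.id,
            asserted={r.id: r for r in (claim, attr_rep, x, y)},
            relations=[
                Relation(attr_rep.id, RelKind.SUPPORTS, claim.id, "urn:mp"),
                Relation(x.id, RelKind.SUPPORTS, y.id, "urn:mp"),
                Relation(y.id, RelKind.SUPPORTS, x.id, "urn:mp"),
            ],
        )
        report = validate(mp)
        assert ViolationCode.SUPPORT_CYCLE in {v.code for v in report.violations}

    def test_claim_not_greatest(self, minimal_mp):
        s = Representation(id=minimal_mp.id + "#s", rep_kind=RepKind.STATEMENT, text="s")
        add_element(minimal_mp, s)
        minimal_mp.relations.append(
            Relation(minimal_mp.claim, RelKind.SUPPORTS, s.id, minimal_mp.id)
        )
        report = validate(minimal_mp)
        assert ViolationCode.CLAIM_NOT_GREATEST in {v.code for v in report.violations}

    def test_report_dict_shape(self, minimal_mp):
        report = validate(minimal_mp)
        d = report.as_dict()
        assert d["is_valid"] is True and d["violations"] == []


class TestElementsOf:
    def test_minimal(self, minimal_mp):
        assert {r.id for r in elements_of(minimal_mp)} == minimal_mp.phi
        assert len(elements_of(minimal_mp)) == 2

    def test_counting(self, minimal_mp):
        for k in range(5):
            add_element(
                minimal_mp,
                Representation(
                    id=f"{minimal_mp.id}#extra{k}", rep_kind=RepKind.STATEMENT, text="t"
                ),
            )
            assert len(elements_of(minimal_mp)) == k + 3


KIND_TABLE = [
    (RepKind.CLAIM, RepKind.STATEMENT, True),
    (RepKind.CLAIM, RepKind.SENTENCE, True),
    (RepKind.STATEMENT, RepKind.SENTENCE, True),
    (RepKind.STATEMENT, RepKind.CLAIM, False),
    (RepKind.REFERENCE, RepKind.QUALIFIER, True),
    (RepKind.SEMANTIC_QUALIFIER, RepKind.QUALIFIER, True),
    (RepKind.QUALIFIER, RepKind.SENTENCE, True),
    (RepKind.REFERENCE, RepKind.SENTENCE, True),
    (RepKind.MATERIAL, RepKind.METHOD, True),
    (RepKind.PROCEDURE, RepKind.METHOD, True),
    (RepKind.METHOD, RepKind.PROCEDURE, False),
    (RepKind.DATA, RepKind.SENTENCE, False),
    (RepKind.DATA, RepKind.METHOD, False),
    (RepKind.ATTRIBUTION, RepKind.SENTENCE, False),
    (RepKind.CLAIM, RepKind.CLAIM, True),
]


@pytest.mark.parametrize("kind,ancestor,expected", KIND_TABLE)
def test_kind_hierarchy(kind, ancestor, expected):
    assert is_a(kind, ancestor) is expected


# ---------------------------------------------------------------------------
# construction-validation equivalence


@st.composite
def build_sequence(draw):
    """A random sequence of element additions and legal relation attempts."""
    n_elements = draw(st.integers(min_value=0, max_value=8))
    kinds = st.sampled_from(
        [RepKind.STATEMENT, RepKind.DATA, RepKind.PROCEDURE, RepKind.MATERIAL,
         RepKind.REFERENCE]
    )
    elems = [(f"e{i}", draw(kinds)) for i in range(n_elements)]
    n_edges = draw(st.integers(min_value=0, max_value=12))
    edges = [
        (
            draw(st.integers(min_value=0, max_value=max(n_elements, 1))),
            draw(st.integers(min_value=0, max_value=max(n_elements, 1))),
        )
        for _ in range(n_edges)
    ]
    return elems, edges


@settings(max_examples=120, derandomize=True, deadline=None)
@given(build_sequence())
def test_builder_never_produces_invalid_object(seq):
    """Whatever the builder accepts, validate() accepts too."""
    author = Agent(id="urn:agent", name="A")
    mp = make_micropublication("the principal claim", author, author)
    elems, edges = seq
    ids = [mp.claim]
    for name, kind in elems:
        rep = Representation(
            id=f"{mp.id}#{name}",
            rep_kind=kind,
            text=None if kind in (RepKind.REFERENCE,) else name,
            target="doc" if kind == RepKind.REFERENCE else None,
        )
        try:
            add_element(mp, rep)
            ids.append(rep.id)
        except MicropubError:
            pass
    for i, j in edges:
        try:
            add_relation(
                mp, ids[i % len(ids)], RelKind.SUPPORTS, ids[j % len(ids)]
            )
        except MicropubError:
            pass
    assert validate(mp).is_valid


def test_phi_plus_reachability(minimal_mp):
    """Every element of Phi+ reaches the claim along supports edges."""
    s = Representation(id=minimal_mp.id + "#s", rep_kind=RepKind.STATEMENT, text="s")
    orphan = Representation(id=minimal_mp.id + "#o", rep_kind=RepKind.STATEMENT, text="o")
    add_element(minimal_mp, s)
    add_element(minimal_mp, orphan)
    add_relation(minimal_mp, s.id, RelKind.SUPPORTS, minimal_mp.claim)
    phi_plus = support_closure_elements(minimal_mp)
    assert s.id in phi_plus and orphan.id not in phi_plus
    pairs = minimal_mp.supports_pairs()
    for element in phi_plus:
        # BFS reachability check
        frontier, seen = {element}, set()
        while frontier:
            node = frontier.pop()
            seen.add(node)
            frontier |= {t for (u, t) in pairs if u == node} - seen
        assert minimal_mp.claim in seen
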