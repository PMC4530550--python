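# Methods

## The model and its assumptions

A micropublication formalizes one argument: MP = ⟨A_mpa, c, A_c, Φ, R⟩.
Φ is the finite, non-empty set of argument elements; it is partitioned
into *asserted* elements (originally instantiated by this
micropublication) and *quoted* elements (re-used from another), which is
how merged networks retain localization of responsibility. R is
partitioned into supports (R⁺) and directlyChallenges (R⁻) edges; both
endpoints of every edge must lie in Φ. Per micropublication the supports
edges form a DAG in which the claim *c* is the greatest element, so R⁺
restricted to the elements that reach *c* (the support graph Φ⁺) is a
strict partial order with greatest element *c*. The minimal level of
support for any statement is its attribution, so attributions are
ordinary elements of Φ that participate in supports edges — the minimal
valid micropublication is `{c, A_c}` with `supports(A_c, c)`, and this
attribution edge is what makes R⁺ non-empty in the minimal form.

Kinds form a small subsumption hierarchy used for rule dispatch:
claim ⊑ statement ⊑ sentence; reference and semantic-qualifier ⊑
qualifier ⊑ sentence; procedure and material ⊑ method, with method
abstract (a material is modelled as supporting any procedure of which it
is a component). Data and article-text stand alone. Sentence-family
elements must carry text, references a bibliographic target, semantic
qualifiers an ontology-term IRI.

Validation is total and reporting, not throwing: `validate()` returns
every violated invariant (empty Φ, missing/duplicated claim, dangling
endpoints, supports cycles, claim not greatest, missing claim
attribution, kind violations, dual edges). The builder API enforces the
same invariants eagerly — anything the builder accepts, `validate()`
accepts (property-tested) — while graphs arriving from foreign RDF are
checked lazily, because third-party documents may violate constraints
the builder would have refused.

## Inference

`supports` is transitive. The stored edges are the asserted base
relation; `supports_closure` computes the smallest transitive superset
by per-node reachability. On cyclic input — possible in merged networks,
which only the per-micropublication DAG invariant constrains — the
closure contains reflexive pairs; they are reported, never silently
dropped.

Challenges are inferred, not stored beyond the direct edges:
`challenges(x, z)` holds if `directlyChallenges(x, z)`, or if
`directlyChallenges(x, y)` for some supporter *y* of *z* (undercutting).
Undercutting defaults to the **transitive** reading — attacking any
ancestor supporter of a claim challenges the claim — because the
challenge case studies treat an attack on a methodology-level statement
as a challenge to the principal claim it transitively supports. A strict
`one_step` mode is available for the narrower reading; both are exposed
through the CLI's `undercut_mode`. Challenges are never chained over
themselves: no "challenger of my challenger" inference is defined, so
none is drawn.

Support and challenge graphs are views instantiated by query and never
stored. A support graph may contain directlyChallenges edges between its
members (the quoted-conflict pattern, where what the micropublication
argues is precisely that two statements conflict); an element may belong
to both the support and the challenge graph of the same claim — the
model does not forbid it and validation does not flag it.

## Networks and analyses

Merging requires each input to be individually valid, deduplicates
elements by IRI, enforces a single asserting micropublication per
element, and keeps per-edge provenance. Quoted elements with no
asserting micropublication in the batch become stub nodes with a
warning. Cross-publication cycles are permitted; every traversal is
cycle-safe (visited sets) and reports cycles rather than breaking them.

Reference resolution mints an annotation micropublication that quotes
the citing statement and cited claim and asserts the claim-level
supports edge; it is idempotent per pair. Resolution micropublications
carry a minted meta-claim (a claim-less container would be invalid) and
are flagged as annotations, excluded from publication tallies, since
they assert no claim text from a document of their own. Publication
identity is keyed by reference target (DOI/PubMed/IRI), so multiple
reference representations resolving to one target collapse to one
publication.

Grounding: a claim is `grounded_by_data` iff some data node has a
supports path to it; `grounded_by_method` additionally requires every
such data node to have a method-kind supporter. A claim with no data in
its ancestry is flagged `NO_EVIDENCE_AT_ROOT`; a reference backing a
statement that has no claim-level backing is `UNRESOLVED_REFERENCE`
(document-level citation never resolved). `SELF_CITATION_CHAIN` — two or
more consecutive lineage hops attributed to the same agent — is a
heuristic and off by default.

Similarity: "sufficient closeness" of similogs is not formally defined,
so the default comparator is deliberately simple and overridable:
Jaccard index over lower-cased, punctuation-stripped token sets,
threshold 0.5. Membership is scored against the holotype only (star
topology), not all-pairs. Explicit curator membership — including
translations, which no lexical score can capture — is expressed by
passing threshold 0. The curator's attribution doubles as the holotype
claim's attribution element in the materialized group micropublication.

## RDF

Serialization uses flat asserts/quotes provenance properties in the
`mp:` namespace, not named graphs. Every relation is additionally
reified as a content-addressed `rdf:Statement` node carrying
`mp:assertedBy`; this makes challenge edges quotable as elements and
makes merged networks round-trip losslessly. No blank nodes are emitted.
Output is written by a small canonical emitter — prefix block plus one
line per triple, sorted by subject, predicate, object — because
byte-stable output for golden files requires an ordering guarantee that
general-purpose Turtle serializers do not give; parsing is rdflib
throughout, for both Turtle and JSON-LD. Materialized
`hasSupportGraphElement` / `hasChallengeGraphElement` triples are
optional on write and ignored on read (views stay query-derived).
Unknown-namespace triples about known elements are kept in an opaque
side-store and re-emitted. Term spellings follow the model's camel-case
names; any respelling against the published vocabulary file lives in the
single `TERMS` table. Text anchoring implements the Open-Annotation
exact-quote selector with a fixed-width context window (default 32
characters); offset selectors are out of scope.

## Fixtures and the synthetic generator

The fixture set reconstructs the worked case studies: a citable claim
with reference and semantic qualifiers; evidence with data and two
methods; an eleven-element digital abstract; a three-publication
resolution network; similarity-group, BEL-claim and annotation patterns;
the two challenge cases; and an eight-publication citation-distortion
network whose foundational claims are hypotheses with no data. Claim and
statement texts are the printed strings where printed; unverbalized
elements (e.g. image data) carry descriptive placeholders. In the
distortion network the representative-claim assertion is materialized as
a curator micropublication whose edge runs from the representative claim
to the fact-form claim, so lineage and grounding traversals descend
through the representative into the distorted chain; under the
similarity-group star convention this makes the fact-form claim the
group root. Each fixture ships as a golden Turtle file regenerated
byte-for-byte by the test suite.

The random generator emulates a literature of n publications: one claim
each, 1–3 supporting statements, data attached with probability
`p_data_support` (default 0.7) and a method behind each datum with
`p_method_per_data` (0.8), document-level references to earlier
publications, claim-level resolutions with `p_reference_resolution`
(0.5) and direct challenges with `p_challenge` (0.2); defaults chosen
once as a plausible mid-density citation web in which most, but not all,
claims are evidence-backed. It does **not** emulate real text (statement
strings are templated, so similarity scores on generated networks are
degenerate), real bibliometric degree distributions, or annotation
layers; passing tests on generated networks therefore demonstrate
structural correctness of merging, inference, grounding and
serialization — not text-similarity quality or realistic network
statistics. Identical seeds give identical networks, and every generated
micropublication is valid by construction.

## Numerical and procedural choices

- Tie-breaks: similog rankings sort by descending score, then IRI;
  traversals iterate sorted neighbours, making every analysis
  deterministic.
- Comparator degeneracy: two texts with no alphanumeric tokens score 1.0
  if equal as strings, else 0.0.
- Edge identity: an edge is (source, kind, target, asserting MP);
  re-adding an identical edge is a no-op, a (source, target) pair may
  never carry both kinds within one micropublication.
- An element present in both the asserted and quoted sets (possible only
  in foreign RDF) is reported under `KIND_VIOLATION` with an explanatory
  detail, keeping the violation-code set closed.
- Problem sizes: oracle-equivalence suites run 500 seeded random graphs
  of ≤ 12 nodes against brute-force path enumeration; round-trip suites
  cover all fixtures plus 200 seeded random networks of 6 publications;
  the acceptance script uses 200 oracle cases and 100 round-trip
  networks. These sizes keep the whole check desk-scale while exercising
  every code path.

## Known limitations

- No argumentation-acceptability semantics (grounded/preferred/stable
  extensions) — the model defines inference rules, not acceptability.
- No OWL reasoning over the published ontology, no SPARQL endpoint, no
  BEL parsing (BEL claims are opaque strings), no text mining of
  articles.
- Trust and weighting of attributions are out of scope; ethos is
  represented, not scored.
- Timestamps are carried but never compared.
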