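# micropub

Typed argument graphs for scientific claims, evidence and challenge.

Biomedical literature argues: a publication advances a principal claim,
backs it with statements paraphrasing earlier work, cites the works those
paraphrases come from, and ultimately rests on empirical data obtained by
reusable methods. Citation practice routinely loses this structure — a
citation points at a whole document, the reader takes the backing on
faith, and entire claim lineages can turn out to rest on no evidence at
all (citation distortion). `micropub` models the argument structure
explicitly so that it can be validated, queried and traced:

- **for knowledge-base curators and discourse annotators**: build and
  exchange formalized arguments (micropublications) as RDF;
- **for meta-researchers**: merge arguments into cross-publication claim
  networks and ask *on what grounds is this statement made?*;
- **for tool builders**: a typed Python API plus a small CLI.

## The model

A micropublication formalizes an argument text *a* as

```
MP_a = ⟨A_mpa, c, A_c, Φ, R⟩
```

where *c* is the single principal **claim**, *A_c* its attribution,
*A_mpa* the attribution of the formalization itself, Φ a finite non-empty
set of representation elements (claims, statements, qualifiers,
references, data, procedures, materials, attributions — partitioned into
*asserted* and *quoted*), and R = R⁺ ⊎ R⁻ a set of typed edges:
`supports` and `directlyChallenges`. Within one micropublication the
supports edges form a DAG whose greatest element is *c*; the elements
with a supports path to *c* are its **support graph** Φ⁺. The minimal
well-formed micropublication is a claim supported by its attribution.

Two inference rules drive the analyses:

- `supports` is **transitive** (closure computed on demand);
- *x* **challenges** *z* if it directly challenges *z*, or *undercuts*
  it: directlyChallenges(x, y) for some *y* with a supports path to *z*.

On merged networks the package derives claim lineages (chains of
citing/cited claims), empirical-grounding reports (does the ancestry of a
claim reach data backed by a method?), challenged-claim listings, and
similarity groups (similog claims represented by a holotype, themselves
materialized as micropublications). Everything reads and writes RDF
(Turtle and JSON-LD) in the `mp` vocabulary (`http://purl.org/mp#`), with
Open-Annotation exact-quote anchoring into source documents.

## Worked example

Merge the digital abstract of a rapamycin/Alzheimer study with the two
publications it cites, resolve the citations to claim level, and trace
the principal claim C3:

```python
from micropub import Attribution, Role, claim_lineage, grounding_report, merge, resolve_reference
from micropub import fixtures as fx

net = merge([fx.example("mp3_digital_abstract"),
             fx.example("mp4_harrison"), fx.example("mp5_hsia")])
attr = Attribution(id=f"{fx.BASE}/mp6#A_MP6", agent=fx.CURATOR.id, role=Role.CURATOR)
s1  = next(n for n in net.nodes    if n.endswith("#S1"))
c11 = next(c for c in net.claims() if c.endswith("#C1.1"))
resolve_reference(net, s1, c11, attr, into=f"{fx.BASE}/mp6")

c3 = next(c for c in net.claims() if c.endswith("#C3"))
for link in claim_lineage(net, c3).links:
    print(link.cited_claim.rsplit("#")[-1], "backs",
          link.citing_statement.rsplit("#")[-1])
report = grounding_report(net, c3)
print(report.grounded_by_data, report.grounded_by_method)
```

prints

```
C1.1 backs S1
True True
```

meaning: after resolution, the statement S1 ("rapamycin … an inhibitor of
the mTOR pathway …") is backed at claim level by C1.1 from the cited
publication rather than by an opaque document reference, and C3's support
ancestry reaches data (D1) that is itself supported by methods (M1, M2) —
the claim is empirically grounded. Running the same report on the
`greenberg` fixture (an eight-publication citation-distortion network)
returns `grounded_by_data = False` with a `NO_EVIDENCE_AT_ROOT` flag: its
foundational publications contain hypotheses, not data.

The `examples/` directory holds one short script per capability
(building/validation, inference views, networks and resolution,
grounding, similarity groups, RDF round-tripping, synthetic networks);
each prints what it computes and says what the numbers mean.

## Command line

```sh
micropub example mp3_digital_abstract        # fixture as Turtle
micropub ground greenberg --claim C11        # grounding report as JSON
micropub lineage example4_network --claim C3 --dot
micropub simulate --seed 7 --out net.ttl     # seeded synthetic network
micropub validate net.ttl                    # exit 1 if invalid
```

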