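"""Serialize to RDF (Turtle / JSON-LD), anchor to text, and parse back.

Output is deterministic (sorted triples), provenance is carried by
asserts/quotes properties plus content-addressed edge reifications, and
anchors follow the Open Annotation exact-quote selector.
"""

from micropub import anchor, from_rdf, to_rdf
from micropub import fixtures as fx

mp1 = fx.example("mp1_citable_claim")
article = ("We report that rapamycin is an inhibitor of the mTOR pathway "
           "in aged transgenic mice.")
a = anchor(mp1.claim, fx.DOC_SPILMAN,
           "rapamycin is an inhibitor of the mTOR pathway",
           context_window=16, document_text=article)
print("anchor verified:", a.verified, " prefix:", repr(a.prefix))

doc = to_rdf(mp1, syntax="turtle", materialize_views=True, anchors=[a])
print(f"turtle document: {len(doc.content.splitlines())} lines")
print("\n".join(line for line in doc.content.splitlines()
                if "hasSupportGraphElement" in line))
# the materialized support-graph view: Ref5 and A_C1

[back] = from_rdf(to_rdf(mp1, syntax="jsonld"))
print("JSON-LD round trip identical:",
      to_rdf(back).content == to_rdf(mp1).content)
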