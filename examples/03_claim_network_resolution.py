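"""Merge publications into a claim network and resolve citations.

Document-level references become claim-level supports edges, asserted by
a new annotation micropublication, giving claim lineages across
publications.
"""

from micropub import Attribution, Role, claim_lineage, merge, resolve_reference
from micropub import fixtures as fx


def local(iri):
    return iri.rsplit("#", 1)[-1]


net = merge([
    fx.example("mp3_digital_abstract"),
    fx.example("mp4_harrison"),
    fx.example("mp5_hsia"),
])
attr = Attribution(id=f"{fx.BASE}/mp6#A_MP6", agent=fx.CURATOR.id, role=Role.CURATOR)
s1 = next(n for n in net.nodes if local(n) == "S1")
c11 = next(c for c in net.claims() if local(c) == "C1.1")
resolve_reference(net, s1, c11, attr, into=f"{fx.BASE}/mp6")

c3 = next(c for c in net.claims() if local(c) == "C3")
lineage = claim_lineage(net, c3)
for link in lineage.links:
    print(f"{local(link.cited_claim)} backs {local(link.citing_statement)}"
          f" (via {link.via_mp.rsplit('/', 1)[-1]})")
# each line is one citing/cited hop of the claim lineage, with the
# micropublication that asserted the connection as provenance
print(lineage.to_dot())
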