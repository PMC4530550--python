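"""Similogs and similarity groups with a holotype claim.

Claims close in meaning form a similarity group represented by a
holotype; the group itself is materialized as a micropublication whose
support graph holds the members.
"""

from micropub import (
    Attribution, Role, build_similarity_group, merge, suggest_similogs,
    token_set_jaccard, validate,
)
from micropub import fixtures as fx


def local(iri):
    return iri.rsplit("#", 1)[-1]


net = merge([
    fx.example("mp1_citable_claim"),
    fx.example("mp3_digital_abstract"),
    fx.example("mp4_harrison"),
])
c1 = next(c for c in net.claims() if local(c) == "C1")
for claim, score in suggest_similogs(net, c1, threshold=0.15):
    print(f"similog candidate {local(claim)}: score {score:.3f}")
# token-set Jaccard against the query claim text; C1.1 is near-identical

attr = Attribution(id=f"{fx.BASE}/group#A", agent=fx.CURATOR.id, role=Role.CURATOR)
group = build_similarity_group(net, c1, {c for c, _ in
                                         suggest_similogs(net, c1, threshold=0.15)},
                               attr, comparator=token_set_jaccard, threshold=0.15)
print("holotype:", local(group.holotype),
      "members:", sorted(local(m) for m in group.members))
print("group micropublication valid:", validate(group.as_micropublication).is_valid)
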