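"""Support/challenge graphs and the inference rules.

supports is transitive; a representation challenges a claim directly or
by undercutting (directly challenging one of its supporters).
"""

from micropub import (
    fixtures, infer_challenges, support_graph, supports_closure, derived_flags,
)


def local(iri):
    return iri.rsplit("#", 1)[-1]


mp3 = fixtures.example("mp3_digital_abstract")
sg = support_graph(mp3)
print("support graph of C3:", sorted(local(n) for n in sg.nodes))
# the ten elements with a supports path to the principal claim

closure = supports_closure(mp3.relations)
print(f"base supports edges: {len(closure.base)}, after closure: {len(closure.closed)}")

s3 = next(i for i in mp3.phi if local(i) == "S3")
print("S3 flags:", derived_flags(s3, mp3.relations, mp3.elements))
# S3 interprets the data, so it is supportedByData (and the data has methods)

case1 = fixtures.example("mp8_challenge_case1")
challenges = infer_challenges(case1.edges)
print("inferred challenges:",
      sorted((local(a), local(b)) for a, b in challenges))
# C11 directly challenges S3 and, by undercutting, the claim S3 supports
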