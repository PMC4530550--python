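"""Build a micropublication from scratch and validate it.

The minimal formalized argument is one claim supported by its
attribution; here we extend it with a backing reference and data.
"""

from micropub import (
    Agent, Media, RelKind, RepKind, Representation,
    add_element, add_relation, elements_of, make_micropublication, validate,
)

author = Agent(id="http://example.org/agent/PSpilman", name="Patricia Spilman")
curator = Agent(id="http://example.org/agent/Curator", name="A Curator")

mp = make_micropublication(
    "rapamycin is an inhibitor of the mTOR pathway", author, curator
)
ref = Representation(id=mp.id + "#Ref5", rep_kind=RepKind.REFERENCE,
                     target="http://example.org/doc/harrison-2009")
data = Representation(id=mp.id + "#D1", rep_kind=RepKind.DATA,
                      media=Media("image/png", "http://example.org/media/fig2"),
                      text="Dose-response curves")
add_element(mp, ref)
add_element(mp, data)
add_relation(mp, ref.id, RelKind.SUPPORTS, mp.claim)
add_relation(mp, data.id, RelKind.SUPPORTS, mp.claim)

report = validate(mp)
print(f"elements in Phi: {len(elements_of(mp))}")   # claim, attribution, ref, data
print(f"relations:       {len(mp.relations)}")       # three supports edges
print(f"is_valid:        {report.is_valid}")
# A valid micropublication has a non-empty element set, a DAG of supports
# edges with the claim as greatest element, and an attributed claim.
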