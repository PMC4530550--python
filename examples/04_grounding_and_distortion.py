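"""Empirical grounding versus citation distortion.

A claim is grounded when its support ancestry reaches data obtained by a
reusable method; a lineage whose foundations hold no evidence is the
citation-distortion pattern.
"""

from micropub import grounding_report
from micropub import fixtures as fx


def local(iri):
    return iri.rsplit("#", 1)[-1]


evidence = fx.example("example4_network")
c3 = next(c for c in evidence.claims() if local(c) == "C3")
report = grounding_report(evidence, c3)
print("evidence network  grounded_by_data:", report.grounded_by_data,
      " grounded_by_method:", report.grounded_by_method)
print("  one evidence path:", " -> ".join(local(n) for n in report.evidence_paths[0]))

distorted = fx.example("greenberg")
c11 = next(c for c in distorted.claims() if local(c) == "C11")
report = grounding_report(distorted, c11, self_citation_check=True)
print("distorted network grounded_by_data:", report.grounded_by_data)
print("  flags:", sorted({f.code for f in report.distortion_flags}))
# NO_EVIDENCE_AT_ROOT: no data anywhere in the ancestry;
# SELF_CITATION_CHAIN: consecutive hops attributed to one laboratory
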