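@prefix mp: <http://purl.org/mp#> .
@prefix oa: <http://www.w3.org/ns/oa#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<http://example.org/micropub/agent/KBCurator> rdf:type mp:Person .
<http://example.org/micropub/agent/KBCurator> rdfs:label "KB Curator" .
<http://example.org/micropub/agent/PSpilman> rdf:type mp:Person .
<http://example.org/micropub/agent/PSpilman> rdfs:label "Patricia Spilman" .
<http://example.org/micropub/edge#0fc1a69626fe> mp:assertedBy <http://example.org/micropub/mp2> .
<http://example.org/micropub/edge#0fc1a69626fe> rdf:object <http://example.org/micropub/mp2#C3> .
<http://example.org/micropub/edge#0fc1a69626fe> rdf:predicate mp:supports .
<http://example.org/micropub/edge#0fc1a69626fe> rdf:subject <http://example.org/micropub/mp2#A_C3> .
<http://example.org/micropub/edge#0fc1a69626fe> rdf:type rdf:Statement .
<http://example.org/micropub/edge#3c32881a46ab> mp:assertedBy <http://example.org/micropub/mp2> .
<http://example.org/micropub/edge#3c32881a46ab> rdf:object <http://example.org/micropub/mp2#D1> .
<http://example.org/micropub/edge#3c32881a46ab> rdf:predicate mp:supports .
<http://example.org/micropub/edge#3c32881a46ab> rdf:subject <http://example.org/micropub/mp2#M1> .
<http://example.org/micropub/edge#3c32881a46ab> rdf:type rdf:Statement .
<http://example.org/micropub/edge#9e0a40653dca> mp:assertedBy <http://example.org/micropub/mp2> .
<http://example.org/micropub/edge#9e0a40653dca> rdf:object <http://example.org/micropub/mp2#C3> .
<http://example.org/micropub/edge#9e0a40653dca> rdf:predicate mp:supports .
<http://example.org/micropub/edge#9e0a40653dca> rdf:subject <http://example.org/micropub/mp2#D1> .
<http://example.org/micropub/edge#9e0a40653dca> rdf:type rdf:Statement .
<http://example.org/micropub/edge#ae8273177019> mp:assertedBy <http://example.org/micropub/mp2> .
<http://example.org/micropub/edge#ae8273177019> rdf:object <http://example.org/micropub/mp2#D1> .
<http://example.org/micropub/edge#ae8273177019> rdf:predicate mp:supports .
<http://example.org/micropub/edge#ae8273177019> rdf:subject <http://example.org/micropub/mp2#M2> .
<http://example.org/micropub/edge#ae8273177019> rdf:type rdf:Statement .
<http://example.org/micropub/mp2#A_C3> mp:attributionOfAgent <http://example.org/micropub/agent/PSpilman> .
<http://example.org/micropub/mp2#A_C3> mp:role "author" .
<http://example.org/micropub/mp2#A_C3> mp:supports <http://example.org/micropub/mp2#C3> .
<http://example.org/micropub/mp2#A_C3> rdf:type mp:Attribution .
<http://example.org/micropub/mp2#C3> rdf:type mp:Claim .
<http://example.org/micropub/mp2#C3> rdf:value "Inhibition of mTOR by rapamycin can slow or block AD progression in a transgenic mouse model of the disease" .
<http://example.org/micropub/mp2#D1> mp:locator "http://example.org/micropub/media/mp2-D1" .
<http://example.org/micropub/mp2#D1> mp:mediaType "image/composite" .
<http://example.org/micropub/mp2#D1> mp:supports <http://example.org/micropub/mp2#C3> .
<http://example.org/micropub/mp2#D1> rdf:type mp:Data .
<http://example.org/micropub/mp2#D1> rdf:value "Composite image of graphs produced from the primary data" .
<http://example.org/micropub/mp2#M1> mp:supports <http://example.org/micropub/mp2#D1> .
<http://example.org/micropub/mp2#M1> rdf:type mp:Procedure .
<http://example.org/micropub/mp2#M1> rdf:value "Rapamycin feeding protocol and Morris water maze protocol" .
<http://example.org/micropub/mp2#M2> mp:supports <http://example.org/micropub/mp2#D1> .
<http://example.org/micropub/mp2#M2> rdf:type mp:Material .
<http://example.org/micropub/mp2#M2> rdf:value "PDAPP transgenic mouse strain (J20 line)" .
<http://example.org/micropub/mp2#attr-mp> mp:attributionOfAgent <http://example.org/micropub/agent/KBCurator> .
<http://example.org/micropub/mp2#attr-mp> mp:role "curator" .
<http://example.org/micropub/mp2#attr-mp> rdf:type mp:Attribution .
<http://example.org/micropub/mp2> mp:argues <http://example.org/micropub/mp2#C3> .
<http://example.org/micropub/mp2> mp:asserts <http://example.org/micropub/mp2#A_C3> .
<http://example.org/micropub/mp2> mp:asserts <http://example.org/micropub/mp2#C3> .
<http://example.org/micropub/mp2> mp:asserts <http://example.org/micropub/mp2#D1> .
<http://example.org/micropub/mp2> mp:asserts <http://example.org/micropub/mp2#M1> .
<http://example.org/micropub/mp2> mp:asserts <http://example.org/micropub/mp2#M2> .
<http://example.org/micropub/mp2> mp:hasAttribution <http://example.org/micropub/mp2#attr-mp> .
<http://example.org/micropub/mp2> mp:sourceDocument <http://example.org/micropub/doc/spilman-2010> .
<http://example.org/micropub/mp2> rdf:type mp:Micropublication .
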