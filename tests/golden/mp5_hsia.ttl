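@prefix mp: <http://purl.org/mp#> .
@prefix oa: <http://www.w3.org/ns/oa#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<http://example.org/micropub/agent/AHsia> rdf:type mp:Person .
<http://example.org/micropub/agent/AHsia> rdfs:label "Albert Hsia" .
<http://example.org/micropub/agent/KBCurator> rdf:type mp:Person .
<http://example.org/micropub/agent/KBCurator> rdfs:label "KB Curator" .
<http://example.org/micropub/edge#52b60b70ef92> mp:assertedBy <http://example.org/micropub/mp5> .
<http://example.org/micropub/edge#52b60b70ef92> rdf:object <http://example.org/micropub/mp5#C2.1> .
<http://example.org/micropub/edge#52b60b70ef92> rdf:predicate mp:supports .
<http://example.org/micropub/edge#52b60b70ef92> rdf:subject <http://example.org/micropub/mp5#D2.1> .
<http://example.org/micropub/edge#52b60b70ef92> rdf:type rdf:Statement .
<http://example.org/micropub/edge#5947f25561f0> mp:assertedBy <http://example.org/micropub/mp5> .
<http://example.org/micropub/edge#5947f25561f0> rdf:object <http://example.org/micropub/mp5#D2.1> .
<http://example.org/micropub/edge#5947f25561f0> rdf:predicate mp:supports .
<http://example.org/micropub/edge#5947f25561f0> rdf:subject <http://example.org/micropub/mp5#M2.1> .
<http://example.org/micropub/edge#5947f25561f0> rdf:type rdf:Statement .
<http://example.org/micropub/edge#7a31e50f62a5> mp:assertedBy <http://example.org/micropub/mp5> .
<http://example.org/micropub/edge#7a31e50f62a5> rdf:object <http://example.org/micropub/mp5#C2.1> .
<http://example.org/micropub/edge#7a31e50f62a5> rdf:predicate mp:supports .
<http://example.org/micropub/edge#7a31e50f62a5> rdf:subject <http://example.org/micropub/mp5#A_C2.1> .
<http://example.org/micropub/edge#7a31e50f62a5> rdf:type rdf:Statement .
<http://example.org/micropub/mp5#A_C2.1> mp:attributionOfAgent <http://example.org/micropub/agent/AHsia> .
<http://example.org/micropub/mp5#A_C2.1> mp:role "author" .
<http://example.org/micropub/mp5#A_C2.1> mp:supports <http://example.org/micropub/mp5#C2.1> .
<http://example.org/micropub/mp5#A_C2.1> rdf:type mp:Attribution .
<http://example.org/micropub/mp5#C2.1> rdf:type mp:Claim .
<http://example.org/micropub/mp5#C2.1> rdf:value "… addition of the Swedish FAD mutation to the APP transgene in a second line of mice, further increased synaptic transmission deficits in young APP mice without plaques" .
<http://example.org/micropub/mp5#D2.1> mp:locator "http://example.org/micropub/media/mp5-D2.1" .
<http://example.org/micropub/mp5#D2.1> mp:mediaType "image/figure" .
<http://example.org/micropub/mp5#D2.1> mp:supports <http://example.org/micropub/mp5#C2.1> .
<http://example.org/micropub/mp5#D2.1> rdf:type mp:Data .
<http://example.org/micropub/mp5#D2.1> rdf:value "Electrophysiology data from APP transgenic mice" .
<http://example.org/micropub/mp5#M2.1> mp:supports <http://example.org/micropub/mp5#D2.1> .
<http://example.org/micropub/mp5#M2.1> rdf:type mp:Material .
<http://example.org/micropub/mp5#M2.1> rdf:value "APP transgenic mouse lines carrying the Swedish FAD mutation" .
<http://example.org/micropub/mp5#attr-mp> mp:attributionOfAgent <http://example.org/micropub/agent/KBCurator> .
<http://example.org/micropub/mp5#attr-mp> mp:role "curator" .
<http://example.org/micropub/mp5#attr-mp> rdf:type mp:Attribution .
<http://example.org/micropub/mp5> mp:argues <http://example.org/micropub/mp5#C2.1> .
<http://example.org/micropub/mp5> mp:asserts <http://example.org/micropub/mp5#A_C2.1> .
<http://example.org/micropub/mp5> mp:asserts <http://example.org/micropub/mp5#C2.1> .
<http://example.org/micropub/mp5> mp:asserts <http://example.org/micropub/mp5#D2.1> .
<http://example.org/micropub/mp5> mp:asserts <http://example.org/micropub/mp5#M2.1> .
<http://example.org/micropub/mp5> mp:hasAttribution <http://example.org/micropub/mp5#attr-mp> .
<http://example.org/micropub/mp5> mp:sourceDocument <http://example.org/micropub/doc/hsia-1999> .
<http://example.org/micropub/mp5> rdf:type mp:Micropublication .
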