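@prefix mp: <http://purl.org/mp#> .
@prefix oa: <http://www.w3.org/ns/oa#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<http://example.org/micropub/agent/DHarrison> rdf:type mp:Person .
<http://example.org/micropub/agent/DHarrison> rdfs:label "David Harrison" .
<http://example.org/micropub/agent/KBCurator> rdf:type mp:Person .
<http://example.org/micropub/agent/KBCurator> rdfs:label "KB Curator" .
<http://example.org/micropub/edge#025e0aaabb38> mp:assertedBy <http://example.org/micropub/mp4> .
<http://example.org/micropub/edge#025e0aaabb38> rdf:object <http://example.org/micropub/mp4#D1.1> .
<http://example.org/micropub/edge#025e0aaabb38> rdf:predicate mp:supports .
<http://example.org/micropub/edge#025e0aaabb38> rdf:subject <http://example.org/micropub/mp4#M1.1> .
<http://example.org/micropub/edge#025e0aaabb38> rdf:type rdf:Statement .
<http://example.org/micropub/edge#d1252975715d> mp:assertedBy <http://example.org/micropub/mp4> .
<http://example.org/micropub/edge#d1252975715d> rdf:object <http://example.org/micropub/mp4#C1.1> .
<http://example.org/micropub/edge#d1252975715d> rdf:predicate mp:supports .
<http://example.org/micropub/edge#d1252975715d> rdf:subject <http://example.org/micropub/mp4#A_C1.1> .
<http://example.org/micropub/edge#d1252975715d> rdf:type rdf:Statement .
<http://example.org/micropub/edge#ee38e5e15d2b> mp:assertedBy <http://example.org/micropub/mp4> .
<http://example.org/micropub/edge#ee38e5e15d2b> rdf:object <http://example.org/micropub/mp4#C1.1> .
<http://example.org/micropub/edge#ee38e5e15d2b> rdf:predicate mp:supports .
<http://example.org/micropub/edge#ee38e5e15d2b> rdf:subject <http://example.org/micropub/mp4#D1.1> .
<http://example.org/micropub/edge#ee38e5e15d2b> rdf:type rdf:Statement .
<http://example.org/micropub/mp4#A_C1.1> mp:attributionOfAgent <http://example.org/micropub/agent/DHarrison> .
<http://example.org/micropub/mp4#A_C1.1> mp:role "author" .
<http://example.org/micropub/mp4#A_C1.1> mp:supports <http://example.org/micropub/mp4#C1.1> .
<http://example.org/micropub/mp4#A_C1.1> rdf:type mp:Attribution .
<http://example.org/micropub/mp4#C1.1> rdf:type mp:Claim .
<http://example.org/micropub/mp4#C1.1> rdf:value "rapamycin … an inhibitor of the mTOR pathway …" .
<http://example.org/micropub/mp4#D1.1> mp:locator "http://example.org/micropub/media/mp4-D1.1" .
<http://example.org/micropub/mp4#D1.1> mp:mediaType "image/figure" .
<http://example.org/micropub/mp4#D1.1> mp:supports <http://example.org/micropub/mp4#C1.1> .
<http://example.org/micropub/mp4#D1.1> rdf:type mp:Data .
<http://example.org/micropub/mp4#D1.1> rdf:value "Survival and mTOR-signalling data from rapamycin-fed mice" .
<http://example.org/micropub/mp4#M1.1> mp:supports <http://example.org/micropub/mp4#D1.1> .
<http://example.org/micropub/mp4#M1.1> rdf:type mp:Procedure .
<http://example.org/micropub/mp4#M1.1> rdf:value "Encapsulated rapamycin feeding protocol" .
<http://example.org/micropub/mp4#attr-mp> mp:attributionOfAgent <http://example.org/micropub/agent/KBCurator> .
<http://example.org/micropub/mp4#attr-mp> mp:role "curator" .
<http://example.org/micropub/mp4#attr-mp> rdf:type mp:Attribution .
<http://example.org/micropub/mp4> mp:argues <http://example.org/micropub/mp4#C1.1> .
<http://example.org/micropub/mp4> mp:asserts <http://example.org/micropub/mp4#A_C1.1> .
<http://example.org/micropub/mp4> mp:asserts <http://example.org/micropub/mp4#C1.1> .
<http://example.org/micropub/mp4> mp:asserts <http://example.org/micropub/mp4#D1.1> .
<http://example.org/micropub/mp4> mp:asserts <http://example.org/micropub/mp4#M1.1> .
<http://example.org/micropub/mp4> mp:hasAttribution <http://example.org/micropub/mp4#attr-mp> .
<http://example.org/micropub/mp4> mp:sourceDocument <http://example.org/micropub/doc/harrison-2009> .
<http://example.org/micropub/mp4> rdf:type mp:Micropublication .
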