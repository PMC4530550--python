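@prefix mp: <http://purl.org/mp#> .
@prefix oa: <http://www.w3.org/ns/oa#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<http://example.org/micropub/agent/DPratt> rdf:type mp:Person .
<http://example.org/micropub/agent/DPratt> rdfs:label "Dexter Pratt" .
<http://example.org/micropub/edge#533ca890b0ae> mp:assertedBy <http://example.org/micropub/mp7-bel> .
<http://example.org/micropub/edge#533ca890b0ae> rdf:object <http://example.org/micropub/mp7-bel#C7> .
<http://example.org/micropub/edge#533ca890b0ae> rdf:predicate mp:supports .
<http://example.org/micropub/edge#533ca890b0ae> rdf:subject <http://example.org/micropub/mp7-bel#A_C7> .
<http://example.org/micropub/edge#533ca890b0ae> rdf:type rdf:Statement .
<http://example.org/micropub/edge#ffa0717152e1> mp:assertedBy <http://example.org/micropub/mp7-bel> .
<http://example.org/micropub/edge#ffa0717152e1> rdf:object <http://example.org/micropub/mp7-bel#C7> .
<http://example.org/micropub/edge#ffa0717152e1> rdf:predicate mp:supports .
<http://example.org/micropub/edge#ffa0717152e1> rdf:subject <http://example.org/micropub/mp7-bel#Ref96> .
<http://example.org/micropub/edge#ffa0717152e1> rdf:type rdf:Statement .
<http://example.org/micropub/mp7-bel#A_C7> mp:attributionOfAgent <http://example.org/micropub/agent/DPratt> .
<http://example.org/micropub/mp7-bel#A_C7> mp:role "author" .
<http://example.org/micropub/mp7-bel#A_C7> mp:supports <http://example.org/micropub/mp7-bel#C7> .
<http://example.org/micropub/mp7-bel#A_C7> rdf:type mp:Attribution .
<http://example.org/micropub/mp7-bel#C7> rdf:type mp:Claim .
<http://example.org/micropub/mp7-bel#C7> rdf:value "a(CHEBI:9168) =| kin(p(HGNC:FRAP1))" .
<http://example.org/micropub/mp7-bel#Ref96> mp:refersTo "PMID:12030785" .
<http://example.org/micropub/mp7-bel#Ref96> mp:supports <http://example.org/micropub/mp7-bel#C7> .
<http://example.org/micropub/mp7-bel#Ref96> rdf:type mp:Reference .
<http://example.org/micropub/mp7-bel#attr-mp> mp:attributionOfAgent <http://example.org/micropub/agent/DPratt> .
<http://example.org/micropub/mp7-bel#attr-mp> mp:role "curator" .
<http://example.org/micropub/mp7-bel#attr-mp> rdf:type mp:Attribution .
<http://example.org/micropub/mp7-bel> mp:argues <http://example.org/micropub/mp7-bel#C7> .
<http://example.org/micropub/mp7-bel> mp:asserts <http://example.org/micropub/mp7-bel#A_C7> .
<http://example.org/micropub/mp7-bel> mp:asserts <http://example.org/micropub/mp7-bel#C7> .
<http://example.org/micropub/mp7-bel> mp:asserts <http://example.org/micropub/mp7-bel#Ref96> .
<http://example.org/micropub/mp7-bel> mp:hasAttribution <http://example.org/micropub/mp7-bel#attr-mp> .
<http://example.org/micropub/mp7-bel> rdf:type mp:Micropublication .
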