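@prefix mp: <http://purl.org/mp#> .
@prefix oa: <http://www.w3.org/ns/oa#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<http://example.org/micropub/agent/KBCurator> rdf:type mp:Person .
<http://example.org/micropub/agent/KBCurator> rdfs:label "KB Curator" .
<http://example.org/micropub/agent/PSpilman> rdf:type mp:Person .
<http://example.org/micropub/agent/PSpilman> rdfs:label "Patricia Spilman" .
<http://example.org/micropub/edge#285ac8e64f73> mp:assertedBy <http://example.org/micropub/mp1> .
<http://example.org/micropub/edge#285ac8e64f73> rdf:object <http://example.org/micropub/mp1#C1> .
<http://example.org/micropub/edge#285ac8e64f73> rdf:predicate mp:supports .
<http://example.org/micropub/edge#285ac8e64f73> rdf:subject <http://example.org/micropub/mp1#A_C1> .
<http://example.org/micropub/edge#285ac8e64f73> rdf:type rdf:Statement .
<http://example.org/micropub/edge#c79620349e79> mp:assertedBy <http://example.org/micropub/mp1> .
<http://example.org/micropub/edge#c79620349e79> rdf:object <http://example.org/micropub/mp1#C1> .
<http://example.org/micropub/edge#c79620349e79> rdf:predicate mp:supports .
<http://example.org/micropub/edge#c79620349e79> rdf:subject <http://example.org/micropub/mp1#Ref5> .
<http://example.org/micropub/edge#c79620349e79> rdf:type rdf:Statement .
<http://example.org/micropub/mp1#A_C1> mp:attributionOfAgent <http://example.org/micropub/agent/PSpilman> .
<http://example.org/micropub/mp1#A_C1> mp:role "author" .
<http://example.org/micropub/mp1#A_C1> mp:supports <http://example.org/micropub/mp1#C1> .
<http://example.org/micropub/mp1#A_C1> rdf:type mp:Attribution .
<http://example.org/micropub/mp1#C1> mp:qualifiedBy <http://example.org/micropub/mp1#Q1> .
<http://example.org/micropub/mp1#C1> mp:qualifiedBy <http://example.org/micropub/mp1#Q2> .
<http://example.org/micropub/mp1#C1> rdf:type mp:Claim .
<http://example.org/micropub/mp1#C1> rdf:value "rapamycin is an inhibitor of the mTOR pathway" .
<http://example.org/micropub/mp1#Q1> mp:hasTerm <http://purl.obolibrary.org/obo/CHEBI_9168> .
<http://example.org/micropub/mp1#Q1> rdf:type mp:SemanticQualifier .
<http://example.org/micropub/mp1#Q2> mp:hasTerm <http://purl.obolibrary.org/obo/INO_0000736> .
<http://example.org/micropub/mp1#Q2> rdf:type mp:SemanticQualifier .
<http://example.org/micropub/mp1#Ref5> mp:refersTo "http://example.org/micropub/doc/harrison-2009" .
<http://example.org/micropub/mp1#Ref5> mp:supports <http://example.org/micropub/mp1#C1> .
<http://example.org/micropub/mp1#Ref5> rdf:type mp:Reference .
<http://example.org/micropub/mp1#attr-mp> mp:attributionOfAgent <http://example.org/micropub/agent/KBCurator> .
<http://example.org/micropub/mp1#attr-mp> mp:role "curator" .
<http://example.org/micropub/mp1#attr-mp> rdf:type mp:Attribution .
<http://example.org/micropub/mp1> mp:argues <http://example.org/micropub/mp1#C1> .
<http://example.org/micropub/mp1> mp:asserts <http://example.org/micropub/mp1#A_C1> .
<http://example.org/micropub/mp1> mp:asserts <http://example.org/micropub/mp1#C1> .
<http://example.org/micropub/mp1> mp:asserts <http://example.org/micropub/mp1#Q1> .
<http://example.org/micropub/mp1> mp:asserts <http://example.org/micropub/mp1#Q2> .
<http://example.org/micropub/mp1> mp:asserts <http://example.org/micropub/mp1#Ref5> .
<http://example.org/micropub/mp1> mp:hasAttribution <http://example.org/micropub/mp1#attr-mp> .
<http://example.org/micropub/mp1> mp:sourceDocument <http://example.org/micropub/doc/spilman-2010> .
<http://example.org/micropub/mp1> rdf:type mp:Micropublication .
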