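@prefix mp: <http://purl.org/mp#> .
@prefix oa: <http://www.w3.org/ns/oa#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<http://example.org/micropub/agent/ANeuroscientist> rdf:type mp:Person .
<http://example.org/micropub/agent/ANeuroscientist> rdfs:label "A. Neuroscientist" .
<http://example.org/micropub/edge#37754298a61e> mp:assertedBy <http://example.org/micropub/mp10> .
<http://example.org/micropub/edge#37754298a61e> rdf:object <http://example.org/micropub/mp10#C10> .
<http://example.org/micropub/edge#37754298a61e> rdf:predicate mp:supports .
<http://example.org/micropub/edge#37754298a61e> rdf:subject <http://example.org/micropub/mp10#A_C10> .
<http://example.org/micropub/edge#37754298a61e> rdf:type rdf:Statement .
<http://example.org/micropub/edge#ec23aabd03cb> mp:assertedBy <http://example.org/micropub/mp10> .
<http://example.org/micropub/edge#ec23aabd03cb> rdf:object <http://example.org/micropub/mp10#C10> .
<http://example.org/micropub/edge#ec23aabd03cb> rdf:predicate mp:supports .
<http://example.org/micropub/edge#ec23aabd03cb> rdf:subject <http://example.org/micropub/mp1#C1> .
<http://example.org/micropub/edge#ec23aabd03cb> rdf:type rdf:Statement .
<http://example.org/micropub/mp1#C1> mp:supports <http://example.org/micropub/mp10#C10> .
<http://example.org/micropub/mp1#C1> rdf:type mp:Claim .
<http://example.org/micropub/mp1#C1> rdf:value "rapamycin is an inhibitor of the mTOR pathway" .
<http://example.org/micropub/mp10#A_C10> mp:attributionOfAgent <http://example.org/micropub/agent/ANeuroscientist> .
<http://example.org/micropub/mp10#A_C10> mp:role "author" .
<http://example.org/micropub/mp10#A_C10> mp:supports <http://example.org/micropub/mp10#C10> .
<http://example.org/micropub/mp10#A_C10> rdf:type mp:Attribution .
<http://example.org/micropub/mp10#C10> rdf:type mp:Claim .
<http://example.org/micropub/mp10#C10> rdf:value "The Spilman result suggests rapamycin analogues are worth investigating as therapeutic agents for human AD" .
<http://example.org/micropub/mp10#attr-mp> mp:attributionOfAgent <http://example.org/micropub/agent/ANeuroscientist> .
<http://example.org/micropub/mp10#attr-mp> mp:role "curator" .
<http://example.org/micropub/mp10#attr-mp> rdf:type mp:Attribution .
<http://example.org/micropub/mp10> mp:argues <http://example.org/micropub/mp10#C10> .
<http://example.org/micropub/mp10> mp:asserts <http://example.org/micropub/mp10#A_C10> .
<http://example.org/micropub/mp10> mp:asserts <http://example.org/micropub/mp10#C10> .
<http://example.org/micropub/mp10> mp:hasAttribution <http://example.org/micropub/mp10#attr-mp> .
<http://example.org/micropub/mp10> mp:quotes <http://example.org/micropub/mp1#C1> .
<http://example.org/micropub/mp10> rdf:type mp:Micropublication .
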