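@prefix mp: <http://purl.org/mp#> .
@prefix oa: <http://www.w3.org/ns/oa#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<http://example.org/micropub/edge#08baeb51bb94> mp:assertedBy <http://example.org/micropub/mp7-similarity> .
<http://example.org/micropub/edge#08baeb51bb94> rdf:object <http://example.org/micropub/pub-c4#C4> .
<http://example.org/micropub/edge#08baeb51bb94> rdf:predicate mp:supports .
<http://example.org/micropub/edge#08baeb51bb94> rdf:subject <http://example.org/micropub/mp3#C3> .
<http://example.org/micropub/edge#08baeb51bb94> rdf:type rdf:Statement .
<http://example.org/micropub/edge#27804721c303> mp:assertedBy <http://example.org/micropub/mp7-similarity> .
<http://example.org/micropub/edge#27804721c303> rdf:object <http://example.org/micropub/pub-c4#C4> .
<http://example.org/micropub/edge#27804721c303> rdf:predicate mp:supports .
<http://example.org/micropub/edge#27804721c303> rdf:subject <http://example.org/micropub/mp4#C1.1> .
<http://example.org/micropub/edge#27804721c303> rdf:type rdf:Statement .
<http://example.org/micropub/edge#51acca801434> mp:assertedBy <http://example.org/micropub/mp7-similarity> .
<http://example.org/micropub/edge#51acca801434> rdf:object <http://example.org/micropub/pub-c4#C4> .
<http://example.org/micropub/edge#51acca801434> rdf:predicate mp:supports .
<http://example.org/micropub/edge#51acca801434> rdf:subject <http://example.org/micropub/pub-c5#C5> .
<http://example.org/micropub/edge#51acca801434> rdf:type rdf:Statement .
<http://example.org/micropub/edge#e244b58bfb76> mp:assertedBy <http://example.org/micropub/mp7-similarity> .
<http://example.org/micropub/edge#e244b58bfb76> rdf:object <http://example.org/micropub/pub-c4#C4> .
<http://example.org/micropub/edge#e244b58bfb76> rdf:predicate mp:supports .
<http://example.org/micropub/edge#e244b58bfb76> rdf:subject <http://example.org/micropub/pub-c6#C6> .
<http://example.org/micropub/edge#e244b58bfb76> rdf:type rdf:Statement .
<http://example.org/micropub/edge#ecfa02c1d6ae> mp:assertedBy <http://example.org/micropub/mp7-similarity> .
<http://example.org/micropub/edge#ecfa02c1d6ae> rdf:object <http://example.org/micropub/pub-c4#C4> .
<http://example.org/micropub/edge#ecfa02c1d6ae> rdf:predicate mp:supports .
<http://example.org/micropub/edge#ecfa02c1d6ae> rdf:subject <http://example.org/micropub/mp7-similarity#A_MP7> .
<http://example.org/micropub/edge#ecfa02c1d6ae> rdf:type rdf:Statement .
<http://example.org/micropub/mp3#C3> mp:supports <http://example.org/micropub/pub-c4#C4> .
<http://example.org/micropub/mp3#C3> rdf:type mp:Claim .
<http://example.org/micropub/mp3#C3> rdf:value "Inhibition of mTOR by rapamycin can slow or block AD progression in a transgenic mouse model of the disease" .
<http://example.org/micropub/mp4#C1.1> mp:supports <http://example.org/micropub/pub-c4#C4> .
<http://example.org/micropub/mp4#C1.1> rdf:type mp:Claim .
<http://example.org/micropub/mp4#C1.1> rdf:value "rapamycin … an inhibitor of the mTOR pathway …" .
<http://example.org/micropub/mp7-similarity#A_MP7> mp:attributionOfAgent <http://example.org/micropub/agent/KBCurator> .
<http://example.org/micropub/mp7-similarity#A_MP7> mp:role "curator" .
<http://example.org/micropub/mp7-similarity#A_MP7> mp:supports <http://example.org/micropub/pub-c4#C4> .
<http://example.org/micropub/mp7-similarity#A_MP7> rdf:type mp:Attribution .
<http://example.org/micropub/mp7-similarity> mp:argues <http://example.org/micropub/pub-c4#C4> .
<http://example.org/micropub/mp7-similarity> mp:asserts <http://example.org/micropub/mp7-similarity#A_MP7> .
<http://example.org/micropub/mp7-similarity> mp:hasAttribution <http://example.org/micropub/mp7-similarity#A_MP7> .
<http://example.org/micropub/mp7-similarity> mp:quotes <http://example.org/micropub/mp3#C3> .
<http://example.org/micropub/mp7-similarity> mp:quotes <http://example.org/micropub/mp4#C1.1> .
<http://example.org/micropub/mp7-similarity> mp:quotes <http://example.org/micropub/pub-c4#C4> .
<http://example.org/micropub/mp7-similarity> mp:quotes <http://example.org/micropub/pub-c5#C5> .
<http://example.org/micropub/mp7-similarity> mp:quotes <http://example.org/micropub/pub-c6#C6> .
<http://example.org/micropub/mp7-similarity> rdf:type mp:Micropublication .
<http://example.org/micropub/pub-c4#C4> rdf:type mp:Claim .
<http://example.org/micropub/pub-c4#C4> rdf:value "Rapamycin directly inhibits the mTOR kinase" .
<http://example.org/micropub/pub-c5#C5> mp:supports <http://example.org/micropub/pub-c4#C4> .
<http://example.org/micropub/pub-c5#C5> rdf:type mp:Claim .
<http://example.org/micropub/pub-c5#C5> rdf:value "Rapamycin blocks mTOR signalling in mammalian cells" .
<http://example.org/micropub/pub-c6#C6> mp:supports <http://example.org/micropub/pub-c4#C4> .
<http://example.org/micropub/pub-c6#C6> rdf:type mp:Claim .
<http://example.org/micropub/pub-c6#C6> rdf:value "RAFT1 … binds FKBP12-rapamycin and mediates its inhibitory action" .
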