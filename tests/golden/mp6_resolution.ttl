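@prefix mp: <http://purl.org/mp#> .
@prefix oa: <http://www.w3.org/ns/oa#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<http://example.org/micropub/doc/harrison-2009> rdf:type mp:ArticleText .
<http://example.org/micropub/doc/hsia-1999> rdf:type mp:ArticleText .
<http://example.org/micropub/edge#0ec889e61118> mp:assertedBy <http://example.org/micropub/mp6> .
<http://example.org/micropub/edge#0ec889e61118> rdf:object <http://example.org/micropub/mp6#claim> .
<http://example.org/micropub/edge#0ec889e61118> rdf:predicate mp:supports .
<http://example.org/micropub/edge#0ec889e61118> rdf:subject <http://example.org/micropub/mp6#attr-claim> .
<http://example.org/micropub/edge#0ec889e61118> rdf:type rdf:Statement .
<http://example.org/micropub/edge#157f15bc547c> mp:assertedBy <http://example.org/micropub/mp6> .
<http://example.org/micropub/edge#157f15bc547c> rdf:object <http://example.org/micropub/doc/hsia-1999> .
<http://example.org/micropub/edge#157f15bc547c> rdf:predicate mp:supports .
<http://example.org/micropub/edge#157f15bc547c> rdf:subject <http://example.org/micropub/mp3#Ref10> .
<http://example.org/micropub/edge#157f15bc547c> rdf:type rdf:Statement .
<http://example.org/micropub/edge#1767e572c828> mp:assertedBy <http://example.org/micropub/mp6> .
<http://example.org/micropub/edge#1767e572c828> rdf:object <http://example.org/micropub/mp3#S2> .
<http://example.org/micropub/edge#1767e572c828> rdf:predicate mp:supports .
<http://example.org/micropub/edge#1767e572c828> rdf:subject <http://example.org/micropub/mp5#C2.1> .
<http://example.org/micropub/edge#1767e572c828> rdf:type rdf:Statement .
<http://example.org/micropub/edge#7c6ab6e2d850> mp:assertedBy <http://example.org/micropub/mp6> .
<http://example.org/micropub/edge#7c6ab6e2d850> rdf:object <http://example.org/micropub/mp3#S1> .
<http://example.org/micropub/edge#7c6ab6e2d850> rdf:predicate mp:supports .
<http://example.org/micropub/edge#7c6ab6e2d850> rdf:subject <http://example.org/micropub/mp4#C1.1> .
<http://example.org/micropub/edge#7c6ab6e2d850> rdf:type rdf:Statement .
<http://example.org/micropub/edge#88f3f9f1120e> mp:assertedBy <http://example.org/micropub/mp6> .
<http://example.org/micropub/edge#88f3f9f1120e> rdf:object <http://example.org/micropub/doc/harrison-2009> .
<http://example.org/micropub/edge#88f3f9f1120e> rdf:predicate mp:supports .
<http://example.org/micropub/edge#88f3f9f1120e> rdf:subject <http://example.org/micropub/mp3#Ref5> .
<http://example.org/micropub/edge#88f3f9f1120e> rdf:type rdf:Statement .
<http://example.org/micropub/mp3#C3> rdf:type mp:Claim .
<http://example.org/micropub/mp3#C3> rdf:value "Inhibition of mTOR by rapamycin can slow or block AD progression in a transgenic mouse model of the disease" .
<http://example.org/micropub/mp3#Ref10> mp:refersTo "http://example.org/micropub/doc/hsia-1999" .
<http://example.org/micropub/mp3#Ref10> mp:supports <http://example.org/micropub/doc/hsia-1999> .
<http://example.org/micropub/mp3#Ref10> rdf:type mp:Reference .
<http://example.org/micropub/mp3#Ref5> mp:refersTo "http://example.org/micropub/doc/harrison-2009" .
<http://example.org/micropub/mp3#Ref5> mp:supports <http://example.org/micropub/doc/harrison-2009> .
<http://example.org/micropub/mp3#Ref5> rdf:type mp:Reference .
<http://example.org/micropub/mp3#S1> rdf:type mp:Statement .
<http://example.org/micropub/mp3#S1> rdf:value "rapamycin … an inhibitor of the mTOR pathway …" .
<http://example.org/micropub/mp3#S2> rdf:type mp:Statement .
<http://example.org/micropub/mp3#S2> rdf:value "PDAPP mice accumulate soluble and deposited Aβ and develop AD-like synaptic deficits as well as cognitive impairment and hippocampal atrophy" .
<http://example.org/micropub/mp4#C1.1> mp:supports <http://example.org/micropub/mp3#S1> .
<http://example.org/micropub/mp4#C1.1> rdf:type mp:Claim .
<http://example.org/micropub/mp4#C1.1> rdf:value "rapamycin … an inhibitor of the mTOR pathway …" .
<http://example.org/micropub/mp5#C2.1> mp:supports <http://example.org/micropub/mp3#S2> .
<http://example.org/micropub/mp5#C2.1> rdf:type mp:Claim .
<http://example.org/micropub/mp5#C2.1> rdf:value "… addition of the Swedish FAD mutation to the APP transgene in a second line of mice, further increased synaptic transmission deficits in young APP mice without plaques" .
<http://example.org/micropub/mp6#A_MP6> mp:attributionOfAgent <http://example.org/micropub/agent/KBCurator> .
<http://example.org/micropub/mp6#A_MP6> mp:role "curator" .
<http://example.org/micropub/mp6#A_MP6> rdf:type mp:Attribution .
<http://example.org/micropub/mp6#attr-claim> mp:attributionOfAgent <http://example.org/micropub/agent/KBCurator> .
<http://example.org/micropub/mp6#attr-claim> mp:role "curator" .
<http://example.org/micropub/mp6#attr-claim> mp:supports <http://example.org/micropub/mp6#claim> .
<http://example.org/micropub/mp6#attr-claim> rdf:type mp:Attribution .
<http://example.org/micropub/mp6#claim> rdf:type mp:Claim .
<http://example.org/micropub/mp6#claim> rdf:value "Resolution of document-level citations to claim-level support for statements of mp3" .
<http://example.org/micropub/mp6> mp:argues <http://example.org/micropub/mp6#claim> .
<http://example.org/micropub/mp6> mp:asserts <http://example.org/micropub/mp6#attr-claim> .
<http://example.org/micropub/mp6> mp:asserts <http://example.org/micropub/mp6#claim> .
<http://example.org/micropub/mp6> mp:hasAttribution <http://example.org/micropub/mp6#A_MP6> .
<http://example.org/micropub/mp6> mp:quotes <http://example.org/micropub/doc/harrison-2009> .
<http://example.org/micropub/mp6> mp:quotes <http://example.org/micropub/doc/hsia-1999> .
<http://example.org/micropub/mp6> mp:quotes <http://example.org/micropub/mp3#C3> .
<http://example.org/micropub/mp6> mp:quotes <http://example.org/micropub/mp3#Ref10> .
<http://example.org/micropub/mp6> mp:quotes <http://example.org/micropub/mp3#Ref5> .
<http://example.org/micropub/mp6> mp:quotes <http://example.org/micropub/mp3#S1> .
<http://example.org/micropub/mp6> mp:quotes <http://example.org/micropub/mp3#S2> .
<http://example.org/micropub/mp6> mp:quotes <http://example.org/micropub/mp4#C1.1> .
<http://example.org/micropub/mp6> mp:quotes <http://example.org/micropub/mp5#C2.1> .
<http://example.org/micropub/mp6> rdf:type mp:Micropublication .
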