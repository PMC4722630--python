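# All clinical-finding instances with their entity class and kind.
PREFIX rs: <https://w3id.org/radsize/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?f ?fid ?ecls ?kind WHERE {
  ?f a rs:ClinicalFinding ;
     rs:findingId ?fid ;
     rs:entityKind ?kind ;
     rs:isAbout ?ent .
  ?ent a ?ecls .
  FILTER(STRSTARTS(STR(?ecls), "https://w3id.org/radsize/anatomy/"))
}
ORDER BY ?fid
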