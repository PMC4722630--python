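# Non-dominated normal-size specifications applicable to the bound
# entity class ?e and quality class ?q: the spec's entity/quality must
# subsume the queried pair, and no other spec may sit strictly between
# them on the entity path while staying on the quality path.
PREFIX rs: <https://w3id.org/radsize/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?spec ?eprime ?qprime WHERE {
  ?spec a rs:NormalSizeSpecification ;
        rs:specEntity ?eprime ;
        rs:specQuality ?qprime .
  ?e rdfs:subClassOf* ?eprime .
  ?q rdfs:subClassOf* ?qprime .
  FILTER NOT EXISTS {
    ?spec2 a rs:NormalSizeSpecification ;
           rs:specEntity ?e2 ;
           rs:specQuality ?q2 .
    FILTER(?spec2 != ?spec)
    ?e rdfs:subClassOf* ?e2 .
    ?e2 rdfs:subClassOf* ?eprime .
    FILTER(?e2 != ?eprime)
    ?q rdfs:subClassOf* ?q2 .
    ?q2 rdfs:subClassOf* ?qprime .
  }
}
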