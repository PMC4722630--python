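# Measurement data of one finding (?f bound at call time): canonical
# value in mm, input order, and the quality class when labelled.
PREFIX rs: <https://w3id.org/radsize/>
SELECT ?m ?vmm ?idx ?qcls WHERE {
  ?f rs:describes ?q .
  ?q rs:hasMeasurement ?m .
  ?m rs:valueMM ?vmm ;
     rs:index ?idx .
  OPTIONAL {
    ?q a ?qcls .
    FILTER(STRSTARTS(STR(?qcls), "https://w3id.org/radsize/quality/"))
  }
}
ORDER BY ?idx
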