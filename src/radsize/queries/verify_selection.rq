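# True iff the selected target-lesion set violates the limits:
# more than five targets, or any organ appearing more than twice.
PREFIX rs: <https://w3id.org/radsize/>
ASK {
  {
    { SELECT (COUNT(?l) AS ?n) WHERE { ?l a rs:TargetLesion ; rs:selected true } }
    FILTER(?n > 5)
  }
  UNION
  {
    { SELECT ?o (COUNT(?l) AS ?c)
      WHERE { ?l a rs:TargetLesion ; rs:selected true ; rs:organ ?o }
      GROUP BY ?o }
    FILTER(?c > 2)
  }
}
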