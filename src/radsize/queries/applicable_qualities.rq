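# Quality classes that appear on any specification applicable to the
# bound entity class ?e.
PREFIX rs: <https://w3id.org/radsize/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT DISTINCT ?qprime WHERE {
  ?spec a rs:NormalSizeSpecification ;
        rs:specEntity ?eprime ;
        rs:specQuality ?qprime .
  ?e rdfs:subClassOf* ?eprime .
}
ORDER BY ?qprime
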