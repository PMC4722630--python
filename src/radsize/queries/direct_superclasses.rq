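# Direct superclasses of the bound class ?c (single subclass hop).
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?p WHERE { ?c rdfs:subClassOf ?p . }
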