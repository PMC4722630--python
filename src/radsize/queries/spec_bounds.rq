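# Range type and bounds (mm) of the bound specification ?spec.
PREFIX rs: <https://w3id.org/radsize/>
SELECT ?rt ?lo ?hi WHERE {
  ?spec rs:rangeType ?rt .
  OPTIONAL { ?spec rs:lowMM ?lo }
  OPTIONAL { ?spec rs:highMM ?hi }
}
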