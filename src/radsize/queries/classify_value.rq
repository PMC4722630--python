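# Compare the bound value ?v (mm) with the bound specification ?spec.
# Bounds are inclusive, with a 1e-9 mm tolerance so that unit
# conversion cannot flip an exact boundary case.
PREFIX rs: <https://w3id.org/radsize/>
SELECT ?label WHERE {
  ?spec rs:rangeType ?rt .
  OPTIONAL { ?spec rs:lowMM ?lo }
  OPTIONAL { ?spec rs:highMM ?hi }
  BIND(
    IF(?rt = "upper_bound",
       IF(?v <= ?hi + 1e-9, "normal", "abnormal_high"),
       IF(?rt = "lower_bound",
          IF(?v >= ?lo - 1e-9, "normal", "abnormal_low"),
          IF(?v < ?lo - 1e-9, "abnormal_low",
             IF(?v > ?hi + 1e-9, "abnormal_high", "normal"))))
    AS ?label)
}
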