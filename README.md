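# radsize

Ontology-based classification of size measurements from radiology
reports, with RECIST 1.1 response evaluation, RDF/SPARQL export and a
longitudinal finding viewer.

Radiology reports state sizes without interpretation — "spleen
14.8 × 8.5 cm", "lymph node up to 1.6 × 1.2 cm" — and whether such a
value is normal depends on reference knowledge the report does not
carry. `radsize` is for clinical-informatics developers and
researchers who need that interpretation to be automatic and
auditable: it ships a knowledge base of *normal-size specifications*
over an anatomical subclass/part-of hierarchy, labels every
measurement finding **normal / abnormal / unclassified**, and layers
tumor-response evaluation and longitudinal review on top.

## The core method

A measurement finding is an Entity–Quality pair (*E*, *Q*) with a
value. The knowledge base holds statements that quality *Q′* of entity
*E′* is normal within an interval, up to an upper bound, or down to a
lower bound (e.g. *lymph node, short axis, ≤ 1 cm*). Classification
retrieves the **most specific** applicable statement: *E* ⊑ *E′* and
*Q* ⊑ *Q′*, no other statement (*E″*, *Q″*) with *E″* strictly between
*E* and *E′* on the subclass path and *Q″* between *Q* and *Q′*; ties
resolve to the shortest entity path. The value is then compared with
the bounds (inclusive, in mm); a finding with no applicable statement
stays *unclassified*. Inheritance does the heavy lifting: one
lymph-node bound covers every lymph-node subclass, while a
submental-node bound (≤ 1.5 cm) overrides it for that subtree.

RECIST 1.1 is implemented over classified lesions: target candidacy
(node short axis ≥ 15 mm, lesion longest diameter ≥ 10 mm), selection
verification (≤ 5 targets, ≤ 2 per organ), per-exam diameter sums
(short axis for nodes, longest diameter otherwise), and the timepoint
response — CR, PD (≥ 20 % over the nadir *and* ≥ 5 mm, or new
lesions), PR (≤ 70 % of baseline), SD — with precedence
CR > PD > PR > SD.

Everything also round-trips through RDF: findings, specifications and
RECIST sums serialize as Turtle, and a query-based execution path
(`query_classify`, SPARQL property paths + value comparison in the
query) reproduces the in-memory classifier label for label.

## Worked example

```python
import datetime as dt
import radsize as rs

graph, specs = rs.packaged_kb()
finding = rs.MeasurementFinding(
    "f1", "P001", "e1", dt.date(2015, 1, 15),
    entity="RID86", entity_kind="anatomical_structure",
    measurements=[rs.Measurement(14.8, "cm"), rs.Measurement(8.5, "cm")],
    sentence="Milz 14,8 x 8,5 cm.",
)
result = rs.classify_finding(finding, specs, graph)
print(result.overall)
for o in result.outcomes:
    print(f"  {o.measurement.value} {o.measurement.unit} -> {o.spec.spec_id}: {o.label}")
```

prints

```
normal
  14.8 cm -> spleen-height: normal
  8.5 cm -> spleen-length: normal
```

The two unlabeled values were paired positionally with the spleen's
height (11–15 cm) and length (7–10 cm) ranges, both inside their
range, so the finding is normal overall. (This reproduces a documented
limit of the approach: measured in the axial plane these values are
really length × width — a splenomegaly — which is exactly the kind of
error the per-dimension provenance makes visible.)

Response evaluation on a diameter-sum timeline:

```python
sums = [rs.RecistSum.from_value("e1", 72.0), rs.RecistSum.from_value("e2", 44.0)]
a = rs.classify_response(sums)
print(a.label, a.baseline_sum_mm, a.nadir_sum_mm, a.current_sum_mm)
```

prints `PR 72.0 72.0 44.0` — a 39 % decrease versus baseline, at least
the 30 % required for a partial response.

## Command line

```
radsize simulate --scenario PR --seed 7 --out cohort/   # synthetic cohort
radsize classify cohort/findings.jsonl --rdf graph.ttl  # labels + Turtle
radsize recist select cohort/findings.jsonl             # target candidates
radsize recist verify cohort/selection.json             # ≤5 / ≤2-per-organ
radsize recist response cohort/selection.json --exams exams.json
radsize view cohort/findings.jsonl --patient P001 --by-region abdomen --format html --out view.html
```

Findings are JSON-Lines (`patient_id`, `exam_id`, `exam_date`,
`entity_id`, `entity_kind`, `measurements: [{value, unit, quality?,
plane?}]`, `sentence`); hierarchies are tab-separated edge lists and
specifications a YAML list — see `src/radsize/data/` for the packaged
knowledge base.

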