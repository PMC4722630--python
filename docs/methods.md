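# Methods

## The problem

Radiology reports state sizes without interpretation ("spleen
14.8 × 8.5 cm"); whether that is normal depends on reference knowledge
the report does not carry. `radsize` encodes that knowledge as a set
of *normal-size specifications* — statements that one size quality of
one anatomical entity is normal up to a bound, down to a bound, or
within an interval — attached to concepts of a subclass / part-of
anatomy DAG, and classifies each measurement finding as **normal**,
**abnormal**, or **unclassified**. On top of the classified findings
it evaluates treatment response under RECIST 1.1 and renders a
longitudinal red/green review per patient.

## Entity–Quality retrieval

A finding is a pair (entity *E*, quality *Q*) with a measured value.
The knowledge base is searched for the *most specific* applicable
specification (*E′*, *Q′*): *E* must be *E′* or a subclass, *Q* must
be *Q′* or a subclass, and no other specification (*E″*, *Q″*) may
exist with *E″* strictly on the subclass path between *E* and *E′*
while *Q″* stays on the path between *Q* and *Q′*. Among surviving
candidates the shortest entity subclass path wins; a residual tie is
broken by the shorter quality path, and an exact double tie raises a
diagnostic (`AmbiguousSpecificationError`) rather than picking
arbitrarily — the retrieval rule itself defines only the entity-path
tie-break, and silent arbitrary choice would make the KB's behaviour
depend on load order. The anatomy is a DAG (multiple superclasses
allowed); "path length" always means shortest directed path.

Because a generic lymph-node bound (short axis ≤ 10 mm) applies to
every lymph-node subclass while a submental-node bound (≤ 15 mm)
overrides it for that subtree, coverage scales with the hierarchy
rather than with the number of statements.

Qualities form a fixed tree under *size* → *1-D extent*: length,
width, height, thickness, diameter (with craniocaudal and left-right
diameter below it), longest axis and short axis. Quality matching uses
the same subclass logic as entities, so a specification on "diameter"
applies to a "craniocaudal diameter" measurement.

## Value comparison and labels

All comparisons run in millimetres (1 cm = 10 mm) with bounds
inclusive at both ends: 10 mm against an "≤ 1 cm" bound is normal, and
40 mm against an "at least 4 cm" lower bound is normal. A tolerance of
1e-9 mm absorbs binary-floating-point artefacts of unit conversion
(0.3 cm converts to 3.0000000000000004 mm and must still satisfy a
3 mm bound). Per dimension the label is `normal`, `abnormal_high`,
`abnormal_low`, or `no_spec`; the finding is *abnormal* if any
dimension is abnormal, *unclassified* iff no dimension found a
specification, *normal* otherwise.

**Unlabeled dimensions.** Reports typically give "14.8 × 8.5 cm"
without saying which value is which quality. Values sorted by
descending size are paired positionally with the entity's applicable
specifications sorted by descending upper bound (lower bound when no
upper exists); surplus values pair with nothing. This rule is a design
choice: it is deterministic, permutation-stable, and reproduces the
documented behaviour of mapping the larger spleen value to the height
range and the next to the length range. Its known cost is that it can
flag more dimensions than a radiologist would attribute (for
"9 × 3.5 × 6.5 cm" it flags the low height as well as the low width);
the overall label is unaffected. Values that carry an explicit quality
label bypass the pairing and resolve through EQ retrieval directly.

**Lesions.** Cysts, masses and other lesions are pathological
structures, not anatomy with a normal size, so by default a finding
with `entity_kind == "lesion"` is labelled abnormal outright, with
`lesion_rule` provenance instead of a matched specification. This is a
documented assumption, switchable with
`classify_finding(..., lesion_always_abnormal=False)`, under which
lesions fall back to KB lookup (and typically come out unclassified).

**Scoring.** `evaluate_against_gold` builds a confusion table
(true/false × normal/abnormal plus unclassified); unclassified
findings count as incorrect — they enter the denominator of the
accuracy but never the numerator.

## RECIST 1.1 rules

The relevant diameter is the short axis for lymph nodes and the
longest diameter otherwise. For a nodal finding without an explicit
short-axis label, the second-largest of a multi-value measurement set
is taken (sizes are reported longest × short); a single unlabeled
nodal value has no identifiable short axis and is excluded with a
diagnostic.

- **Candidacy** (baseline): lymph node short axis ≥ 15 mm, lesion
  longest diameter ≥ 10 mm, both inclusive. Candidacy is computed; the
  actual selection is the radiologist's input.
- **Selection verification**: at most five targets, at most two per
  organ; the organ is the nearest part-of parent of the lesion's
  entity.
- **Diameter sum**: per exam, sum of relevant diameters over the
  selection, itemised per lesion; an absent lesion contributes 0 mm, a
  lesion with no recorded measurement at the exam is an error.
- **Response**: CR when all non-nodal targets have disappeared and
  every pathological lymph node short axis is < 10 mm (strict); PD
  when new lesions appeared, or the sum is ≥ 120 % of the nadir *and*
  ≥ 5 mm above it; PR when the sum is ≤ 70 % of the baseline sum;
  SD otherwise. The nadir is the smallest sum strictly before the
  current exam, baseline included. Precedence CR > PD > PR > SD:
  progression dominates response, and new lesions dominate everything
  except a fully resolved CR state is still overridden (new lesions →
  PD). Percent thresholds are inclusive ("at least"), the CR node rule
  strict ("< 10 mm").

## Knowledge-graph export and the query path

`export_graph` serializes hierarchies, specifications, findings and
RECIST sums as RDF Turtle in the project namespace
`https://w3id.org/radsize/`. Each finding node *describes* one quality
instance per dimension; the quality *inheres in* a material-entity
instance typed by the anatomy class and *has* a scalar measurement
datum carrying value, unit and canonical mm value. Specification nodes
carry entity class, quality class, range type and mm bounds; a RECIST
sum is the *output of* a sum-calculation node whose class is a
subclass of data transformation. Original concept identifiers
(RadLex-style ids) are kept as annotations; the external ontologies
they come from are referenced, not imported. Export refuses findings
whose type is still unset unless explicitly building a pre-
classification graph for the query path.

`query_classify` re-runs classification over such a graph through
SPARQL (queries shipped as package data under `radsize/queries/`):
candidate retrieval uses `rdfs:subClassOf*` property paths with a
`NOT EXISTS` domination filter, the path-length tie-break walks the
hierarchy with single-hop queries, and value comparison happens in a
query `BIND`/`IF` with the same 1e-9 mm tolerance. Pairing of
unlabeled dimensions and the overall-label aggregation run in Python
around the queries, mirroring a triple-store prototype's write-back
step; labels are asserted back into the graph. No description-logic
reasoning is involved anywhere — classification is retrieval plus
value comparison. The equivalence of this path with the in-memory
classifier on every generated finding is the package's strongest
internal oracle. Selection verification is additionally available as a
single SPARQL ASK query.

## Longitudinal view

Tracks group one patient's findings by entity. Entities on the
singleton whitelist (liver, spleen, kidney sides, gallbladder wall,
aorta segments, trachea — configurable) yield *linked* tracks:
consecutive findings are asserted to describe the same structure.
Lymph nodes and lesions yield *unlinked* tracks grouped by entity
label only, since identity across exams cannot be established without
explicit marking; two lesions of the same organ at one exam therefore
appear as two entries of one unlinked track. Rendering (text or static
HTML, no server) shows one column per exam, measurement values next to
the verbatim report sentence, abnormal cells red, normal green,
unclassified neutral; it is a pure function of the tracks.

## Synthetic cohorts

The generator emulates measurement findings from serial CT reports of
a small cohort. Defaults: 5 patients, 3 exams 90 days apart, noise
ε = 0.05, abnormal share 0.35. Per patient and exam it draws organ
findings (kidney craniocaudal diameter, gallbladder-wall thickness,
ureter width, ascending-aorta diameter, a three-dimensional unlabeled
spleen, a lymph node with labelled axes) plus an uncovered rib finding,
and four target lesions (two liver, one lung, one mediastinal node)
whose baseline diameters respect candidacy thresholds. Follow-up
diameters are baseline × factorᵗ × noise with per-scenario factors
CR 0 (nodes settle at 6 mm), PR 0.65, PD 1.4, SD 1.0 — chosen with
margin to the 30 %/20 % thresholds so the intended response survives
the noise band. Noise is multiplicative uniform on [1−ε, 1+ε] because
sizes are positive and ratio-scaled. Values are rounded to 0.1 of the
reported unit, as in reports.

Gold normality labels are fixed at draw time from the generating
parameters (which side of the known bound the rounded value was placed
on), never by running the classifier; normal draws keep a 15 % margin
to the boundary. Hence at ε = 0 the classifier recovers the gold
labels exactly for every KB-covered finding, and with noise any
disagreement is confined to values within the noise band (plus the
rounding quantum) of a specification boundary — both are asserted as
tests. What passing these tests does **not** show: robustness to the
extraction noise, annotation ambiguity and KB gaps of real free-text
reports, whose unclassified rates and error modes the generator does
not emulate; the shipped KB is fixture-scale (39 concepts, 9 active
specifications), not a clinical release.

## Numerical and degenerate-input choices

- Canonical unit mm; boundary tolerance 1e-9 mm everywhere (both
  execution paths).
- Exams are ordered by (date, exam id); response classification
  requires a baseline plus at least one follow-up, else it is an
  error.
- Empty target selection sums to 0 mm; CR/PD/PR checks still apply.
- Cycles in either hierarchy relation abort loading, naming the cycle;
  duplicate edges warn and deduplicate; specification files load
  order-independently and reject unresolvable entities/qualities and
  malformed bounds record by record.
- The ascending-aorta root bound ships exactly as stated in its source
  ("at least 4 cm", a lower bound), although a 4 cm ascending aorta is
  clinically an ectasia: the packaged KB reproduces its source,
  including that known misclassification.
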