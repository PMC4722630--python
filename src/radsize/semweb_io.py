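"""Knowledge-graph export and the query-based classification path.

Findings, normal-size specifications and RECIST sums are serialized as
RDF (Turtle) in a project namespace: a clinical-finding node describes
one quality instance per measured dimension, each quality inheres in a
material-entity instance and carries a scalar measurement datum with
its value, unit and canonical mm value.  Specification subgraphs state
entity class, quality class, range type and bounds; RECIST sums are
the output of a sum-calculation node (a data transformation).
Annotation properties keep the original source identifiers
(RadLex-style ids) next to the minted IRIs.

``query_classify`` re-runs the normality classification purely through
SPARQL queries over such a graph — retrieval of the most specific
specification via subclass property paths with a domination filter,
and value comparison inside the query — providing an execution path
independent of the in-memory classifier, as in a triple-store-backed
prototype.  Classification is not done by logical axioms or reasoning;
it is plain retrieval plus value comparison.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from rdflib import RDF, RDFS, XSD, Graph, Literal, Namespace, URIRef

from .findings import MeasurementFinding
from .normality import (
    ABNORMAL,
    NORMAL,
    UNCLASSIFIED,
    ClassificationResult,
)
from .ontology_kb import AnatomyGraph, SizeSpecification, SpecificationSet
from .qualities import ALL_QUALITIES, QualityKind
from .recist import RecistSum, TargetLesion

RS = Namespace("https://w3id.org/radsize/")


class GraphExportError(Exception):
    """Refused or malformed graph export."""


def _slug(name: str) -> str:
    return name.lower().replace(" ", "-")


_QUALITY_BY_SLUG = {_slug(q.name): q for q in ALL_QUALITIES}


def anatomy_iri(concept_id: str) -> URIRef:
    return RS[f"anatomy/{concept_id}"]


def quality_iri(quality: QualityKind) -> URIRef:
    return RS[f"quality/{_slug(quality.name)}"]


def spec_iri(spec: SizeSpecification) -> URIRef:
    return RS[f"spec/{spec.spec_id}"]


def load_query(name: str) -> str:
    """Load one of the packaged SPARQL query files (``*.rq``)."""
    return (resources.files("radsize") / "queries" / f"{name}.rq").read_text("utf-8")


# ---------------------------------------------------------------------------
# Export


def _add_hierarchies(g: Graph, graph: AnatomyGraph) -> None:
    for node in graph.nodes():
        cls = anatomy_iri(node)
        g.add((cls, RDF.type, RS.AnatomicalEntityClass))
        g.add((cls, RDFS.label, Literal(graph.label(node))))
        g.add((cls, RS.sourceId, Literal(node)))
    for child, parent in graph.subclass.edges:
        g.add((anatomy_iri(child), RDFS.subClassOf, anatomy_iri(parent)))
    for part, whole in graph.partof.edges:
        g.add((anatomy_iri(part), RS.partOf, anatomy_iri(whole)))
    for q in ALL_QUALITIES:
        cls = quality_iri(q)
        g.add((cls, RDF.type, RS.SizeQualityClass))
        g.add((cls, RDFS.label, Literal(q.name)))
        if q.parent is not None:
            g.add((cls, RDFS.subClassOf, quality_iri(q.parent)))


def _add_spec(g: Graph, spec: SizeSpecification) -> None:
    node = spec_iri(spec)
    g.add((node, RDF.type, RS.NormalSizeSpecification))
    g.add((node, RS.rangeType, Literal(spec.range_type)))
    g.add((node, RS.specEntity, anatomy_iri(spec.entity)))
    g.add((node, RS.specQuality, quality_iri(spec.quality)))
    if spec.low_mm is not None:
        g.add((node, RS.lowMM, Literal(spec.low_mm, datatype=XSD.double)))
    if spec.high_mm is not None:
        g.add((node, RS.highMM, Literal(spec.high_mm, datatype=XSD.double)))


_TYPE_BY_LABEL = {NORMAL: RS.NormalFinding, ABNORMAL: RS.AbnormalFinding}


def _add_finding(
    g: Graph,
    finding: MeasurementFinding,
    result: Optional[ClassificationResult],
) -> None:
    f = RS[f"finding/{finding.finding_id}"]
    g.add((f, RDF.type, RS.ClinicalFinding))
    g.add((f, RS.findingId, Literal(finding.finding_id)))
    g.add((f, RS.patientId, Literal(finding.patient_id)))
    g.add((f, RS.examId, Literal(finding.exam_id)))
    g.add((f, RS.examDate, Literal(finding.exam_date.isoformat(), datatype=XSD.date)))
    g.add((f, RS.entityKind, Literal(finding.entity_kind)))
    g.add((f, RS.sentence, Literal(finding.sentence)))

    entity_inst = RS[f"finding/{finding.finding_id}/entity"]
    g.add((entity_inst, RDF.type, anatomy_iri(finding.entity)))
    g.add((f, RS.isAbout, entity_inst))

    matched = {}
    if result is not None:
        for o in result.outcomes:
            if o.spec is not None:
                matched[(o.measurement.value_mm, o.measurement.quality)] = o

    for i, m in enumerate(finding.measurements):
        q_inst = RS[f"finding/{finding.finding_id}/q{i}"]
        g.add((q_inst, RDF.type, RS.QualityInstance))
        if m.quality is not None:
            g.add((q_inst, RDF.type, quality_iri(m.quality)))
        if m.plane is not None:
            g.add((q_inst, RS.inPlane, RS[f"plane/{m.plane}"]))
        g.add((f, RS.describes, q_inst))
        g.add((q_inst, RS.inheresIn, entity_inst))
        m_inst = RS[f"finding/{finding.finding_id}/m{i}"]
        g.add((m_inst, RDF.type, RS.ScalarMeasurementDatum))
        g.add((m_inst, RS.hasValue, Literal(m.value, datatype=XSD.double)))
        g.add((m_inst, RS.hasUnit, RS[f"unit/{m.unit}"]))
        g.add((m_inst, RS.valueMM, Literal(m.value_mm, datatype=XSD.double)))
        g.add((m_inst, RS["index"], Literal(i, datatype=XSD.integer)))
        g.add((q_inst, RS.hasMeasurement, m_inst))
        outcome = matched.get((m.value_mm, m.quality))
        if outcome is not None and outcome.spec is not None:
            g.add((m_inst, RS.matchedSpec, spec_iri(outcome.spec)))
            g.add((m_inst, RS.dimensionLabel, Literal(outcome.label)))

    if finding.finding_type != "unset":
        g.add((f, RS.findingType, Literal(finding.finding_type)))
        cls = _TYPE_BY_LABEL.get(finding.finding_type)
        if cls is not None:
            g.add((f, RDF.type, cls))


def _add_recist_sum(g: Graph, s: RecistSum) -> None:
    node = RS[f"recist/sum/{s.exam_id}"]
    calc = RS[f"recist/calc/{s.exam_id}"]
    g.add((RS.RecistSumCalculation, RDFS.subClassOf, RS.DataTransformation))
    g.add((node, RDF.type, RS.RecistSum))
    g.add((node, RS.examId, Literal(s.exam_id)))
    g.add((node, RS.valueMM, Literal(s.value_mm, datatype=XSD.double)))
    g.add((calc, RDF.type, RS.RecistSumCalculation))
    g.add((node, RS.outputOf, calc))
    for lesion_id, value in s.contributions:
        g.add((calc, RS.hasInputLesion, RS[f"lesion/{lesion_id}"]))
        g.add((node, RS.contributionOf, Literal(f"{lesion_id}={value}")))


def export_graph(
    findings: Sequence[MeasurementFinding],
    results: Optional[Sequence[ClassificationResult]] = None,
    specs: Optional[SpecificationSet] = None,
    graph: Optional[AnatomyGraph] = None,
    sums: Optional[Sequence[RecistSum]] = None,
    allow_unclassified: bool = False,
) -> Graph:
    """Build the RDF graph for findings, specifications and RECIST sums.

    Findings must have been classified (``finding_type`` set) unless
    ``allow_unclassified`` is passed — the query-based path exports
    first and classifies inside the triple store.
    """
    if not allow_unclassified:
        unset = [f.finding_id for f in findings if f.finding_type == "unset"]
        if unset:
            raise GraphExportError(f"findings not yet classified: {unset}; classify first")
    g = Graph()
    g.bind("rs", RS)
    if graph is not None:
        _add_hierarchies(g, graph)
    if specs is not None:
        for spec in specs:
            _add_spec(g, spec)
    by_id = {r.finding_id: r for r in (results or ())}
    for finding in findings:
        _add_finding(g, finding, by_id.get(finding.finding_id))
    for s in sums or ():
        _add_recist_sum(g, s)
    return g


def export_selection(selection: Sequence[TargetLesion]) -> Graph:
    """Serialize a target-lesion selection for the verification query."""
    g = Graph()
    g.bind("rs", RS)
    for lesion in selection:
        node = RS[f"lesion/{lesion.lesion_id}"]
        g.add((node, RDF.type, RS.TargetLesion))
        g.add((node, RS.selected, Literal(True)))
        g.add((node, RS.organ, anatomy_iri(lesion.organ)))
        g.add((node, RS.kind, Literal(lesion.kind)))
    return g


def write_turtle(g: Graph, path) -> None:
    g.serialize(destination=str(path), format="turtle")


def read_turtle(path) -> Graph:
    g = Graph()
    g.parse(str(path), format="turtle")
    return g


# ---------------------------------------------------------------------------
# Query-based execution path


def _subclass_distance(g: Graph, query_text: str, start: URIRef, goal: URIRef) -> Optional[int]:
    """Shortest subclass-path length computed by iterated single-hop queries."""
    if start == goal:
        return 0
    frontier = {start}
    seen = {start}
    dist = 0
    while frontier:
        dist += 1
        nxt = set()
        for node in frontier:
            for row in g.query(query_text, initBindings={"c": node}):
                parent = row[0]
                if parent == goal:
                    return dist
                if parent not in seen:
                    seen.add(parent)
                    nxt.add(parent)
        frontier = nxt
    return None


class _QuerySpec:
    """A specification as seen through the graph: IRI plus sort bound."""

    def __init__(self, g: Graph, bounds_q: str, iri: URIRef):
        self.iri = iri
        rows = list(g.query(bounds_q, initBindings={"spec": iri}))
        rt, lo, hi = rows[0]
        self.range_type = str(rt)
        self.low_mm = float(lo) if lo is not None else None
        self.high_mm = float(hi) if hi is not None else None

    @property
    def sort_bound_mm(self) -> float:
        return self.high_mm if self.high_mm is not None else self.low_mm


def _most_specific_query(
    g: Graph,
    queries: Mapping[str, str],
    entity_cls: URIRef,
    quality_cls: URIRef,
) -> Optional[URIRef]:
    rows = list(
        g.query(queries["candidate_specs"], initBindings={"e": entity_cls, "q": quality_cls})
    )
    if not rows:
        return None
    scored = []
    for spec, eprime, qprime in rows:
        e_len = _subclass_distance(g, queries["direct_superclasses"], entity_cls, eprime)
        q_len = _subclass_distance(g, queries["direct_superclasses"], quality_cls, qprime)
        scored.append(((e_len, q_len), spec))
    scored.sort(key=lambda t: t[0])
    best = scored[0][0]
    ties = [s for k, s in scored if k == best]
    if len(ties) > 1:
        raise GraphExportError(
            f"ambiguous knowledge graph: {sorted(str(t) for t in ties)} tie for "
            f"({entity_cls}, {quality_cls})"
        )
    return scored[0][1]


def _classify_value_query(g: Graph, query_text: str, spec: URIRef, value_mm: float) -> str:
    rows = list(
        g.query(
            query_text,
            initBindings={"spec": spec, "v": Literal(value_mm, datatype=XSD.double)},
        )
    )
    return str(rows[0][0])


def query_classify(
    g: Graph,
    lesion_always_abnormal: bool = True,
) -> dict[str, str]:
    """Classify every finding in the graph via SPARQL and write labels back.

    Specification retrieval (subclass property paths with the
    domination filter, path-length tie-break by iterated single-hop
    queries) and value comparison both run inside SPARQL; only the
    pairing of unlabeled dimensions with retrieved specifications and
    the aggregation into the overall label happen outside, as in the
    write-back step of a triple-store pipeline.
    """
    queries = {
        name: load_query(name)
        for name in (
            "findings",
            "measurements",
            "candidate_specs",
            "applicable_qualities",
            "direct_superclasses",
            "spec_bounds",
            "classify_value",
        )
    }
    labels: dict[str, str] = {}
    for f, fid, ecls, kind in g.query(queries["findings"]):
        fid = str(fid)
        if lesion_always_abnormal and str(kind) == "lesion":
            labels[fid] = ABNORMAL
            _write_back(g, f, ABNORMAL)
            continue
        measurements = list(g.query(queries["measurements"], initBindings={"f": f}))
        dim_labels: list[str] = []
        unlabeled: list[float] = []
        used_specs: set[URIRef] = set()
        for _m, vmm, _idx, qcls in measurements:
            if qcls is not None:
                spec = _most_specific_query(g, queries, ecls, qcls)
                if spec is None:
                    dim_labels.append("no_spec")
                else:
                    used_specs.add(spec)
                    dim_labels.append(
                        _classify_value_query(g, queries["classify_value"], spec, float(vmm))
                    )
            else:
                unlabeled.append(float(vmm))
        if unlabeled:
            qualities = [
                row[0]
                for row in g.query(
                    queries["applicable_qualities"], initBindings={"e": ecls}
                )
            ]
            spec_iris: dict[URIRef, None] = {}
            for qcls in qualities:
                spec = _most_specific_query(g, queries, ecls, qcls)
                if spec is not None and spec not in used_specs:
                    spec_iris[spec] = None
            qspecs = sorted(
                (_QuerySpec(g, queries["spec_bounds"], iri) for iri in spec_iris),
                key=lambda s: -s.sort_bound_mm,
            )
            for i, value in enumerate(sorted(unlabeled, reverse=True)):
                if i < len(qspecs):
                    dim_labels.append(
                        _classify_value_query(
                            g, queries["classify_value"], qspecs[i].iri, value
                        )
                    )
                else:
                    dim_labels.append("no_spec")
        if all(lbl == "no_spec" for lbl in dim_labels):
            overall = UNCLASSIFIED
        elif any(lbl in ("abnormal_high", "abnormal_low") for lbl in dim_labels):
            overall = ABNORMAL
        else:
            overall = NORMAL
        labels[fid] = overall
        _write_back(g, f, overall)
    return labels


def _write_back(g: Graph, finding_node: URIRef, label: str) -> None:
    g.set((finding_node, RS.findingType, Literal(label)))
    cls = _TYPE_BY_LABEL.get(label)
    if cls is not None:
        g.add((finding_node, RDF.type, cls))


def query_verify_selection(g: Graph) -> bool:
    """Boolean target-selection check as a single ASK query (True = pass)."""
    violated = bool(g.query(load_query("verify_selection")))
    return not violated
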