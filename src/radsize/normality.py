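"""Normality classification of measurement findings.

Each measured value is compared with the most specific applicable
normal-size specification retrieved by Entity-Quality matching: a
value inside the normal range (bounds inclusive) is normal, outside it
abnormal (high or low), and a value with no applicable specification
stays unclassifiable.  A finding is abnormal when any of its
dimensions is abnormal, unclassified when none of its dimensions could
be matched to a specification, and normal otherwise.

Lesions, masses and cysts are themselves pathological structures, not
anatomy with a normal size, so by default a finding about a lesion is
labelled abnormal outright (with dedicated provenance); the rule can
be switched off to route lesions through the knowledge base like any
other entity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .findings import Measurement, MeasurementFinding, assign_dimensions
from .ontology_kb import (
    INTERVAL,
    LOWER_BOUND,
    UPPER_BOUND,
    AnatomyGraph,
    SizeSpecification,
    SpecificationSet,
    most_specific_spec,
    specs_for_entity,
)
from .units import geq, leq

NORMAL = "normal"
ABNORMAL = "abnormal"
UNCLASSIFIED = "unclassified"

ABNORMAL_HIGH = "abnormal_high"
ABNORMAL_LOW = "abnormal_low"
NO_SPEC = "no_spec"

#: provenance tag used when the lesion rule fires instead of a size spec
LESION_RULE = "lesion_rule"


@dataclass(frozen=True)
class DimensionOutcome:
    """Per-dimension comparison outcome with matched-spec provenance."""

    measurement: Measurement
    spec: Optional[SizeSpecification]
    label: str

    def __post_init__(self) -> None:
        if (self.label == NO_SPEC) != (self.spec is None):
            raise ValueError("label no_spec exactly when no spec matched")


@dataclass(frozen=True)
class ClassificationResult:
    finding_id: str
    outcomes: tuple[DimensionOutcome, ...]
    overall: str
    provenance: str = ""  # e.g. LESION_RULE when the lesion default fired


def classify_value(value_mm: float, spec: SizeSpecification) -> str:
    """Compare a value (mm) with one specification; bounds are inclusive."""
    if spec.range_type == UPPER_BOUND:
        return NORMAL if leq(value_mm, spec.high_mm) else ABNORMAL_HIGH
    if spec.range_type == LOWER_BOUND:
        return NORMAL if geq(value_mm, spec.low_mm) else ABNORMAL_LOW
    assert spec.range_type == INTERVAL
    if not geq(value_mm, spec.low_mm):
        return ABNORMAL_LOW
    if not leq(value_mm, spec.high_mm):
        return ABNORMAL_HIGH
    return NORMAL


def overall_label(outcomes: Sequence[DimensionOutcome]) -> str:
    if all(o.label == NO_SPEC for o in outcomes):
        return UNCLASSIFIED
    if any(o.label in (ABNORMAL_HIGH, ABNORMAL_LOW) for o in outcomes):
        return ABNORMAL
    return NORMAL


def classify_finding(
    finding: MeasurementFinding,
    specs: SpecificationSet,
    graph: AnatomyGraph,
    lesion_always_abnormal: bool = True,
) -> ClassificationResult:
    """Classify one finding and write the resulting type back onto it.

    Values with an explicit quality label retrieve their specification
    directly via most-specific EQ matching; unlabeled values are routed
    through the positional dimension assignment against the entity's
    applicable specifications.
    """
    if lesion_always_abnormal and finding.entity_kind == "lesion":
        outcomes = tuple(
            DimensionOutcome(m, None, NO_SPEC) for m in finding.measurements
        )
        result = ClassificationResult(
            finding.finding_id, outcomes, ABNORMAL, provenance=LESION_RULE
        )
        finding.finding_type = ABNORMAL
        return result

    if finding.entity in graph:
        applicable = specs_for_entity(graph, specs, finding.entity)
    else:
        applicable = []
    outcomes = []
    for measurement, spec in assign_dimensions(finding, applicable):
        if measurement.quality is not None and finding.entity in graph:
            # labelled dimensions resolve through EQ retrieval directly
            spec = most_specific_spec(graph, specs, finding.entity, measurement.quality)
        if spec is None:
            outcomes.append(DimensionOutcome(measurement, None, NO_SPEC))
        else:
            outcomes.append(
                DimensionOutcome(measurement, spec, classify_value(measurement.value_mm, spec))
            )
    overall = overall_label(outcomes)
    finding.finding_type = overall
    return ClassificationResult(finding.finding_id, tuple(outcomes), overall)


def classify_findings(
    findings: Iterable[MeasurementFinding],
    specs: SpecificationSet,
    graph: AnatomyGraph,
    lesion_always_abnormal: bool = True,
) -> list[ClassificationResult]:
    return [
        classify_finding(f, specs, graph, lesion_always_abnormal) for f in findings
    ]


# ---------------------------------------------------------------------------
# Evaluation against gold labels


@dataclass(frozen=True)
class ConfusionTable:
    """Confusion counts for normal/abnormal classification.

    ``false_normal`` counts findings the classifier called normal that
    are abnormal per the gold label (and vice versa for
    ``false_abnormal``).  Unclassified findings count as incorrect:
    they enter the denominator of the accuracy but never the numerator.
    """

    true_normal: int
    true_abnormal: int
    false_normal: int
    false_abnormal: int
    unclassified: int

    @property
    def total(self) -> int:
        return (
            self.true_normal
            + self.true_abnormal
            + self.false_normal
            + self.false_abnormal
            + self.unclassified
        )

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            return 0.0
        return (self.true_normal + self.true_abnormal) / self.total

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.accuracy


def evaluate_against_gold(
    results: Mapping[str, str] | Iterable[ClassificationResult],
    gold_labels: Mapping[str, str],
) -> ConfusionTable:
    """Score overall labels against gold normal/abnormal labels.

    *results* is either a mapping finding-id -> overall label or an
    iterable of :class:`ClassificationResult`.  Every finding needs a
    gold label (``normal`` or ``abnormal``) and vice versa; mismatched
    id sets raise with the offending ids listed.
    """
    if not isinstance(results, Mapping):
        results = {r.finding_id: r.overall for r in results}
    missing_gold = sorted(set(results) - set(gold_labels))
    missing_results = sorted(set(gold_labels) - set(results))
    if missing_gold or missing_results:
        raise ValueError(
            f"id sets differ; no gold label for {missing_gold}, "
            f"no result for {missing_results}"
        )
    tn = ta = fn = fa = unc = 0
    for fid, label in results.items():
        gold = gold_labels[fid]
        if gold not in (NORMAL, ABNORMAL):
            raise ValueError(f"gold label for {fid} must be normal/abnormal, got {gold!r}")
        if label == UNCLASSIFIED:
            unc += 1
        elif label == NORMAL:
            tn += gold == NORMAL
            fn += gold == ABNORMAL
        elif label == ABNORMAL:
            ta += gold == ABNORMAL
            fa += gold == NORMAL
        else:
            raise ValueError(f"result label for {fid} must be classified, got {label!r}")
    return ConfusionTable(tn, ta, fn, fa, unc)
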