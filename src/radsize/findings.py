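"""Measurement findings and dimension assignment.

A measurement finding reports one to three measured values about one
anatomical entity at one examination ("1.6 x 1.2 cm, aortopulmonary
lymph node").  Report text rarely labels the individual values with
their qualities (length vs. width vs. short axis), so unlabeled values
must be paired with the normal-size specifications that apply to the
entity before they can be compared.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Optional, Sequence, Union

from .ontology_kb import AnatomyGraph, SizeSpecification
from .qualities import QualityKind, get_quality
from .units import to_mm

ENTITY_KINDS = ("anatomical_structure", "lymph_node", "lesion")
FINDING_TYPES = ("unset", "normal", "abnormal", "unclassified")

PLANES = ("axial", "coronal", "sagittal")
AXES = ("craniocaudal", "left-right", "anterior-posterior")


@dataclass(frozen=True)
class Measurement:
    """One measured length: value + unit, optionally a quality label and plane."""

    value: float
    unit: str
    quality: Optional[QualityKind] = None
    plane: Optional[str] = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"measurement value must be positive, got {self.value}")
        if self.unit not in ("cm", "mm"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.plane is not None and self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")

    @property
    def value_mm(self) -> float:
        return to_mm(self.value, self.unit)


@dataclass
class MeasurementFinding:
    """One reported measurement set about one anatomical entity at one exam."""

    finding_id: str
    patient_id: str
    exam_id: str
    exam_date: dt.date
    entity: str
    entity_kind: str
    measurements: list[Measurement]
    sentence: str = ""
    entity_label: str = ""
    finding_type: str = "unset"

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError("a finding requires at least one measurement")
        if self.entity_kind not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind {self.entity_kind!r}")
        if self.finding_type not in FINDING_TYPES:
            raise ValueError(f"unknown finding type {self.finding_type!r}")


class PlaneAxisModel:
    """The three imaging planes and body axes with their spatial relations.

    ``parallel_to`` holds between planes that do not intersect (every
    plane is parallel to itself); ``orthogonal_to`` holds between
    linearly independent planes/axes.  Both relations are symmetric.
    The craniocaudal axis is orthogonal to the axial plane, so a
    craniocaudal-diameter measurement cannot be taken in the axial
    plane — it carries plane coronal, sagittal, or none.
    """

    planes = PLANES
    axes = AXES

    _orthogonal = {
        frozenset(("craniocaudal", "axial")),
        frozenset(("anterior-posterior", "coronal")),
        frozenset(("left-right", "sagittal")),
        frozenset(("axial", "coronal")),
        frozenset(("axial", "sagittal")),
        frozenset(("coronal", "sagittal")),
    }
    _parallel = {
        frozenset(("craniocaudal", "coronal")),
        frozenset(("craniocaudal", "sagittal")),
        frozenset(("left-right", "axial")),
        frozenset(("left-right", "coronal")),
        frozenset(("anterior-posterior", "axial")),
        frozenset(("anterior-posterior", "sagittal")),
    }

    @classmethod
    def orthogonal_to(cls, a: str, b: str) -> bool:
        return frozenset((a, b)) in cls._orthogonal

    @classmethod
    def parallel_to(cls, a: str, b: str) -> bool:
        if a == b:
            return True
        return frozenset((a, b)) in cls._parallel

    @classmethod
    def admissible_planes(cls, quality: QualityKind) -> tuple[str, ...]:
        """Planes in which a measurement of *quality* can be taken."""
        if quality.name == "craniocaudal diameter":
            return ("coronal", "sagittal")
        return cls.planes


@dataclass(frozen=True)
class RejectedRecord:
    line_no: int
    reason: str
    raw: str


@dataclass
class ReadResult:
    findings: list[MeasurementFinding]
    rejects: list[RejectedRecord] = field(default_factory=list)


def _infer_entity_kind(entity: str, graph: Optional[AnatomyGraph]) -> str:
    """Fallback inference when the input omits entity_kind."""
    if graph is not None and entity in graph:
        if graph.is_a(entity, "RID13296"):
            return "lymph_node"
        if "lesion" in graph and graph.is_a(entity, "lesion"):
            return "lesion"
    return "anatomical_structure"


def _parse_measurement(rec: dict) -> Measurement:
    quality = get_quality(rec["quality"]) if rec.get("quality") else None
    return Measurement(
        value=float(rec["value"]),
        unit=rec["unit"],
        quality=quality,
        plane=rec.get("plane"),
    )


def read_findings(
    stream: Union[IO[str], Iterable[str]],
    graph: Optional[AnatomyGraph] = None,
) -> ReadResult:
    """Parse JSON-Lines finding records.

    One finding per line with keys ``patient_id``, ``exam_id``,
    ``exam_date`` (ISO 8601), ``entity_id``, ``entity_label``,
    ``entity_kind``, ``measurements`` (list of ``{value, unit,
    quality?, plane?}``) and ``sentence``.  Records that cannot be
    validated go to the reject channel with the line number and a
    reason instead of aborting the read.
    """
    result = ReadResult(findings=[])
    for line_no, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            result.rejects.append(RejectedRecord(line_no, f"malformed JSON: {exc}", line))
            continue
        try:
            entity = rec["entity_id"]
            if not entity:
                raise ValueError("missing entity")
            measurements = [_parse_measurement(m) for m in rec.get("measurements", [])]
            if not measurements:
                raise ValueError("no parsable measurement")
            kind = rec.get("entity_kind") or _infer_entity_kind(entity, graph)
            finding = MeasurementFinding(
                finding_id=rec.get("finding_id") or f"f{line_no}",
                patient_id=rec["patient_id"],
                exam_id=rec["exam_id"],
                exam_date=dt.date.fromisoformat(rec["exam_date"]),
                entity=entity,
                entity_kind=kind,
                measurements=measurements,
                sentence=rec.get("sentence", ""),
                entity_label=rec.get("entity_label", ""),
            )
        except (KeyError, ValueError, TypeError) as exc:
            result.rejects.append(RejectedRecord(line_no, str(exc), line))
            continue
        result.findings.append(finding)
    return result


def finding_to_record(finding: MeasurementFinding) -> dict:
    """Serialize a finding back to the JSON-Lines schema."""
    return {
        "finding_id": finding.finding_id,
        "patient_id": finding.patient_id,
        "exam_id": finding.exam_id,
        "exam_date": finding.exam_date.isoformat(),
        "entity_id": finding.entity,
        "entity_label": finding.entity_label,
        "entity_kind": finding.entity_kind,
        "measurements": [
            {
                "value": m.value,
                "unit": m.unit,
                **({"quality": m.quality.name} if m.quality else {}),
                **({"plane": m.plane} if m.plane else {}),
            }
            for m in finding.measurements
        ],
        "sentence": finding.sentence,
        "finding_type": finding.finding_type,
    }


def exam_sort_key(finding: MeasurementFinding) -> tuple:
    """Deterministic exam ordering: date first, exam id as tiebreak."""
    return (finding.exam_date, finding.exam_id)


def assign_dimensions(
    finding: MeasurementFinding,
    applicable: Sequence[SizeSpecification],
) -> list[tuple[Measurement, Optional[SizeSpecification]]]:
    """Pair each measured value with the specification it is judged against.

    Values that carry an explicit quality label are paired directly
    with the specification of that quality.  The remaining unlabeled
    values, sorted by descending size, are paired positionally with the
    remaining specifications sorted by descending upper bound (the
    lower bound stands in when no upper bound exists): the biggest
    measured value is judged against the quality with the biggest
    normal ceiling.  Surplus values pair with ``None``.  The pairing
    depends only on the multiset of values, never on input order.
    """
    by_quality = {s.quality: s for s in applicable}
    labeled: list[tuple[Measurement, Optional[SizeSpecification]]] = []
    used_ids: set[str] = set()
    unlabeled: list[Measurement] = []
    for m in finding.measurements:
        if m.quality is not None:
            spec = by_quality.get(m.quality)
            if spec is None:
                # fall back to a spec whose quality subsumes the label
                spec = next(
                    (s for s in applicable if m.quality.is_a(s.quality)), None
                )
            labeled.append((m, spec))
            if spec is not None:
                used_ids.add(spec.spec_id)
        else:
            unlabeled.append(m)

    remaining = sorted(
        (s for s in applicable if s.spec_id not in used_ids),
        key=lambda s: -s.sort_bound_mm,
    )
    unlabeled.sort(key=lambda m: -m.value_mm)
    pairs: list[tuple[Measurement, Optional[SizeSpecification]]] = list(labeled)
    for i, m in enumerate(unlabeled):
        pairs.append((m, remaining[i] if i < len(remaining) else None))
    return pairs
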