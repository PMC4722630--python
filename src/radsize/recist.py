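"""RECIST 1.1 target-lesion rules and response classification.

Four computations: (1) candidacy — which baseline findings are large
enough to serve as target lesions (longest diameter >= 10 mm for
lesions, short axis >= 15 mm for lymph nodes); (2) verification of the
radiologist's selection (at most five targets, at most two per organ);
(3) the diameter sum per exam (short axis for nodal targets, longest
diameter otherwise); (4) the timepoint response — Complete Response,
Partial Response, Progressive Disease or Stable Disease.

Response thresholds: PR needs at least a 30 % decrease of the sum
versus baseline; PD needs at least a 20 % increase versus the nadir
(the smallest sum so far, baseline included) together with an absolute
increase of at least 5 mm, or the appearance of new lesions; CR needs
all target lesions gone and every pathological lymph node short axis
below 10 mm.  Precedence is CR > PD > PR > SD: progression dominates
response, and anything not otherwise classified is stable disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .findings import MeasurementFinding
from .ontology_kb import AnatomyGraph
from .qualities import LONGEST_AXIS, SHORT_AXIS
from .units import BOUNDARY_TOL_MM, geq, leq

CR, PR, PD, SD = "CR", "PR", "PD", "SD"

#: candidacy thresholds, mm
LESION_TARGET_MIN_MM = 10.0
LYMPH_NODE_TARGET_MIN_MM = 15.0
#: selection limits
MAX_TARGETS = 5
MAX_PER_ORGAN = 2
#: response thresholds
PR_DECREASE_FRACTION = 0.30
PD_INCREASE_FRACTION = 0.20
PD_ABSOLUTE_MIN_MM = 5.0
CR_NODE_RESIDUAL_MM = 10.0  # pathological nodes must shrink strictly below this


class RecistError(Exception):
    """Invalid input to a RECIST computation."""


@dataclass
class TargetLesion:
    """One measurable lesion followed across exams.

    ``diameters_mm`` maps exam id to the RECIST-relevant diameter
    (short axis for lymph nodes, longest diameter otherwise); a lesion
    absent at an exam carries 0 mm there.
    """

    lesion_id: str
    entity: str
    organ: str
    kind: str  # "lymph_node" or "lesion"
    diameters_mm: dict[str, float] = field(default_factory=dict)
    potential_target: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("lymph_node", "lesion"):
            raise ValueError(f"target lesion kind must be lymph_node or lesion, got {self.kind!r}")
        for exam, d in self.diameters_mm.items():
            if d < 0:
                raise ValueError(f"negative diameter at exam {exam}")

    def present(self, exam_id: str) -> bool:
        return self.diameters_mm.get(exam_id, 0.0) > 0.0

    def diameter(self, exam_id: str) -> float:
        return self.diameters_mm.get(exam_id, 0.0)


@dataclass(frozen=True)
class RecistSum:
    """Sum of target-lesion diameters at one exam, with per-lesion contributions."""

    exam_id: str
    contributions: tuple[tuple[str, float], ...] = ()

    @property
    def value_mm(self) -> float:
        return sum(v for _, v in self.contributions)

    @classmethod
    def from_value(cls, exam_id: str, value_mm: float) -> "RecistSum":
        """A sum known only as a total (single aggregate contribution)."""
        if value_mm < 0:
            raise ValueError("diameter sum must be non-negative")
        if value_mm == 0:
            return cls(exam_id, ())
        return cls(exam_id, (("sum", value_mm),))


@dataclass(frozen=True)
class ResponseAssessment:
    exam_id: str
    label: str
    baseline_sum_mm: float
    nadir_sum_mm: float
    current_sum_mm: float
    new_lesions: bool


@dataclass(frozen=True)
class SelectionCheck:
    ok: bool
    violations: tuple[str, ...] = ()


def relevant_diameter_mm(finding: MeasurementFinding) -> Optional[float]:
    """The RECIST-relevant diameter of a finding, in mm.

    Lymph nodes report their short axis: a value explicitly labelled
    short axis, otherwise the second-largest of a multi-dimensional
    measurement set (size is reported as longest axis x short axis).  A
    nodal finding with a single unlabeled value has no identifiable
    short axis.  Other lesions report their longest diameter: the value
    labelled longest axis, otherwise the largest value.
    """
    labelled = {m.quality.name: m.value_mm for m in finding.measurements if m.quality}
    values = sorted((m.value_mm for m in finding.measurements), reverse=True)
    if finding.entity_kind == "lymph_node":
        if SHORT_AXIS.name in labelled:
            return labelled[SHORT_AXIS.name]
        if len(values) >= 2:
            return values[1]
        return None
    if LONGEST_AXIS.name in labelled:
        return labelled[LONGEST_AXIS.name]
    return values[0]


def locate_organ(graph: AnatomyGraph, entity: str) -> str:
    """Resolve the organ/region a lesion is located in via the part-of closure.

    Returns the nearest part-of parent (following subclass edges where
    needed); falls back to the entity itself when nothing more general
    is recorded.
    """
    if entity not in graph:
        return entity
    frontier = [entity]
    seen = {entity}
    while frontier:
        next_frontier = []
        for node in frontier:
            parents = sorted(graph.partof.successors(node))
            if parents:
                return parents[0]
            for parent in sorted(graph.subclass.successors(node)):
                if parent not in seen:
                    seen.add(parent)
                    next_frontier.append(parent)
        frontier = next_frontier
    return entity


def candidate_targets(
    baseline_findings: Sequence[MeasurementFinding],
    graph: Optional[AnatomyGraph] = None,
) -> tuple[list[TargetLesion], list[str]]:
    """Flag baseline findings large enough to be selected as target lesions.

    Only lymph nodes and lesions are considered.  Returns the candidate
    list plus diagnostics for findings lacking the relevant diameter.
    Candidacy is computed; the actual selection remains the
    radiologist's input.
    """
    candidates: list[TargetLesion] = []
    diagnostics: list[str] = []
    for finding in baseline_findings:
        if finding.entity_kind not in ("lymph_node", "lesion"):
            continue
        diameter = relevant_diameter_mm(finding)
        if diameter is None:
            diagnostics.append(
                f"{finding.finding_id}: no identifiable "
                f"{'short axis' if finding.entity_kind == 'lymph_node' else 'longest diameter'}"
            )
            continue
        threshold = (
            LYMPH_NODE_TARGET_MIN_MM
            if finding.entity_kind == "lymph_node"
            else LESION_TARGET_MIN_MM
        )
        organ = locate_organ(graph, finding.entity) if graph else finding.entity
        candidates.append(
            TargetLesion(
                lesion_id=finding.finding_id,
                entity=finding.entity,
                organ=organ,
                kind=finding.entity_kind,
                diameters_mm={finding.exam_id: diameter},
                potential_target=geq(diameter, threshold),
            )
        )
    return candidates, diagnostics


def verify_selection(selection: Sequence[TargetLesion]) -> SelectionCheck:
    """Check the selected target set: at most five, at most two per organ."""
    violations: list[str] = []
    if len(selection) > MAX_TARGETS:
        violations.append(f"{len(selection)} target lesions selected; at most {MAX_TARGETS} allowed")
    per_organ: dict[str, int] = {}
    for lesion in selection:
        per_organ[lesion.organ] = per_organ.get(lesion.organ, 0) + 1
    for organ, count in sorted(per_organ.items()):
        if count > MAX_PER_ORGAN:
            violations.append(
                f"organ {organ!r} appears {count} times; at most {MAX_PER_ORGAN} allowed"
            )
    return SelectionCheck(ok=not violations, violations=tuple(violations))


def recist_sum(selection: Sequence[TargetLesion], exam_id: str) -> RecistSum:
    """Sum the relevant diameters of all selected target lesions at one exam.

    A lesion that has disappeared contributes 0 mm; a lesion with no
    recorded measurement at the exam at all is an error naming it.
    """
    contributions = []
    for lesion in selection:
        if exam_id not in lesion.diameters_mm:
            raise RecistError(
                f"target lesion {lesion.lesion_id!r} has no measurement at exam {exam_id!r}"
            )
        contributions.append((lesion.lesion_id, lesion.diameters_mm[exam_id]))
    return RecistSum(exam_id, tuple(contributions))


def classify_response(
    sums: Sequence[RecistSum],
    lymph_node_short_axes_mm: Sequence[float] = (),
    new_lesions: bool = False,
    targets_disappeared: Optional[bool] = None,
) -> ResponseAssessment:
    """Classify the latest exam of an ordered diameter-sum timeline.

    *sums* is the chronological sequence of RECIST sums, baseline
    first; the last entry is the exam under assessment.
    *lymph_node_short_axes_mm* lists the short axes of all pathological
    lymph nodes (target or not) at the current exam, for the CR
    residual rule.  *targets_disappeared* may override the
    disappearance test when contributions are not itemised.
    """
    if len(sums) < 2:
        raise RecistError("response classification requires baseline and at least one follow-up")
    baseline = sums[0].value_mm
    current = sums[-1].value_mm
    nadir = min(s.value_mm for s in sums[:-1])

    if targets_disappeared is None:
        # disappearance judged on itemised contributions: every non-nodal
        # target at 0 mm (nodal targets are governed by the <10 mm rule)
        targets_disappeared = current == 0.0 or all(
            v == 0.0 for _, v in sums[-1].contributions
        )
    nodes_resolved = all(
        axis < CR_NODE_RESIDUAL_MM - BOUNDARY_TOL_MM for axis in lymph_node_short_axes_mm
    )
    label = SD
    if targets_disappeared and nodes_resolved and not new_lesions:
        label = CR
    elif new_lesions or (
        geq(current, (1.0 + PD_INCREASE_FRACTION) * nadir)
        and geq(current - nadir, PD_ABSOLUTE_MIN_MM)
    ):
        label = PD
    elif leq(current, (1.0 - PR_DECREASE_FRACTION) * baseline):
        label = PR
    return ResponseAssessment(
        exam_id=sums[-1].exam_id,
        label=label,
        baseline_sum_mm=baseline,
        nadir_sum_mm=nadir,
        current_sum_mm=current,
        new_lesions=new_lesions,
    )


def assess_timeline(
    selection: Sequence[TargetLesion],
    exam_ids: Sequence[str],
    new_lesion_flags: Mapping[str, bool],
    lymph_node_short_axes_mm: Optional[Mapping[str, Sequence[float]]] = None,
) -> list[ResponseAssessment]:
    """Run sum + response classification over every follow-up exam in order."""
    if not exam_ids:
        raise RecistError("empty exam timeline")
    sums = [recist_sum(selection, exam_id) for exam_id in exam_ids]
    assessments = []
    for t in range(1, len(sums)):
        exam_id = exam_ids[t]
        axes: Sequence[float]
        if lymph_node_short_axes_mm is not None:
            axes = lymph_node_short_axes_mm.get(exam_id, ())
        else:
            axes = [
                lesion.diameter(exam_id)
                for lesion in selection
                if lesion.kind == "lymph_node" and lesion.present(exam_id)
            ]
        non_nodal_gone = all(
            not lesion.present(exam_id) for lesion in selection if lesion.kind == "lesion"
        )
        assessments.append(
            classify_response(
                sums[: t + 1],
                lymph_node_short_axes_mm=axes,
                new_lesions=bool(new_lesion_flags.get(exam_id, False)),
                targets_disappeared=non_nodal_gone,
            )
        )
    return assessments
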