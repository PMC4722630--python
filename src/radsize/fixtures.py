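"""Packaged mini knowledge base and deterministic synthetic cohorts.

The packaged KB covers the anatomy needed by the classifier's worked
examples: a lymph-node subtree, spleen, kidney, gallbladder wall,
ureter, aorta segments, thorax/abdomen regions and a lesion branch,
with the standard normal-size statements (lymph-node short axis <= 1
cm, gallbladder-wall thickness 1-3 mm, spleen height/length/width
intervals, ...).

The generator emulates measurement findings extracted from serial CT
reports of a small cohort: per patient a baseline and follow-up exams,
organ measurements drawn inside or outside their normal ranges with a
pre-decided gold label, and target lesions whose diameters evolve by a
per-scenario scale factor under multiplicative noise.  Gold labels are
fixed at draw time from the generating parameters, never by running
the classifier.  Everything is seeded and reproducible bit for bit.
"""

from __future__ import annotations

import datetime as dt
import json
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .findings import Measurement, MeasurementFinding
from .ontology_kb import (
    AnatomyGraph,
    SpecificationSet,
    load_anatomy,
    read_specs_file,
)
from .qualities import CRANIOCAUDAL_DIAMETER, LONGEST_AXIS, SHORT_AXIS
from .recist import TargetLesion

SCENARIOS = ("CR", "PR", "PD", "SD", "mixed")

#: follow-up scale factor per scenario, chosen with margin to the
#: response thresholds so the expected label survives the noise band
SCENARIO_FACTORS = {"CR": 0.0, "PR": 0.65, "PD": 1.4, "SD": 1.0}

#: residual short axis of nodal targets once a patient reaches CR (mm)
CR_NODE_RESIDUAL_MM = 6.0

# example sentences in the style of the source reports (German),
# exercising non-ASCII handling end to end
_SENTENCES = {
    "lymph_node": "Die LK im aortopulmonalen Fenster und prätracheal größenunverändert mit einer Größe von bis zu {size}.",
    "organ": "Die {label} misst {size}, regelrechte Größe und Konfiguration.",
    "lesion": "Nachweis einer Läsion in der {label} mit einer Größe von {size}.",
}


def packaged_kb() -> tuple[AnatomyGraph, SpecificationSet]:
    """Load the packaged anatomy graph and normal-size specifications."""
    data = resources.files("radsize") / "data"
    labels: dict[str, str] = {}
    for line in (data / "anatomy_labels.tsv").read_text("utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        concept_id, label = line.split("\t")
        labels[concept_id] = label
    records = []
    for line in (data / "anatomy_edges.tsv").read_text("utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        child, parent, relation = line.split("\t")
        records.append((child, parent, relation))
    graph = load_anatomy(records, labels)
    import io

    specs = read_specs_file(io.StringIO((data / "specs.yaml").read_text("utf-8")), graph)
    return graph, specs


@dataclass(frozen=True)
class Scenario:
    """Study conditions for one synthetic cohort."""

    name: str = "mixed"
    n_patients: int = 5
    exams_per_patient: int = 3
    noise: float = 0.05  # multiplicative, uniform in [1 - noise, 1 + noise]
    p_abnormal: float = 0.35  # share of organ findings drawn abnormal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; expected one of {SCENARIOS}")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if self.exams_per_patient < 2:
            raise ValueError("need a baseline and at least one follow-up exam")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")


@dataclass
class GeneratedCohort:
    findings: list[MeasurementFinding]
    gold_normality: dict[str, str]  # finding id -> normal/abnormal
    covered: set[str]  # finding ids whose entity has a KB specification
    selections: dict[str, list[TargetLesion]]  # patient -> target selection
    new_lesion_flags: dict[str, dict[str, bool]]  # patient -> exam -> flag
    exam_ids: dict[str, list[str]]  # patient -> chronological exam ids
    gold_response: dict[str, dict[str, str]]  # patient -> follow-up exam -> label

    def write(self, outdir: Path | str) -> None:
        """Write the cohort as plain-text files (JSON-Lines + JSON)."""
        from .findings import finding_to_record

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "findings.jsonl", "w", encoding="utf-8") as fh:
            for finding in self.findings:
                rec = finding_to_record(finding)
                rec.pop("finding_type")
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
        with open(outdir / "selection.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    patient: [
                        {
                            "lesion_id": t.lesion_id,
                            "entity": t.entity,
                            "organ": t.organ,
                            "kind": t.kind,
                            "diameters_mm": t.diameters_mm,
                        }
                        for t in lesions
                    ]
                    for patient, lesions in self.selections.items()
                },
                fh,
                indent=1,
            )
        with open(outdir / "new_lesions.json", "w", encoding="utf-8") as fh:
            json.dump(self.new_lesion_flags, fh, indent=1)
        with open(outdir / "gold.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "normality": self.gold_normality,
                    "covered": sorted(self.covered),
                    "response": self.gold_response,
                    "exam_ids": self.exam_ids,
                },
                fh,
                indent=1,
            )


# (entity, label, quality or None, normal draw, abnormal draw) for organ
# findings; draws return values in mm.  Normal draws keep a margin to
# the range boundary; abnormal draws sit clearly outside.
def _organ_templates(rng: random.Random):
    def inside(lo: float, hi: float) -> float:
        margin = 0.15 * (hi - lo)
        return rng.uniform(lo + margin, hi - margin)

    def above(hi: float) -> float:
        return rng.uniform(1.1 * hi, 1.3 * hi)

    def below(lo: float) -> float:
        return rng.uniform(0.7 * lo, 0.9 * lo)

    return [
        # kidney, labelled craniocaudal diameter, interval 80-130 mm
        (
            "RID205",
            "kidney",
            CRANIOCAUDAL_DIAMETER,
            lambda: inside(80, 130),
            lambda: above(130) if rng.random() < 0.5 else below(80),
        ),
        # gallbladder wall, unlabeled single value, interval 1-3 mm
        (
            "RID33779",
            "wall of gallbladder",
            None,
            lambda: inside(1, 3),
            lambda: above(3),
        ),
        # ureter, unlabeled single value, interval 4-7 mm
        ("RID229", "ureter", None, lambda: inside(4, 7), lambda: above(7)),
        # ascending aorta, unlabeled diameter, lower bound 40 mm
        ("RID580", "ascending aorta", None, lambda: rng.uniform(42, 52), lambda: below(40)),
    ]


_SPLEEN_RANGES = ((110.0, 150.0), (70.0, 100.0), (40.0, 60.0))  # height, length, width


def _spleen_values(rng: random.Random, abnormal: bool) -> list[float]:
    values = []
    for lo, hi in _SPLEEN_RANGES:
        margin = 0.15 * (hi - lo)
        values.append(rng.uniform(lo + margin, hi - margin))
    if abnormal:
        # scale all dimensions together: splenomegaly (or a uniformly
        # small spleen), keeping the descending height > length > width
        # order the positional assignment relies on
        scale = 1.35 if rng.random() < 0.7 else 0.6
        values = [v * scale for v in values]
    return values


def _noisy(value: float, rng: random.Random, noise: float) -> float:
    return value * rng.uniform(1.0 - noise, 1.0 + noise)


def generate(scenario: Scenario) -> GeneratedCohort:
    """Generate a seeded synthetic cohort for the given scenario."""
    rng = random.Random(scenario.seed)
    cohort = GeneratedCohort([], {}, set(), {}, {}, {}, {})

    base_date = dt.date(2015, 1, 15)
    entities_with_specs = {"RID205", "RID33779", "RID229", "RID580", "RID86", "RID13296"}

    for p in range(scenario.n_patients):
        patient = f"P{p + 1:03d}"
        if scenario.name == "mixed":
            response = ("CR", "PR", "PD", "SD")[p % 4]
        else:
            response = scenario.name
        factor = SCENARIO_FACTORS[response]
        pd_by_new_lesion = response == "PD" and p % 2 == 0 and scenario.name == "mixed"

        exam_ids = [f"{patient}-e{t + 1}" for t in range(scenario.exams_per_patient)]
        cohort.exam_ids[patient] = exam_ids
        cohort.new_lesion_flags[patient] = {e: False for e in exam_ids}
        cohort.gold_response[patient] = {e: response for e in exam_ids[1:]}

        fid_counter = 0

        def make_finding(
            exam_idx: int,
            entity: str,
            label: str,
            kind: str,
            measurements: list[Measurement],
            sentence_kind: str,
        ) -> MeasurementFinding:
            nonlocal fid_counter
            fid_counter += 1
            size = " x ".join(f"{m.value:g}" for m in measurements) + f" {measurements[0].unit}"
            sentence = _SENTENCES[sentence_kind].format(label=label, size=size)
            finding = MeasurementFinding(
                finding_id=f"{patient}-f{fid_counter:03d}",
                patient_id=patient,
                exam_id=exam_ids[exam_idx],
                exam_date=base_date + dt.timedelta(days=90 * exam_idx),
                entity=entity,
                entity_kind=kind,
                measurements=measurements,
                sentence=sentence,
                entity_label=label,
            )
            cohort.findings.append(finding)
            return finding

        # --- organ findings (normality classification material) -----
        for t in range(scenario.exams_per_patient):
            for entity, label, quality, draw_normal, draw_abnormal in _organ_templates(rng):
                abnormal = rng.random() < scenario.p_abnormal
                value = draw_abnormal() if abnormal else draw_normal()
                f = make_finding(
                    t,
                    entity,
                    label,
                    "anatomical_structure",
                    [
                        Measurement(
                            round(_noisy(value, rng, scenario.noise), 1), "mm", quality
                        )
                    ],
                    "organ",
                )
                cohort.gold_normality[f.finding_id] = "abnormal" if abnormal else "normal"
                cohort.covered.add(f.finding_id)

            # spleen, unlabeled three-dimensional
            abnormal = rng.random() < scenario.p_abnormal
            values = _spleen_values(rng, abnormal)
            f = make_finding(
                t,
                "RID86",
                "spleen",
                "anatomical_structure",
                [
                    Measurement(round(_noisy(v / 10.0, rng, scenario.noise), 1), "cm")
                    for v in values
                ],
                "organ",
            )
            cohort.gold_normality[f.finding_id] = "abnormal" if abnormal else "normal"
            cohort.covered.add(f.finding_id)

            # a non-target lymph node with labelled axes
            abnormal = rng.random() < scenario.p_abnormal
            short = rng.uniform(11.5, 14.0) if abnormal else rng.uniform(3.0, 8.5)
            ln_entity = rng.choice(
                ["mediastinal-lymph-node", "axillary-lymph-node", "aortopulmonary-lymph-node"]
            )
            f = make_finding(
                t,
                ln_entity,
                ln_entity.replace("-", " "),
                "lymph_node",
                [
                    Measurement(
                        round(_noisy(short * rng.uniform(1.3, 1.8), rng, scenario.noise), 1),
                        "mm",
                        LONGEST_AXIS,
                    ),
                    Measurement(
                        round(_noisy(short, rng, scenario.noise), 1), "mm", SHORT_AXIS
                    ),
                ],
                "lymph_node",
            )
            cohort.gold_normality[f.finding_id] = "abnormal" if abnormal else "normal"
            cohort.covered.add(f.finding_id)

            # an uncovered entity: stays unclassifiable by construction
            f = make_finding(
                t,
                "rib",
                "rib",
                "anatomical_structure",
                [Measurement(round(rng.uniform(15, 35), 1), "mm")],
                "organ",
            )
            cohort.gold_normality[f.finding_id] = "normal"

        # --- target lesions (RECIST material) ------------------------
        lesion_specs = [
            ("liver-lesion", "liver", "lesion", rng.uniform(15, 40)),
            ("liver-lesion", "liver", "lesion", rng.uniform(12, 30)),
            ("lung-lesion", "lung", "lesion", rng.uniform(11, 35)),
            ("mediastinal-lymph-node", "mediastinum", "lymph_node", rng.uniform(16, 28)),
        ]
        selection = []
        for j, (entity, organ, kind, baseline_mm) in enumerate(lesion_specs):
            diameters: dict[str, float] = {}
            for t, exam_id in enumerate(exam_ids):
                if t == 0:
                    d = baseline_mm
                elif pd_by_new_lesion:
                    d = _noisy(baseline_mm, rng, scenario.noise)
                elif response == "CR":
                    d = CR_NODE_RESIDUAL_MM if kind == "lymph_node" else 0.0
                else:
                    d = _noisy(baseline_mm * factor**t, rng, scenario.noise)
                d = round(d, 1)  # the value as it would be reported
                diameters[exam_id] = d
                if d > 0:
                    if kind == "lymph_node":
                        ms = [
                            Measurement(round(d * 1.5, 1), "mm", LONGEST_AXIS),
                            Measurement(d, "mm", SHORT_AXIS),
                        ]
                        f = make_finding(t, entity, entity.replace("-", " "), kind, ms, "lymph_node")
                        cohort.gold_normality[f.finding_id] = (
                            "abnormal" if d > 10.0 else "normal"
                        )
                        cohort.covered.add(f.finding_id)
                    else:
                        ms = [Measurement(d, "mm", LONGEST_AXIS)]
                        f = make_finding(t, entity, entity.replace("-", " "), kind, ms, "lesion")
                        cohort.gold_normality[f.finding_id] = "abnormal"
                        cohort.covered.add(f.finding_id)
            selection.append(
                TargetLesion(
                    lesion_id=f"{patient}-T{j + 1}",
                    entity=entity,
                    organ=organ,
                    kind=kind,
                    diameters_mm=diameters,
                )
            )
        cohort.selections[patient] = selection
        if pd_by_new_lesion:
            for exam_id in exam_ids[1:]:
                cohort.new_lesion_flags[patient][exam_id] = True

    return cohort
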