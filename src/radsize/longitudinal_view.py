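"""Longitudinal finding review: selective retrieval and red/green rendering.

Classified findings are retrieved by anatomical entity (subclass
closure) or body region (part-of closure) and arranged into per-entity
tracks over consecutive exams.  For organs that exist exactly once in
the body (liver, spleen, ...) consecutive findings describe the same
structure, so the track is *linked*; lymph nodes and lesions cannot be
identified across exams reliably, so their entries are grouped by
entity label only and the track is marked unlinked.  Rendering shows
measured values next to the verbatim report sentence, with abnormal
findings in red and normal ones in green; unclassified stays neutral.
"""

from __future__ import annotations

import html
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .findings import MeasurementFinding, exam_sort_key
from .ontology_kb import AnatomyGraph, KBError

#: anatomical entities that occur exactly once in the body and can be
#: linked across exams; configurable per deployment
DEFAULT_SINGLETON_ENTITIES = frozenset(
    {
        "liver",
        "RID86",  # spleen
        "left-kidney",
        "right-kidney",
        "gallbladder",
        "RID33779",  # wall of gallbladder
        "RID580",  # ascending aorta
        "aortic-arch",
        "aorta",
        "trachea",
    }
)


@dataclass(frozen=True)
class TrackEntry:
    exam_date: str
    exam_id: str
    measurements: str  # display string, e.g. "1.6 x 1.2 cm"
    label: str  # normal / abnormal / unclassified
    sentence: str


@dataclass(frozen=True)
class FindingTrack:
    patient_id: str
    entity: str
    entity_label: str
    linked: bool
    entries: tuple[TrackEntry, ...]


def select_findings(
    findings: Sequence[MeasurementFinding],
    graph: AnatomyGraph,
    by_entity: Optional[str] = None,
    by_region: Optional[str] = None,
) -> list[MeasurementFinding]:
    """Filter findings by anatomical entity or body region.

    ``by_entity`` keeps findings whose entity is the given concept or
    any subclass of it; ``by_region`` keeps findings whose entity
    reaches the region through the combined subclass / part-of closure.
    """
    if (by_entity is None) == (by_region is None):
        raise ValueError("pass exactly one of by_entity or by_region")
    target = by_entity if by_entity is not None else by_region
    if target not in graph:
        raise KBError(f"unknown concept {target!r}")
    out = []
    for finding in findings:
        if finding.entity not in graph:
            continue
        if by_entity is not None:
            if graph.is_a(finding.entity, by_entity):
                out.append(finding)
        else:
            if by_region in graph.region_closure(finding.entity):
                out.append(finding)
    return out


def _display_measurements(finding: MeasurementFinding) -> str:
    unit = finding.measurements[0].unit
    if all(m.unit == unit for m in finding.measurements):
        values = " x ".join(f"{m.value:g}" for m in finding.measurements)
        return f"{values} {unit}"
    return " x ".join(f"{m.value:g} {m.unit}" for m in finding.measurements)


def build_tracks(
    findings: Sequence[MeasurementFinding],
    singleton_entities: frozenset[str] = DEFAULT_SINGLETON_ENTITIES,
) -> list[FindingTrack]:
    """Group one patient's classified findings into longitudinal tracks.

    Singleton entities yield one linked track holding all their exams;
    everything else (lymph nodes, lesions) yields an unlinked track per
    entity whose entries are displayed side by side without asserting
    identity across exams.
    """
    patients = {f.patient_id for f in findings}
    if len(patients) > 1:
        raise ValueError(f"build_tracks expects one patient, got {sorted(patients)}")
    groups: dict[str, list[MeasurementFinding]] = {}
    for finding in findings:
        groups.setdefault(finding.entity, []).append(finding)
    tracks = []
    for entity in sorted(groups):
        fs = sorted(groups[entity], key=exam_sort_key)
        entries = tuple(
            TrackEntry(
                exam_date=f.exam_date.isoformat(),
                exam_id=f.exam_id,
                measurements=_display_measurements(f),
                label=f.finding_type,
                sentence=f.sentence,
            )
            for f in fs
        )
        tracks.append(
            FindingTrack(
                patient_id=fs[0].patient_id,
                entity=entity,
                entity_label=fs[0].entity_label or entity,
                linked=entity in singleton_entities,
                entries=entries,
            )
        )
    return tracks


_TEXT_MARK = {"abnormal": "[ABNORMAL]", "normal": "[normal]", "unclassified": "[--]"}
_CSS_CLASS = {"abnormal": "abnormal", "normal": "normal", "unclassified": "neutral"}


def _exam_columns(tracks: Sequence[FindingTrack]) -> list[tuple[str, str]]:
    exams = {(e.exam_date, e.exam_id) for t in tracks for e in t.entries}
    return sorted(exams)


def render(tracks: Sequence[FindingTrack], format: str = "text") -> str:
    """Render tracks as a chronological table (one column per exam).

    Pure function of its inputs: the same tracks always produce a
    byte-identical document.
    """
    if format == "text":
        return _render_text(tracks)
    if format == "html":
        return _render_html(tracks)
    raise ValueError(f"unknown format {format!r}; expected 'text' or 'html'")


def _cell(track: FindingTrack, exam: tuple[str, str]) -> Optional[TrackEntry]:
    for entry in track.entries:
        if (entry.exam_date, entry.exam_id) == exam:
            return entry
    return None


def _render_text(tracks: Sequence[FindingTrack]) -> str:
    columns = _exam_columns(tracks)
    lines = ["exam:      " + "  |  ".join(date for date, _ in columns)]
    for track in tracks:
        linkage = "linked" if track.linked else "unlinked"
        lines.append(f"{track.entity_label} ({linkage}):")
        cells = []
        for exam in columns:
            entry = _cell(track, exam)
            if entry is None:
                cells.append("-")
            else:
                cells.append(
                    f"{entry.measurements} {_TEXT_MARK[entry.label]} {entry.sentence}".strip()
                )
        lines.append("    " + "  |  ".join(cells))
    return "\n".join(lines) + "\n"


_HTML_HEAD = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>finding review</title>
<style>
table { border-collapse: collapse; }
td, th { border: 1px solid #999; padding: 4px 8px; vertical-align: top; }
td.abnormal { background: #fbb; }
td.normal { background: #bfb; }
td.neutral { background: #eee; }
.sentence { color: #333; font-size: smaller; display: block; }
</style></head><body>
"""


def _render_html(tracks: Sequence[FindingTrack]) -> str:
    columns = _exam_columns(tracks)
    parts = [_HTML_HEAD, "<table>\n<tr><th>entity</th>"]
    for date, exam_id in columns:
        parts.append(f"<th>{html.escape(date)}<br>{html.escape(exam_id)}</th>")
    parts.append("</tr>\n")
    for track in tracks:
        linkage = "linked" if track.linked else "unlinked"
        parts.append(f"<tr><td>{html.escape(track.entity_label)} ({linkage})</td>")
        for exam in columns:
            entry = _cell(track, exam)
            if entry is None:
                parts.append('<td class="neutral"></td>')
            else:
                parts.append(
                    f'<td class="{_CSS_CLASS[entry.label]}">{html.escape(entry.measurements)}'
                    f'<span class="sentence">{html.escape(entry.sentence)}</span></td>'
                )
        parts.append("</tr>\n")
    parts.append("</table>\n</body></html>\n")
    return "".join(parts)
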