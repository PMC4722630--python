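"""The size-quality hierarchy.

Qualities follow the PATO size branch: ``size`` is the root, ``1-D
extent`` is its child, and the familiar one-dimensional qualities
(length, width, height, thickness, diameter) sit below that.  Four
radiology-specific qualities are added: ``craniocaudal diameter`` and
``left-right diameter`` as subclasses of ``diameter``, and ``longest
axis`` / ``short axis`` as subclasses of ``1-D extent``.  The short
axis is the longest extent orthogonal to the longest in-plane axis
and is the relevant diameter for lymph nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class QualityKind:
    """One node of the quality hierarchy."""

    name: str
    parent: Optional["QualityKind"] = None

    def ancestors(self) -> list["QualityKind"]:
        """Reflexive list of ancestors from self up to the root."""
        out, node = [], self
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def is_a(self, other: "QualityKind") -> bool:
        """True if self equals *other* or is a (transitive) subclass."""
        return other in self.ancestors()

    def path_length_to(self, other: "QualityKind") -> Optional[int]:
        """Subclass-path length from self up to *other*; None if not an ancestor."""
        for i, anc in enumerate(self.ancestors()):
            if anc == other:
                return i
        return None

    def __repr__(self) -> str:  # keep error messages short
        return f"QualityKind({self.name!r})"


SIZE = QualityKind("size")
ONE_D_EXTENT = QualityKind("1-D extent", SIZE)
LENGTH = QualityKind("length", ONE_D_EXTENT)
WIDTH = QualityKind("width", ONE_D_EXTENT)
HEIGHT = QualityKind("height", ONE_D_EXTENT)
THICKNESS = QualityKind("thickness", ONE_D_EXTENT)
DIAMETER = QualityKind("diameter", ONE_D_EXTENT)
CRANIOCAUDAL_DIAMETER = QualityKind("craniocaudal diameter", DIAMETER)
LEFT_RIGHT_DIAMETER = QualityKind("left-right diameter", DIAMETER)
LONGEST_AXIS = QualityKind("longest axis", ONE_D_EXTENT)
SHORT_AXIS = QualityKind("short axis", ONE_D_EXTENT)

ALL_QUALITIES = (
    SIZE,
    ONE_D_EXTENT,
    LENGTH,
    WIDTH,
    HEIGHT,
    THICKNESS,
    DIAMETER,
    CRANIOCAUDAL_DIAMETER,
    LEFT_RIGHT_DIAMETER,
    LONGEST_AXIS,
    SHORT_AXIS,
)

_BY_NAME = {q.name: q for q in ALL_QUALITIES}
# accept common spelling variants seen in input files
_ALIASES = {
    "1d extent": ONE_D_EXTENT,
    "1-d extent": ONE_D_EXTENT,
    "one-dimensional extent": ONE_D_EXTENT,
    "cranio-caudal diameter": CRANIOCAUDAL_DIAMETER,
    "craniocaudal_diameter": CRANIOCAUDAL_DIAMETER,
    "left-right_diameter": LEFT_RIGHT_DIAMETER,
    "longest_axis": LONGEST_AXIS,
    "short_axis": SHORT_AXIS,
}


def get_quality(name: str) -> QualityKind:
    """Resolve a quality by name (case-insensitive, tolerant of _ for space)."""
    key = name.strip().lower()
    if key in _BY_NAME:
        return _BY_NAME[key]
    if key in _ALIASES:
        return _ALIASES[key]
    key2 = key.replace("_", " ")
    if key2 in _BY_NAME:
        return _BY_NAME[key2]
    raise KeyError(f"unknown size quality {name!r}")
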