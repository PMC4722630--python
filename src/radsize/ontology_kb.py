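"""Anatomical hierarchy and the normal-size knowledge base.

The knowledge base pairs anatomical entities (nodes of a subclass /
part-of DAG, RadLex-style identifiers) with normal-size statements:
an upper bound, a lower bound, or an interval for one size quality of
one entity.  Classification retrieves, for a measured (entity,
quality) pair, the *most specific* applicable statement along both
subclass hierarchies — the Entity–Quality (EQ) matching scheme.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import yaml

from .qualities import QualityKind, get_quality
from .units import to_mm

SUBCLASS_OF = "subclass_of"
PART_OF = "part_of"
UNREACHABLE = "unreachable"


class KBError(Exception):
    """Knowledge-base loading or lookup failure."""


class CycleError(KBError):
    """A relation layer that must be acyclic contains a cycle."""


class AmbiguousSpecificationError(KBError):
    """Two applicable specifications tie on both subclass path lengths."""


@dataclass(frozen=True)
class Concept:
    """An anatomical concept: opaque identifier plus display label."""

    identifier: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("concept identifier must be non-empty")


class AnatomyGraph:
    """Concept hierarchy with separate subclass-of and part-of layers.

    Both layers are DAGs over the same node set.  Edges point from the
    more specific concept to the more general one (child -> parent,
    part -> whole).
    """

    def __init__(self) -> None:
        self.subclass = nx.DiGraph()
        self.partof = nx.DiGraph()
        self.labels: dict[str, str] = {}

    # -- construction -------------------------------------------------
    def add_concept(self, identifier: str, label: str = "") -> None:
        if not identifier:
            raise ValueError("concept identifier must be non-empty")
        self.subclass.add_node(identifier)
        self.partof.add_node(identifier)
        if label:
            self.labels[identifier] = label

    def add_edge(self, child: str, parent: str, relation: str) -> None:
        layer = self._layer(relation)
        if layer.has_edge(child, parent):
            warnings.warn(
                f"duplicate {relation} edge {child} -> {parent}; deduplicated",
                stacklevel=2,
            )
            return
        for g in (self.subclass, self.partof):
            g.add_node(child)
            g.add_node(parent)
        layer.add_edge(child, parent)

    def _layer(self, relation: str) -> nx.DiGraph:
        if relation == SUBCLASS_OF:
            return self.subclass
        if relation == PART_OF:
            return self.partof
        raise KBError(f"unknown relation {relation!r}")

    def check_acyclic(self) -> None:
        for name, g in ((SUBCLASS_OF, self.subclass), (PART_OF, self.partof)):
            try:
                cycle = nx.find_cycle(g)
            except nx.NetworkXNoCycle:
                continue
            raise CycleError(f"cycle in {name} relation: {cycle}")

    # -- queries ------------------------------------------------------
    def __contains__(self, identifier: str) -> bool:
        return identifier in self.subclass

    def nodes(self) -> list[str]:
        return list(self.subclass.nodes)

    def label(self, identifier: str) -> str:
        return self.labels.get(identifier, identifier)

    def require(self, identifier: str) -> None:
        if identifier not in self:
            raise KBError(f"unknown concept {identifier!r}")

    def subclass_ancestors(self, identifier: str) -> set[str]:
        """Reflexive transitive subclass closure (identifier and everything above it)."""
        self.require(identifier)
        return {identifier} | nx.descendants(self.subclass, identifier)

    def subclass_descendants(self, identifier: str) -> set[str]:
        """Reflexive set of concepts that are the identifier or a subclass of it."""
        self.require(identifier)
        return {identifier} | nx.ancestors(self.subclass, identifier)

    def is_a(self, a: str, b: str) -> bool:
        """True if a equals b or is a transitive subclass of b."""
        return b in self.subclass_ancestors(a)

    def region_closure(self, identifier: str) -> set[str]:
        """Concepts reachable upward from *identifier* over subclass-of and part-of.

        Used for body-region retrieval: an entity belongs to a region
        when some chain of subclass and part-of steps reaches it.
        """
        self.require(identifier)
        seen = {identifier}
        stack = [identifier]
        while stack:
            node = stack.pop()
            for g in (self.subclass, self.partof):
                for parent in g.successors(node):
                    if parent not in seen:
                        seen.add(parent)
                        stack.append(parent)
        return seen


def load_anatomy(
    edge_records: Iterable[tuple[str, str, str]],
    labels: Optional[dict[str, str]] = None,
) -> AnatomyGraph:
    """Build an :class:`AnatomyGraph` from (child, parent, relation) records.

    Raises :class:`CycleError` if either relation layer is cyclic (a
    self-edge is the degenerate case).  Duplicate edges are warned
    about and deduplicated.
    """
    graph = AnatomyGraph()
    for identifier, label in (labels or {}).items():
        graph.add_concept(identifier, label)
    for child, parent, relation in edge_records:
        graph.add_edge(child, parent, relation)
    graph.check_acyclic()
    return graph


def read_anatomy_files(
    edges_path: Union[str, Path], labels_path: Optional[Union[str, Path]] = None
) -> AnatomyGraph:
    """Read the tab-separated edge list and optional label file."""
    labels: dict[str, str] = {}
    if labels_path is not None:
        with open(labels_path, encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                labels[row[0]] = row[1]
    records = []
    with open(edges_path, encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise KBError(f"{edges_path}:{lineno}: expected child<TAB>parent<TAB>relation")
            records.append((row[0], row[1], row[2]))
    return load_anatomy(records, labels)


def subclass_path_length(graph: AnatomyGraph, a: str, b: str) -> Union[int, str]:
    """Shortest directed chain of subclass edges from *a* up to *b*.

    Returns 0 iff ``a == b`` and the string ``"unreachable"`` when no
    chain exists (disjoint branches).
    """
    graph.require(a)
    graph.require(b)
    try:
        return nx.shortest_path_length(graph.subclass, a, b)
    except nx.NetworkXNoPath:
        return UNREACHABLE


# ---------------------------------------------------------------------------
# Normal-size specifications


UPPER_BOUND = "upper_bound"
LOWER_BOUND = "lower_bound"
INTERVAL = "interval"
RANGE_TYPES = (UPPER_BOUND, LOWER_BOUND, INTERVAL)


@dataclass(frozen=True)
class SizeSpecification:
    """One normal-size statement about an (entity, quality) pair.

    Bounds are stored in mm.  ``upper_bound`` carries only ``high_mm``
    (normal iff value <= high), ``lower_bound`` only ``low_mm`` (normal
    iff value >= low), and ``interval`` both (normal iff low <= value
    <= high); all bounds are inclusive.
    """

    entity: str
    quality: QualityKind
    range_type: str
    low_mm: Optional[float] = None
    high_mm: Optional[float] = None
    spec_id: str = ""

    def __post_init__(self) -> None:
        if self.range_type not in RANGE_TYPES:
            raise ValueError(f"unknown range type {self.range_type!r}")
        if self.range_type == UPPER_BOUND:
            if self.high_mm is None or self.low_mm is not None:
                raise ValueError("upper_bound requires high and forbids low")
        elif self.range_type == LOWER_BOUND:
            if self.low_mm is None or self.high_mm is not None:
                raise ValueError("lower_bound requires low and forbids high")
        else:
            if self.low_mm is None or self.high_mm is None:
                raise ValueError("interval requires both bounds")
            if not self.low_mm < self.high_mm:
                raise ValueError(
                    f"interval requires low < high, got [{self.low_mm}, {self.high_mm}] mm"
                )
        for bound in (self.low_mm, self.high_mm):
            if bound is not None and bound <= 0:
                raise ValueError("bounds must be strictly positive")

    @property
    def sort_bound_mm(self) -> float:
        """Upper bound, or the lower bound when no upper bound exists.

        Used to order specifications when pairing unlabeled measured
        values with qualities.
        """
        return self.high_mm if self.high_mm is not None else self.low_mm  # type: ignore[return-value]


class SpecificationSet:
    """A validated, order-independent collection of size specifications."""

    def __init__(self, specs: Sequence[SizeSpecification]) -> None:
        self._specs = tuple(sorted(specs, key=lambda s: (s.entity, s.quality.name, s.spec_id)))

    def __iter__(self):
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __eq__(self, other) -> bool:
        return isinstance(other, SpecificationSet) and self._specs == other._specs

    def by_id(self, spec_id: str) -> SizeSpecification:
        for spec in self._specs:
            if spec.spec_id == spec_id:
                return spec
        raise KeyError(spec_id)


def load_specs(
    spec_records: Iterable[dict],
    graph: AnatomyGraph,
) -> SpecificationSet:
    """Validate raw specification records against the anatomy and quality hierarchies.

    Each record carries ``entity_id``, ``quality``, ``range_type``,
    ``low``/``high`` and ``unit``; bounds are normalised to mm.  A record
    whose entity or quality cannot be resolved, or whose bounds are
    malformed, aborts the load with a message naming the record.
    Records flagged ``enabled: false`` are skipped (shipped alternatives).
    """
    specs: list[SizeSpecification] = []
    for i, rec in enumerate(spec_records):
        if not rec.get("enabled", True):
            continue
        where = f"specification record {i} ({rec})"
        entity = rec.get("entity_id")
        if not entity or entity not in graph:
            raise KBError(f"unresolvable entity in {where}")
        try:
            quality = get_quality(rec["quality"])
        except KeyError as exc:
            raise KBError(f"unresolvable quality in {where}: {exc}") from None
        unit = rec.get("unit", "mm")
        try:
            low = to_mm(float(rec["low"]), unit) if rec.get("low") is not None else None
            high = to_mm(float(rec["high"]), unit) if rec.get("high") is not None else None
            spec = SizeSpecification(
                entity=entity,
                quality=quality,
                range_type=rec["range_type"],
                low_mm=low,
                high_mm=high,
                spec_id=rec.get("id") or f"{entity}:{quality.name}:{rec['range_type']}",
            )
        except (ValueError, KeyError) as exc:
            raise KBError(f"malformed bounds in {where}: {exc}") from None
        specs.append(spec)
    return SpecificationSet(specs)


def read_specs_file(path: Union[str, Path, io.TextIOBase], graph: AnatomyGraph) -> SpecificationSet:
    """Read a YAML/JSON specification document (a list of records)."""
    if isinstance(path, io.TextIOBase):
        records = yaml.safe_load(path)
    else:
        with open(path, encoding="utf-8") as fh:
            records = yaml.safe_load(fh)
    if not isinstance(records, list):
        raise KBError("specification file must contain a list of records")
    return load_specs(records, graph)


# ---------------------------------------------------------------------------
# Most-specific EQ retrieval


def applicable_specs(
    graph: AnatomyGraph, specs: SpecificationSet, entity: str, quality: QualityKind
) -> list[SizeSpecification]:
    """All specifications whose entity/quality subsume the query pair."""
    ancestors = graph.subclass_ancestors(entity)
    return [s for s in specs if s.entity in ancestors and quality.is_a(s.quality)]


def most_specific_spec(
    graph: AnatomyGraph,
    specs: SpecificationSet,
    entity: str,
    quality: QualityKind,
) -> Optional[SizeSpecification]:
    """Retrieve the most specific specification for an (entity, quality) pair.

    A candidate (E', Q') applies when the queried entity E is E' or a
    subclass of E' and likewise for the quality.  A candidate is
    dominated when another applicable spec (E'', Q'') has E'' strictly
    on the subclass path between E and E' and Q'' on the path between
    Q and Q'.  Among the non-dominated candidates the one with the
    shortest subclass path from E to E' wins; a remaining tie is broken
    by the shorter quality path, and an exact double tie raises
    :class:`AmbiguousSpecificationError` rather than picking arbitrarily.

    Returns ``None`` when no specification applies (the finding will be
    left unclassified).
    """
    candidates = applicable_specs(graph, specs, entity, quality)
    if not candidates:
        return None

    def entity_between(mid: str, top: str) -> bool:
        # mid lies on a subclass path between the query entity and top
        return graph.is_a(entity, mid) and graph.is_a(mid, top)

    def quality_between(mid: QualityKind, top: QualityKind) -> bool:
        return quality.is_a(mid) and mid.is_a(top)

    surviving = []
    for cand in candidates:
        dominated = False
        for other in candidates:
            if other is cand:
                continue
            if (
                other.entity != cand.entity
                and entity_between(other.entity, cand.entity)
                and quality_between(other.quality, cand.quality)
            ):
                dominated = True
                break
        if not dominated:
            surviving.append(cand)

    def keys(spec: SizeSpecification) -> tuple[int, int]:
        e_len = subclass_path_length(graph, entity, spec.entity)
        q_len = quality.path_length_to(spec.quality)
        assert isinstance(e_len, int) and q_len is not None
        return e_len, q_len

    surviving.sort(key=keys)
    best_e, best_q = keys(surviving[0])
    ties = [s for s in surviving if keys(s) == (best_e, best_q)]
    if len(ties) > 1:
        raise AmbiguousSpecificationError(
            f"ambiguous knowledge base: {[t.spec_id for t in ties]} tie for "
            f"({entity}, {quality.name}) at entity path {best_e}, quality path {best_q}"
        )
    return surviving[0]


def specs_for_entity(
    graph: AnatomyGraph, specs: SpecificationSet, entity: str
) -> list[SizeSpecification]:
    """Distinct most-specific specifications applicable to *entity*, one per quality.

    For every quality that appears on an applicable specification, the
    most specific spec for (entity, that quality) is retrieved; the
    deduplicated result is the set available for pairing with unlabeled
    measured values.
    """
    ancestors = graph.subclass_ancestors(entity)
    qualities = {s.quality for s in specs if s.entity in ancestors}
    out: list[SizeSpecification] = []
    seen: set[str] = set()
    for q in sorted(qualities, key=lambda q: q.name):
        spec = most_specific_spec(graph, specs, entity, q)
        if spec is not None and spec.spec_id not in seen:
            seen.add(spec.spec_id)
            out.append(spec)
    return out
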