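"""Anatomy graph loading and most-specific EQ specification retrieval."""

import itertools

import pytest

from radsize.ontology_kb import (
    AmbiguousSpecificationError,
    CycleError,
    KBError,
    SizeSpecification,
    SpecificationSet,
    load_anatomy,
    load_specs,
    most_specific_spec,
    subclass_path_length,
)
from radsize.qualities import (
    ALL_QUALITIES,
    DIAMETER,
    ONE_D_EXTENT,
    SHORT_AXIS,
    THICKNESS,
    get_quality,
)


class TestLoadAnatomy:
    def test_single_edge_gives_path_length_one(self):
        g = load_anatomy([("mediastinal-ln", "ln", "subclass_of")])
        assert subclass_path_length(g, "mediastinal-ln", "ln") == 1

    def test_self_cycle_fails(self):
        with pytest.raises(CycleError):
            load_anatomy([("submental-ln", "ln", "subclass_of"), ("ln", "ln", "subclass_of")])

    def test_longer_cycle_fails_in_partof_layer(self):
        with pytest.raises(CycleError):
            load_anatomy([("a", "b", "part_of"), ("b", "a", "part_of")])

    def test_duplicate_edge_warns_and_dedupes(self):
        with pytest.warns(UserWarning, match="duplicate"):
            g = load_anatomy([("a", "b", "subclass_of"), ("a", "b", "subclass_of")])
        assert g.subclass.number_of_edges() == 1

    def test_unknown_relation_rejected(self):
        with pytest.raises(KBError):
            load_anatomy([("a", "b", "sibling_of")])

    def test_packaged_hierarchy_has_lymph_node_subtree(self, anatomy):
        subclasses = anatomy.subclass_descendants("RID13296") - {"RID13296"}
        assert len(subclasses) >= 5
        assert len(anatomy.nodes()) >= 35


class TestSubclassPathLength:
    def test_identity_is_zero(self, anatomy):
        assert subclass_path_length(anatomy, "RID86", "RID86") == 0

    def test_disjoint_branches_unreachable(self, anatomy):
        assert subclass_path_length(anatomy, "RID86", "RID13296") == "unreachable"

    def test_unknown_concept_raises(self, anatomy):
        with pytest.raises(KBError):
            subclass_path_length(anatomy, "RID86", "nonexistent")


class TestLoadSpecs:
    def test_cm_bounds_normalised_to_mm(self, anatomy):
        specs = load_specs(
            [
                {"entity_id": "RID13296", "quality": "short axis",
                 "range_type": "upper_bound", "high": 1, "unit": "cm"},
                {"entity_id": "RID33779", "quality": "thickness",
                 "range_type": "interval", "low": 0.1, "high": 0.3, "unit": "cm"},
            ],
            anatomy,
        )
        ln, wall = sorted(specs, key=lambda s: s.entity)
        assert ln.high_mm == 10.0 and ln.low_mm is None
        assert (wall.low_mm, wall.high_mm) == (1.0, 3.0)

    def test_inverted_interval_rejected(self, anatomy):
        with pytest.raises(KBError, match="malformed bounds"):
            load_specs(
                [{"entity_id": "RID205", "quality": "craniocaudal diameter",
                  "range_type": "interval", "low": 13, "high": 8, "unit": "cm"}],
                anatomy,
            )

    def test_unresolvable_entity_rejected(self, anatomy):
        with pytest.raises(KBError, match="unresolvable entity"):
            load_specs(
                [{"entity_id": "no-such-organ", "quality": "length",
                  "range_type": "upper_bound", "high": 1, "unit": "cm"}],
                anatomy,
            )

    def test_load_is_order_independent(self, anatomy):
        records = [
            {"entity_id": "RID13296", "quality": "short axis",
             "range_type": "upper_bound", "high": 1, "unit": "cm"},
            {"entity_id": "RID229", "quality": "width",
             "range_type": "interval", "low": 0.4, "high": 0.7, "unit": "cm"},
            {"entity_id": "RID580", "quality": "diameter",
             "range_type": "lower_bound", "low": 4, "unit": "cm"},
        ]
        assert load_specs(records, anatomy) == load_specs(records[::-1], anatomy)


class TestMostSpecificSpec:
    def test_submental_node_gets_its_own_bound(self, anatomy, specs):
        spec = most_specific_spec(anatomy, specs, "RID7710", SHORT_AXIS)
        assert spec.high_mm == 15.0

    def test_mediastinal_node_inherits_generic_bound(self, anatomy, specs):
        spec = most_specific_spec(anatomy, specs, "mediastinal-lymph-node", SHORT_AXIS)
        assert spec.spec_id == "ln-short-axis" and spec.high_mm == 10.0

    def test_uncovered_entity_resolves_to_none(self, anatomy, specs):
        assert most_specific_spec(anatomy, specs, "rib", ONE_D_EXTENT) is None

    def test_quality_subsumption_matches_like_entities(self, anatomy, specs):
        # a spec stated on "diameter" applies to its subclass qualities
        spec = most_specific_spec(anatomy, specs, "RID580", get_quality("craniocaudal diameter"))
        assert spec is not None and spec.spec_id == "ascending-aorta-root-diameter"

    def test_double_tie_is_a_diagnosed_ambiguity(self, anatomy):
        specs = load_specs(
            [
                {"id": "a", "entity_id": "RID13296", "quality": "short axis",
                 "range_type": "upper_bound", "high": 1, "unit": "cm"},
                {"id": "b", "entity_id": "RID13296", "quality": "short axis",
                 "range_type": "upper_bound", "high": 2, "unit": "cm"},
            ],
            anatomy,
        )
        with pytest.raises(AmbiguousSpecificationError):
            most_specific_spec(anatomy, specs, "RID7710", SHORT_AXIS)


def brute_force_most_specific(graph, specs, entity, quality):
    """Independent oracle: enumerate, filter, remove dominated, minimise path.

    Works from first principles on ancestor sets rather than the
    library's retrieval code path.
    """

    def entity_ancestors(node):
        out, frontier = {node}, [node]
        while frontier:
            n = frontier.pop()
            for parent in graph.subclass.successors(n):
                if parent not in out:
                    out.add(parent)
                    frontier.append(parent)
        return out

    def quality_ancestors(q):
        out = []
        while q is not None:
            out.append(q)
            q = q.parent
        return out

    e_anc = entity_ancestors(entity)
    q_anc = quality_ancestors(quality)
    candidates = [s for s in specs if s.entity in e_anc and s.quality in q_anc]
    if not candidates:
        return None

    def dominated(c):
        for other in candidates:
            if other is c or other.entity == c.entity:
                continue
            if c.entity in entity_ancestors(other.entity) and other.quality in q_anc:
                if c.quality in quality_ancestors(other.quality):
                    return True
        return False

    survivors = [c for c in candidates if not dominated(c)]

    def e_dist(c):
        # BFS over subclass edges
        from collections import deque

        seen, dq = {entity}, deque([(entity, 0)])
        while dq:
            node, d = dq.popleft()
            if node == c.entity:
                return d
            for parent in graph.subclass.successors(node):
                if parent not in seen:
                    seen.add(parent)
                    dq.append((parent, d + 1))
        raise AssertionError("candidate must be reachable")

    def q_dist(c):
        return q_anc.index(c.quality)

    survivors.sort(key=lambda c: (e_dist(c), q_dist(c)))
    best = (e_dist(survivors[0]), q_dist(survivors[0]))
    ties = [s for s in survivors if (e_dist(s), q_dist(s)) == best]
    if len(ties) > 1:
        return "ambiguous"
    return survivors[0]


def test_retrieval_equivalent_to_brute_force_on_full_kb(anatomy, specs):
    """EQ retrieval agrees with the enumerate-filter-minimise oracle everywhere."""
    for entity, quality in itertools.product(anatomy.nodes(), ALL_QUALITIES):
        expected = brute_force_most_specific(anatomy, specs, entity, quality)
        if expected == "ambiguous":
            with pytest.raises(AmbiguousSpecificationError):
                most_specific_spec(anatomy, specs, entity, quality)
        else:
            assert most_specific_spec(anatomy, specs, entity, quality) == expected, (
                entity,
                quality.name,
            )


def test_adding_a_spec_never_removes_coverage(anatomy, specs):
    before = {}
    for entity, quality in itertools.product(anatomy.nodes(), ALL_QUALITIES):
        try:
            before[(entity, quality)] = most_specific_spec(anatomy, specs, entity, quality)
        except AmbiguousSpecificationError:
            before[(entity, quality)] = "ambiguous"
    extra = SizeSpecification(
        entity="liver", quality=get_quality("length"),
        range_type="upper_bound", high_mm=180.0, spec_id="liver-length",
    )
    enlarged = SpecificationSet(list(specs) + [extra])
    for (entity, quality), old in before.items():
        if old in (None, "ambiguous"):
            continue
        try:
            new = most_specific_spec(anatomy, enlarged, entity, quality)
        except AmbiguousSpecificationError:
            pytest.fail(f"coverage lost to ambiguity for {(entity, quality.name)}")
        assert new is not None
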