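"""Domain model: compatibility relation, graph construction, clique
predicates."""

import pytest
from hypothesis import given, settings, strategies as st

from cliquefold.errors import InputError
from cliquefold.model import (
    BasePair,
    InteractionVertex,
    Strand,
    StrandSet,
    StructureVertex,
    are_compatible,
    build_graph,
    clique_weight,
    is_valid_constrained_clique,
    make_clique,
)

from conftest import bp


class TestTypes:
    def test_strand_normalization_and_validation(self):
        assert Strand("A", "ggat").sequence == "GGAU"
        with pytest.raises(InputError):
            Strand("A", "GG-AC")
        with pytest.raises(InputError):
            Strand("A", "")
        with pytest.raises(InputError):
            StrandSet([Strand("A", "GG"), Strand("A", "CC")])

    def test_base_pair_is_order_insensitive(self):
        assert bp("B", 5, "A", 2) == bp("A", 2, "B", 5)
        with pytest.raises(InputError):
            bp("A", 3, "A", 3)

    def test_structure_vertex_invariants(self):
        v = StructureVertex("A", {bp("A", 0, "A", 9), bp("A", 1, "A", 8)})
        assert not v.is_pseudoknotted and not v.is_empty
        # crossing pairs i<k<j<l
        pk = StructureVertex("A", {bp("A", 0, "A", 5), bp("A", 2, "A", 8)})
        assert pk.is_pseudoknotted
        assert StructureVertex("A", frozenset()).is_empty
        with pytest.raises(InputError):  # foreign strand
            StructureVertex("A", {bp("A", 0, "B", 3)})
        with pytest.raises(InputError):  # reused position
            StructureVertex("A", {bp("A", 0, "A", 9), bp("A", 0, "A", 5)})

    def test_interaction_vertex_invariants(self):
        v = InteractionVertex(("B", "A"), {bp("A", 0, "B", 3), bp("A", 1, "B", 2)})
        assert v.strand_pair == ("A", "B")  # canonical order
        with pytest.raises(InputError):  # same strand twice
            InteractionVertex(("A", "A"), {bp("A", 0, "A", 3)})
        with pytest.raises(InputError):  # empty site
            InteractionVertex(("A", "B"), frozenset())
        with pytest.raises(InputError):  # crossing within one site
            InteractionVertex(("A", "B"), {bp("A", 0, "B", 2), bp("A", 1, "B", 3)})
        with pytest.raises(InputError):  # intra-strand pair in interaction
            InteractionVertex(("A", "B"), {bp("A", 0, "A", 3)})


class TestCompatibility:
    def test_same_strand_structures_incompatible(self):
        u = StructureVertex("A", {bp("A", 0, "A", 9)})
        v = StructureVertex("A", {bp("A", 1, "A", 8)})
        assert not are_compatible(u, v)

    def test_empty_structure_compatible_with_interaction(self):
        u = StructureVertex("A", frozenset())
        v = InteractionVertex(("A", "B"), {bp("A", 2, "B", 5)})
        assert are_compatible(u, v)

    def test_shared_nucleotide_incompatible(self):
        u = StructureVertex("A", {bp("A", 2, "A", 9)})
        v = InteractionVertex(("A", "B"), {bp("A", 2, "B", 5)})
        assert not are_compatible(u, v)

    def test_crossing_but_disjoint_interactions_compatible(self):
        u = InteractionVertex(("A", "B"), {bp("A", 1, "B", 8)})
        v = InteractionVertex(("A", "C"), {bp("A", 5, "C", 3)})
        assert are_compatible(u, v)

    @staticmethod
    def _random_vertex(draw_kind, positions):
        if draw_kind == "struct":
            sid = positions[0][0][0]
            pairs = {
                BasePair((sid, a[1]), (sid, b[1])) for a, b in positions if a[1] != b[1]
            }
            return StructureVertex(sid, frozenset(pairs))
        return None

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_compatibility_is_symmetric(self, data):
        vertices = _random_vertices(data)
        u = data.draw(st.sampled_from(vertices))
        v = data.draw(st.sampled_from(vertices))
        if u is not v:
            assert are_compatible(u, v) == are_compatible(v, u)

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_compatible_vertices_share_no_paired_position(self, data):
        vertices = _random_vertices(data)
        u = data.draw(st.sampled_from(vertices))
        v = data.draw(st.sampled_from(vertices))
        if u is not v and are_compatible(u, v):
            assert not (u.paired_positions & v.paired_positions)


def _random_vertices(data):
    """A small pool of random structure/interaction vertices on strands A/B."""
    from hypothesis import strategies as st

    out = []
    for sid in ("A", "B"):
        for _ in range(2):
            n = data.draw(st.integers(0, 3))
            used = set()
            pairs = []
            for _ in range(n):
                i = data.draw(st.integers(0, 9))
                j = data.draw(st.integers(0, 9))
                if i != j and i not in used and j not in used:
                    used.update((i, j))
                    pairs.append(BasePair((sid, i), (sid, j)))
            out.append(StructureVertex(sid, frozenset(pairs)))
    for _ in range(2):
        n = data.draw(st.integers(1, 3))
        used_a, used_b = set(), set()
        pairs = []
        for _ in range(n):
            i = data.draw(st.integers(0, 9))
            j = data.draw(st.integers(0, 9))
            if i not in used_a and j not in used_b:
                used_a.add(i)
                used_b.add(j)
                pairs.append(BasePair(("A", i), ("B", j)))
        pairs = _drop_crossings(pairs)
        if pairs:
            out.append(InteractionVertex(("A", "B"), frozenset(pairs)))
    return out


def _drop_crossings(pairs):
    kept = []
    for p in sorted(pairs, key=lambda p: p.a[1]):
        q = p.b[1]
        if all(q < k.b[1] for k in kept):
            kept.append(p)
    return kept


class TestBuildGraph:
    def test_counts_adjacency_and_auto_empty(self, two_strands):
        sa = StructureVertex("A", {bp("A", 0, "A", 9)})
        sb = StructureVertex("B", {bp("B", 0, "B", 5)})
        iv = InteractionVertex(("A", "B"), {bp("A", 4, "B", 8)})
        g = build_graph(two_strands, [sa, sb], [iv])
        # 2 given structures + 2 auto-empty + 1 interaction
        assert len(g) == 5
        for sid in ("A", "B"):
            empty = g.vertex(g.empty_structure_id(sid))
            assert empty.is_empty
        # disjoint pair sets: every cross-class pair adjacent
        for i in range(5):
            for j in range(i + 1, 5):
                vi, vj = g.vertex(i), g.vertex(j)
                same_strand_structs = (
                    isinstance(vi, StructureVertex)
                    and isinstance(vj, StructureVertex)
                    and vi.strand_id == vj.strand_id
                )
                assert g.adjacent(i, j) == (not same_strand_structs)

    def test_duplicates_collapse(self, two_strands):
        sa1 = StructureVertex("A", {bp("A", 0, "A", 9)})
        sa2 = StructureVertex("A", {bp("A", 0, "A", 9)})
        g = build_graph(two_strands, [sa1, sa2], [])
        n_structs_a = len(g.structure_ids_by_strand["A"])
        assert n_structs_a == 2  # the candidate + the auto-empty

    def test_conflicting_candidates_lose_their_edge(self, two_strands):
        sa = StructureVertex("A", {bp("A", 2, "A", 9)})
        iv = InteractionVertex(("A", "B"), {bp("A", 2, "B", 5)})
        g = build_graph(two_strands, [sa], [iv])
        ids = {(type(v).__name__, getattr(v, "strand_id", None), v.is_empty): v.vertex_id for v in g.vertices}
        a_struct = next(
            v.vertex_id
            for v in g.vertices
            if isinstance(v, StructureVertex) and v.strand_id == "A" and not v.is_empty
        )
        inter = g.interaction_ids[0]
        assert not g.adjacent(a_struct, inter)

    def test_adjacency_matches_pairwise_recomputation(self):
        from cliquefold.synthetic import InstanceSpec, generate_instance

        for seed in range(5):
            inst = generate_instance(InstanceSpec(seed=seed, n_strands=2))
            g = inst.graph()
            for i in range(len(g)):
                for j in range(i + 1, len(g)):
                    assert g.adjacent(i, j) == are_compatible(
                        g.vertex(i), g.vertex(j)
                    )


class TestCliquePredicates:
    def _graph(self, two_strands):
        sa = StructureVertex("A", {bp("A", 0, "A", 9)}, energy=-3.2, weight=3.2)
        sb = StructureVertex("B", {bp("B", 0, "B", 5)}, energy=-1.1, weight=1.1)
        iv = InteractionVertex(("A", "B"), {bp("A", 4, "B", 8)}, energy=-2.0, weight=2.0)
        return build_graph(two_strands, [sa, sb], [iv])

    def test_all_empty_clique_is_weak(self, two_strands):
        g = self._graph(two_strands)
        empties = [g.empty_structure_id(sid) for sid in ("A", "B")]
        assert not is_valid_constrained_clique(empties, g)

    def test_full_valid_clique(self, two_strands):
        g = self._graph(two_strands)
        members = [
            v.vertex_id
            for v in g.vertices
            if not (isinstance(v, StructureVertex) and v.is_empty)
        ]
        assert is_valid_constrained_clique(members, g)

    def test_missing_structure_for_one_strand(self, two_strands):
        g = self._graph(two_strands)
        a_struct = g.structure_ids_by_strand["A"][0]
        inter = g.interaction_ids[0]
        assert not is_valid_constrained_clique([a_struct, inter], g)

    def test_clique_weight_examples(self, two_strands):
        g = self._graph(two_strands)
        assert clique_weight([], g) == 0
        members = [
            v.vertex_id
            for v in g.vertices
            if not (isinstance(v, StructureVertex) and v.is_empty)
        ]
        assert clique_weight(members, g) == pytest.approx(3.2 + 1.1 + 2.0)

    def test_clique_weight_matches_independent_resummation(self):
        from cliquefold.synthetic import InstanceSpec, brute_force_optimum, generate_instance

        inst = generate_instance(InstanceSpec(seed=11, n_strands=2))
        g = inst.graph()
        for clique in brute_force_optimum(g, top_k=5):
            resum = 0.0
            for m in clique.members:
                resum += g.vertex(m).weight
            assert clique.weight == pytest.approx(resum, abs=1e-12)
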