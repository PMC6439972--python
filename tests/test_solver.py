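"""The breakout local search: move contracts, set maintenance, archive
validity, determinism, and small-scale optimality against the exhaustive
oracle."""

import random

import pytest

from cliquefold.errors import SolverError
from cliquefold.model import (
    InteractionVertex,
    StructureVertex,
    build_graph,
    is_valid_constrained_clique,
)
from cliquefold.solver import BreakoutCliqueSearch, SolverConfig, run
from cliquefold.synthetic import InstanceSpec, brute_force_optimum, generate_instance

from conftest import bp


def small_graph(seed=0, **kw):
    spec = InstanceSpec(seed=seed, **kw)
    return generate_instance(spec).graph()


class TestConfig:
    def test_perturbation_strength_is_ceil_with_min_one(self):
        cfg = SolverConfig()
        assert cfg.perturbation_strength(5) == 1
        assert cfg.perturbation_strength(23) == 3
        assert cfg.perturbation_strength(30) == 3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(max_iterations=0)
        with pytest.raises(ValueError):
            SolverConfig(p0=1.5)


class TestInitialClique:
    @pytest.mark.parametrize("seed", range(20))
    def test_initial_clique_is_valid(self, seed):
        g = small_graph(seed=seed)
        solver = BreakoutCliqueSearch(g, SolverConfig(seed=seed))
        state = solver.initial_clique()
        members = state.members()
        assert is_valid_constrained_clique(members, g)
        # exactly one interaction seed plus one structure per strand
        n_inter = sum(1 for m in members if g.is_interaction(m))
        assert n_inter == 1
        assert len(members) == 1 + len(g.strands.ids)

    def test_refuses_graph_without_interactions(self, two_strands):
        sa = StructureVertex("A", {bp("A", 0, "A", 9)})
        g = build_graph(two_strands, [sa], [])
        with pytest.raises(SolverError):
            BreakoutCliqueSearch(g)

    def test_empty_structure_fallback(self, two_strands):
        # the only non-empty structure conflicts with the only interaction
        sa = StructureVertex("A", {bp("A", 4, "A", 9)}, weight=5.0)
        iv = InteractionVertex(("A", "B"), {bp("A", 4, "B", 8)}, weight=1.0)
        g = build_graph(two_strands, [sa], [iv])
        solver = BreakoutCliqueSearch(g, SolverConfig(seed=1))
        state = solver.initial_clique()
        assert g.empty_structure_id("A") in state.members()


class TestMoveSetMaintenance:
    @pytest.mark.parametrize("seed", range(5))
    def test_maintained_sets_equal_definitions_along_random_traces(self, seed):
        g = small_graph(seed=seed)
        solver = BreakoutCliqueSearch(g, SolverConfig(seed=seed))
        state = solver.initial_clique()
        rng = random.Random(seed)
        for step in range(200):
            pa, om, oc = solver.move_sets(state)
            ref_pa, ref_om, ref_oc = solver.reference_move_sets(state.members())
            assert pa == ref_pa
            assert om == ref_om
            assert oc == ref_oc
            moves = solver._candidate_moves(state, with_removes=True, respect_tabu=False)
            if not moves or rng.random() < 0.05:
                solver.move_restart(state)
                continue
            _, move = rng.choice(moves)
            solver.apply_move(state, move)

    def test_added_vertex_leaves_pa_and_oc(self, two_strands):
        g = small_graph(seed=9)
        solver = BreakoutCliqueSearch(g, SolverConfig(seed=0))
        state = solver.initial_clique()
        pa, _, _ = solver.move_sets(state)
        if pa:
            v = min(pa)
            solver.apply_move(state, ("add", v))
            pa2, _, oc2 = solver.move_sets(state)
            assert v not in pa2 and v not in oc2


class TestMoves:
    def _solver_state(self, seed=0):
        g = small_graph(seed=seed)
        solver = BreakoutCliqueSearch(g, SolverConfig(seed=seed))
        return solver, solver.initial_clique()

    def test_add_updates_weight_exactly(self):
        solver, state = self._solver_state(seed=4)
        pa, _, _ = solver.move_sets(state)
        if not pa:
            pytest.skip("no addable vertex in this instance")
        v = min(pa)
        before = state.weight
        solver.apply_move(state, ("add", v))
        assert state.weight == pytest.approx(before + solver.w[v])
        assert is_valid_constrained_clique(state.members(), solver.g)

    def test_remove_makes_vertex_tabu(self):
        solver, state = self._solver_state(seed=4)
        # ensure removal is non-weak: add another interaction first if possible
        pa, _, _ = solver.move_sets(state)
        for v in sorted(pa):
            solver.apply_move(state, ("add", v))
        moves = solver._candidate_moves(state, with_removes=True, respect_tabu=False)
        removes = [m for _, m in moves if m[0] == "remove"]
        if not removes:
            pytest.skip("no legal remove on this instance")
        u = removes[0][1]
        solver.apply_move(state, ("remove", u))
        assert state.is_tabu(u)
        tabu_moves = solver._candidate_moves(state, with_removes=True, respect_tabu=True)
        assert all(not (m[0] in ("add", "replace") and m[1] == u) for _, m in tabu_moves)

    def test_weak_producing_moves_never_offered(self, two_strands):
        # single interaction + all-empty structures: removing it would be weak
        iv = InteractionVertex(("A", "B"), {bp("A", 0, "B", 5)})
        g = build_graph(two_strands, [], [iv])
        from cliquefold.energy import score_graph

        solver = BreakoutCliqueSearch(score_graph(g), SolverConfig(seed=0))
        state = solver.initial_clique()
        moves = solver._candidate_moves(state, with_removes=True, respect_tabu=False)
        assert all(m[0] != "remove" for _, m in moves)

    @pytest.mark.parametrize("seed", range(10))
    def test_restart_always_yields_valid_clique(self, seed):
        solver, state = self._solver_state(seed=seed)
        for _ in range(20):
            solver.move_restart(state)
            assert is_valid_constrained_clique(state.members(), solver.g)


class TestDescentAndPerturbation:
    @pytest.mark.parametrize("seed", range(10))
    def test_descent_is_monotone_and_terminates(self, seed):
        solver, state = (lambda s: (s, s.initial_clique()))(
            BreakoutCliqueSearch(small_graph(seed=seed), SolverConfig(seed=seed))
        )
        before = state.weight
        solver.local_search_descent(state)
        assert state.weight >= before - 1e-12
        # local optimum: no strictly improving add/replace remains
        moves = solver._candidate_moves(state, with_removes=False, respect_tabu=False)
        assert all(delta <= 1e-9 for delta, _ in moves)

    @pytest.mark.parametrize("seed", range(10))
    def test_perturbation_preserves_validity(self, seed):
        solver = BreakoutCliqueSearch(small_graph(seed=seed), SolverConfig(seed=seed))
        state = solver.initial_clique()
        for _ in range(30):
            solver.local_search_descent(state)
            solver.perturb(state)
            assert is_valid_constrained_clique(state.members(), solver.g)

    def test_omega_above_threshold_forces_restart(self):
        solver = BreakoutCliqueSearch(small_graph(seed=1), SolverConfig(seed=1))
        state = solver.initial_clique()
        state.omega = solver.config.t_threshold + 1
        solver.perturb(state)
        assert state.omega == 0  # strong perturbation resets the counter


class TestRun:
    def test_every_archived_clique_is_valid_and_a_networkx_clique(self):
        import networkx as nx

        g = small_graph(seed=13)
        archive = run(g, SolverConfig(seed=13, max_iterations=100, restarts=2))
        nxg = g.to_networkx()
        for clique in archive:
            assert is_valid_constrained_clique(clique.members, g)
            sub = nxg.subgraph(clique.members)
            n = len(clique.members)
            assert sub.number_of_edges() == n * (n - 1) // 2

    def test_same_seed_reproduces_archive(self):
        g1 = small_graph(seed=21)
        g2 = small_graph(seed=21)
        cfg = SolverConfig(seed=5, max_iterations=100, restarts=2)
        a1 = run(g1, cfg)
        a2 = run(g2, SolverConfig(seed=5, max_iterations=100, restarts=2))
        assert [c.members for c in a1] == [c.members for c in a2]

    def test_trivial_graph_archives_exactly_its_single_complex(self, two_strands):
        iv = InteractionVertex(("A", "B"), {bp("A", 0, "B", 5)})
        from cliquefold.energy import score_graph

        g = score_graph(build_graph(two_strands, [], [iv]))
        archive = run(g, SolverConfig(seed=0, max_iterations=20, restarts=1))
        assert len(archive) == 1
        members = archive[0].members
        assert g.interaction_ids[0] in members
        assert len(members) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_best_archived_weight_matches_exhaustive_optimum(self, seed):
        g = small_graph(seed=100 + seed)
        oracle = brute_force_optimum(g, top_k=1)
        archive = run(g, SolverConfig(seed=seed))
        best = max(c.weight for c in archive)
        assert best == pytest.approx(oracle[0].weight, abs=1e-9)

    def test_oracle_never_beaten(self):
        g = small_graph(seed=77)
        oracle_best = brute_force_optimum(g, top_k=1)[0].weight
        archive = run(g, SolverConfig(seed=3, max_iterations=200, restarts=3))
        assert max(c.weight for c in archive) <= oracle_best + 1e-9
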