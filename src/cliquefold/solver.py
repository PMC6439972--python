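"""Breakout local search for the constrained maximum-weight clique problem.

The search space is the set of *valid* cliques of the compatibility graph:
pairwise compatible vertex sets with exactly one secondary-structure vertex
per strand and at least one base pair overall (non-weak).  The solver
maximizes total vertex weight (= minimizes total free energy over
stabilizing candidates) and, because sub-optimal complexes matter, archives
every distinct valid clique it ever visits.

The heuristic alternates two phases until a fixed number of iterations is
reached:

* *descent*: repeatedly apply the best strictly-improving add or replace
  move until a local optimum;
* *perturbation*: escape the optimum with a directed sequence of add /
  replace / remove moves under tabu control, escalating to a clique restart
  after too many non-improving descents.

Move sets follow the constrained formulation: only interaction vertices are
ever added or removed on their own (PA and OC contain interactions only);
replacements swap same-kind vertices (interaction for interaction, or
structure for structure on the same strand), which preserves the
one-structure-per-strand constraint by construction.  Moves that would
produce a weak clique are never offered.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .errors import SolverError
from .model import (
    Clique,
    CompatibilityGraph,
    InteractionVertex,
    StructureVertex,
    are_compatible,
    make_clique,
)

_EPS = 1e-9


@dataclass
class SolverConfig:
    """Search parameters.

    The perturbation strength is ``L = ceil(l0_fraction * |V|)`` (minimum 1);
    with ``l0_fraction == lmax_fraction`` the strength is constant, matching
    the published calibration.  ``t_threshold`` is the number of consecutive
    non-improving descents tolerated before a strong perturbation (clique
    restart).  ``alpha_s`` and ``alpha_r`` gate degrading swap and remove
    moves during directed perturbation; ``phi`` is the tabu tenure in moves;
    ``p0`` is the probability of a directed (rather than uniformly random)
    perturbation.
    """

    max_iterations: int = 500
    restarts: int = 5
    seed: int = 0
    max_solutions: int = 10
    l0_fraction: float = 0.1
    lmax_fraction: float = 0.1
    t_threshold: int = 10
    alpha_s: float = 0.5
    alpha_r: float = 0.5
    phi: int = 7
    p0: float = 1.0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 <= self.p0 <= 1:
            raise ValueError("p0 must be in [0, 1]")
        if self.l0_fraction > self.lmax_fraction:
            raise ValueError("l0_fraction must not exceed lmax_fraction")

    def perturbation_strength(self, n_vertices: int) -> int:
        return max(1, math.ceil(self.l0_fraction * n_vertices))


# move encodings: ("add", v), ("replace", v, u), ("remove", u)
Move = Tuple


class SolverState:
    """Mutable search state over a fixed graph (bitset representation)."""

    def __init__(self, solver: "BreakoutCliqueSearch"):
        self.solver = solver
        self.c_mask: int = 0
        self.weight: float = 0.0
        self.pairs: int = 0
        self.tabu: Dict[int, int] = {}
        self.move_counter: int = 0
        self.omega: int = 0
        self.best_weight: float = -math.inf
        self.best_mask: int = 0

    # -- queries -----------------------------------------------------------

    def members(self) -> FrozenSet[int]:
        return frozenset(_bits(self.c_mask))

    def is_tabu(self, v: int) -> bool:
        return self.tabu.get(v, -1) > self.move_counter

    # -- elementary updates ------------------------------------------------

    def _add(self, v: int) -> None:
        s = self.solver
        assert not self.c_mask >> v & 1
        self.c_mask |= 1 << v
        self.weight += s.w[v]
        self.pairs += s.npairs[v]

    def _remove(self, u: int) -> None:
        s = self.solver
        assert self.c_mask >> u & 1
        self.c_mask &= ~(1 << u)
        self.weight -= s.w[u]
        self.pairs -= s.npairs[u]
        self.tabu[u] = self.move_counter + s.config.phi

    def _settle(self) -> None:
        """Archive the current clique and update the incumbent."""
        self.move_counter += 1
        s = self.solver
        if self.c_mask not in s.archive:
            s.archive[self.c_mask] = self.weight
        if self.weight > self.best_weight + _EPS:
            self.best_weight = self.weight
            self.best_mask = self.c_mask


def _bits(mask: int):
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


class BreakoutCliqueSearch:
    """One search over a scored compatibility graph.

    Use :func:`run` for the plain functional interface; the class exposes
    the individual phases (initial clique, descent, perturbation, restart)
    for inspection and testing.
    """

    def __init__(self, g: CompatibilityGraph, config: Optional[SolverConfig] = None):
        self.g = g
        self.config = config or SolverConfig()
        n = len(g)
        self.n = n
        self.full_mask = (1 << n) - 1
        self.adj = list(g.adjacency)
        self.w = [v.weight for v in g.vertices]
        self.npairs = [len(v.pairs) for v in g.vertices]
        self.inter_mask = 0
        for vid in g.interaction_ids:
            self.inter_mask |= 1 << vid
        if not g.interaction_ids:
            raise SolverError(
                "the graph has no interaction candidates: a multi-strand "
                "complex needs at least one interaction site to be non-weak; "
                "supply interaction candidates"
            )
        self.struct_masks = {
            sid: sum(1 << vid for vid in vids)
            for sid, vids in g.structure_ids_by_strand.items()
        }
        self.archive: Dict[int, float] = {}
        self.rng = random.Random(self.config.seed)

    # -- move enumeration --------------------------------------------------

    def move_sets(self, state: SolverState) -> Tuple[Set[int], Set[Tuple[int, int]], Set[int]]:
        """Current PA (addable interactions), OM (same-kind replacement
        pairs) and OC (interactions outside the clique), from the bitset
        representation."""
        pa: Set[int] = set()
        om: Set[Tuple[int, int]] = set()
        c = state.c_mask
        inter = self.inter_mask
        for v in _bits(self.full_mask & ~c):
            missing = c & ~self.adj[v]
            if missing == 0:
                if inter >> v & 1:
                    pa.add(v)
            elif missing & (missing - 1) == 0:
                u = missing.bit_length() - 1
                if bool(inter >> v & 1) == bool(inter >> u & 1):
                    om.add((v, u))
        oc = set(_bits(inter & ~c))
        return pa, om, oc

    def reference_move_sets(
        self, members: FrozenSet[int]
    ) -> Tuple[Set[int], Set[Tuple[int, int]], Set[int]]:
        """From-scratch PA/OM/OC computed straight from the definitions via
        pairwise compatibility tests (independent of the bitset route)."""
        g = self.g
        verts = g.vertices
        pa: Set[int] = set()
        om: Set[Tuple[int, int]] = set()
        for v in range(len(g)):
            if v in members:
                continue
            blockers = [
                u for u in members if not are_compatible(verts[v], verts[u])
            ]
            if not blockers and isinstance(verts[v], InteractionVertex):
                pa.add(v)
            if len(blockers) == 1:
                u = blockers[0]
                if isinstance(verts[v], InteractionVertex) == isinstance(
                    verts[u], InteractionVertex
                ):
                    om.add((v, u))
        oc = {
            v
            for v in range(len(g))
            if isinstance(verts[v], InteractionVertex) and v not in members
        }
        return pa, om, oc

    def _candidate_moves(
        self, state: SolverState, with_removes: bool, respect_tabu: bool
    ) -> List[Tuple[float, Move]]:
        """All legal (non-weak-producing) moves with their weight deltas."""
        moves: List[Tuple[float, Move]] = []
        c = state.c_mask
        inter = self.inter_mask
        w = self.w
        npairs = self.npairs
        for v in _bits(self.full_mask & ~c):
            if respect_tabu and state.is_tabu(v):
                continue
            missing = c & ~self.adj[v]
            if missing == 0:
                if inter >> v & 1:
                    moves.append((w[v], ("add", v)))
            elif missing & (missing - 1) == 0:
                u = missing.bit_length() - 1
                if bool(inter >> v & 1) != bool(inter >> u & 1):
                    continue
                if state.pairs - npairs[u] + npairs[v] <= 0:
                    continue  # would be weak
                moves.append((w[v] - w[u], ("replace", v, u)))
        if with_removes:
            for u in _bits(c & inter):
                if state.pairs - npairs[u] <= 0:
                    continue
                moves.append((-w[u], ("remove", u)))
        return moves

    # -- move application --------------------------------------------------

    def apply_move(self, state: SolverState, move: Move) -> None:
        kind = move[0]
        if kind == "add":
            state._add(move[1])
        elif kind == "replace":
            state._remove(move[2])
            state._add(move[1])
        elif kind == "remove":
            state._remove(move[1])
        else:  # pragma: no cover
            raise AssertionError(f"unknown move {move!r}")
        state._settle()

    # -- phases ------------------------------------------------------------

    def initial_clique(self, state: Optional[SolverState] = None) -> SolverState:
        """Random interaction vertex plus one compatible structure vertex
        per strand (the empty structure guarantees satisfiability)."""
        state = state or SolverState(self)
        state.c_mask = 0
        state.weight = 0.0
        state.pairs = 0
        seed_v = self.rng.choice(self.g.interaction_ids)
        state._add(seed_v)
        for sid in self.g.strands.ids:
            compatible = [
                v
                for v in _bits(self.struct_masks[sid])
                if self.adj[v] & state.c_mask == state.c_mask
            ]
            state._add(self.rng.choice(compatible))
        state._settle()
        return state

    def local_search_descent(self, state: SolverState) -> SolverState:
        """Apply the best strictly-improving add/replace move until none
        exists (ties broken uniformly at random)."""
        while True:
            moves = self._candidate_moves(state, with_removes=False, respect_tabu=False)
            best_delta = _EPS
            best: List[Move] = []
            for delta, move in moves:
                if delta > best_delta + _EPS:
                    best_delta = delta
                    best = [move]
                elif best and abs(delta - best_delta) <= _EPS:
                    best.append(move)
            if not best:
                break
            self.apply_move(state, best[0] if len(best) == 1 else self.rng.choice(best))
        return state

    def perturb(self, state: SolverState) -> SolverState:
        """Escape a local optimum.

        After more than ``t_threshold`` consecutive non-improving descents a
        strong perturbation (clique restart) is applied; otherwise a
        directed (with probability ``p0``) or uniformly random sequence of
        ``L`` weak moves (add/replace/remove under tabu control) is applied.
        Directed moves prefer the smallest weight degradation and accept a
        degrading replace only if the new/old clique weight ratio stays
        above ``alpha_s``, a remove only if the removed weight is at most
        ``(1 - alpha_r)`` of the clique weight.
        """
        cfg = self.config
        if state.omega > cfg.t_threshold:
            self.move_restart(state)
            state.omega = 0
            return state
        directed = self.rng.random() < cfg.p0
        strength = cfg.perturbation_strength(self.n)
        for _ in range(strength):
            moves = self._candidate_moves(state, with_removes=True, respect_tabu=True)
            acceptable: List[Tuple[float, Move]] = []
            for delta, move in moves:
                if move[0] == "replace" and delta < -_EPS and state.weight > _EPS:
                    if (state.weight + delta) / state.weight < cfg.alpha_s:
                        continue
                if move[0] == "remove" and state.weight > _EPS:
                    if self.w[move[1]] > (1 - cfg.alpha_r) * state.weight + _EPS:
                        continue
                acceptable.append((delta, move))
            if not acceptable:
                self.move_restart(state)  # no legal weak move: forced restart
                return state
            if directed:
                best_delta = max(d for d, _ in acceptable)
                pool = [m for d, m in acceptable if abs(d - best_delta) <= _EPS]
            else:
                pool = [m for _, m in acceptable]
            self.apply_move(state, self.rng.choice(pool))
        return state

    def move_restart(self, state: SolverState) -> SolverState:
        """Strong perturbation: force a random outside interaction into the
        clique, repair the structure vertices strand by strand, then drop
        interactions that no longer fit.  No-op when every interaction is
        already in the clique."""
        oc = list(_bits(self.inter_mask & ~state.c_mask))
        if not oc:
            return state
        seed_v = self.rng.choice(oc)
        old_members = list(_bits(state.c_mask))
        kept = 1 << seed_v
        # repair structures: keep the current one when still compatible,
        # otherwise pick a random compatible replacement (empty as fallback)
        for sid in self.g.strands.ids:
            current = [
                u for u in old_members if self.struct_masks[sid] >> u & 1
            ]
            cur = current[0] if current else None
            if cur is not None and self.adj[cur] >> seed_v & 1:
                kept |= 1 << cur
            else:
                options = [
                    v
                    for v in _bits(self.struct_masks[sid])
                    if self.adj[v] & kept == kept
                ]
                kept |= 1 << self.rng.choice(options)
        # drop interactions that conflict with the rebuilt core
        for u in old_members:
            if not (self.inter_mask >> u & 1) or u == seed_v:
                continue
            if self.adj[u] & kept == kept:
                kept |= 1 << u
            else:
                state.tabu[u] = state.move_counter + self.config.phi
        state.c_mask = kept
        state.weight = sum(self.w[v] for v in _bits(kept))
        state.pairs = sum(self.npairs[v] for v in _bits(kept))
        state._settle()
        return state

    # -- driver ------------------------------------------------------------

    def run_restart(self) -> SolverState:
        """One independent restart: initial clique, then alternate descent
        and perturbation for ``max_iterations`` iterations."""
        state = self.initial_clique()
        for _ in range(self.config.max_iterations):
            before_best = state.best_weight
            self.local_search_descent(state)
            if state.best_weight > before_best + _EPS:
                state.omega = 0
            else:
                state.omega += 1
            self.perturb(state)
        return state

    def run(self) -> List[Clique]:
        """All restarts; returns every distinct valid clique encountered,
        in deterministic (insertion) order."""
        for _ in range(self.config.restarts):
            self.run_restart()
        return [
            make_clique(frozenset(_bits(mask)), self.g) for mask in self.archive
        ]


def run(g: CompatibilityGraph, config: Optional[SolverConfig] = None) -> List[Clique]:
    """Solve the constrained maximum-weight clique problem on ``g`` and
    return the archive of all distinct valid cliques encountered."""
    return BreakoutCliqueSearch(g, config).run()
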