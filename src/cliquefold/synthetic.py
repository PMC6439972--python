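"""Random, structurally valid problem instances and an exhaustive oracle.

The generator stands in for external secondary-structure and interaction
prediction tools: it emits random strands together with candidate
structures (optionally pseudoknotted) and candidate interaction sites whose
base pairs are canonical by construction (sequence letters are filled in to
respect complementarity), so the energy models accept every candidate.

An *overlap* knob controls how often candidates deliberately reuse
nucleotide positions and therefore conflict, which shapes the compatibility
graph.  With ``plant_optimum`` the instance contains one mutually
compatible selection (one strong structure per strand plus strong duplexes)
whose dominance over all decoys is verified with the exhaustive oracle, so
the constrained optimum is known.

``brute_force_optimum`` enumerates every (one structure per strand)
selection times every compatible interaction subset — exact by
construction, guarded against combinatorial blowup — and is the reference
the heuristic solver is tested against.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .energy import score_graph
from .errors import GuardExceeded, InputError
from .model import (
    BasePair,
    Clique,
    CompatibilityGraph,
    InteractionVertex,
    Strand,
    StrandSet,
    StructureVertex,
    build_graph,
    make_clique,
)

COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}
PAIR_CHOICES = ["GC", "CG", "AU", "UA", "GU", "UG"]
PAIR_WEIGHTS = [0.30, 0.30, 0.15, 0.15, 0.05, 0.05]


@dataclass(frozen=True)
class InstanceSpec:
    """Knobs of the instance generator; a fixed seed gives an identical
    instance."""

    n_strands: int = 3
    length_range: Tuple[int, int] = (20, 40)
    structures_per_strand: int = 4
    interactions_per_pair: int = 2
    helix_len_range: Tuple[int, int] = (2, 5)
    pseudoknot_prob: float = 0.25
    overlap_prob: float = 0.3
    duplicate_strands: bool = False
    plant_optimum: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strands < 1:
            raise InputError("n_strands must be >= 1")
        if self.structures_per_strand < 0 or self.interactions_per_pair < 0:
            raise InputError("candidate counts must be >= 0")
        if not 0 <= self.overlap_prob <= 1 or not 0 <= self.pseudoknot_prob <= 1:
            raise InputError("probabilities must lie in [0, 1]")
        if self.duplicate_strands and self.n_strands < 2:
            raise InputError("duplicate_strands needs at least two strands")
        if self.duplicate_strands and self.plant_optimum:
            raise InputError(
                "duplicate_strands and plant_optimum are mutually exclusive: "
                "a twin strand makes the planted optimum non-unique"
            )


@dataclass(frozen=True)
class PlantedSolution:
    """The known-optimal selection: pair sets keyed by scope."""

    structure_pairs: Dict[str, FrozenSet[BasePair]]
    interaction_pairs: Tuple[FrozenSet[BasePair], ...]


@dataclass
class Instance:
    strands: StrandSet
    structures: List[StructureVertex]
    interactions: List[InteractionVertex]
    planted: Optional[PlantedSolution] = None

    def graph(self) -> CompatibilityGraph:
        """Scored compatibility graph of the instance."""
        g = build_graph(self.strands, self.structures, self.interactions)
        return score_graph(g)


class _SeqBuilder:
    """Mutable strand sequences with position locking for complementarity
    fill-in."""

    def __init__(self, ids: Sequence[str], lengths: Sequence[int], rng: random.Random):
        self.rng = rng
        self.letters: Dict[str, List[str]] = {
            sid: [rng.choice("ACGU") for _ in range(n)] for sid, n in zip(ids, lengths)
        }
        self.locked: Dict[str, Set[int]] = {sid: set() for sid in ids}
        self.used: Dict[str, Set[int]] = {sid: set() for sid in ids}

    def length(self, sid: str) -> int:
        return len(self.letters[sid])

    def try_pair(self, a: Tuple[str, int], b: Tuple[str, int], gc_only: bool = False) -> bool:
        """Make positions a and b canonically pairable, locking them;
        returns False if both are locked to incompatible letters."""
        (sa, pa), (sb, pb) = a, b
        la, lb = self.letters[sa][pa], self.letters[sb][pb]
        a_locked = pa in self.locked[sa]
        b_locked = pb in self.locked[sb]
        if a_locked and b_locked:
            ok = la + lb in ("GC", "CG", "AU", "UA", "GU", "UG")
            if gc_only:
                ok = la + lb in ("GC", "CG")
            return ok
        if a_locked:
            self.letters[sb][pb] = COMPLEMENT[la]
        elif b_locked:
            self.letters[sa][pa] = COMPLEMENT[lb]
        else:
            if gc_only:
                x = self.rng.choice(["GC", "CG"])
            else:
                x = self.rng.choices(PAIR_CHOICES, weights=PAIR_WEIGHTS, k=1)[0]
            self.letters[sa][pa] = x[0]
            self.letters[sb][pb] = x[1]
        self.locked[sa].add(pa)
        self.locked[sb].add(pb)
        return True

    def mark_used(self, pairs: Sequence[BasePair]) -> None:
        for p in pairs:
            for sid, pos in p.endpoints:
                self.used[sid].add(pos)

    def strand_set(self, ids: Sequence[str]) -> StrandSet:
        return StrandSet(Strand(sid, "".join(self.letters[sid])) for sid in ids)


def _intra_helix(
    b: _SeqBuilder,
    sid: str,
    rng: random.Random,
    k: int,
    gc_only: bool = False,
    want_overlap: Optional[bool] = None,
    must_cover: Optional[int] = None,
) -> Optional[List[BasePair]]:
    """One helix of k pairs inside a strand (loop of >= 3 between arms)."""
    n = b.length(sid)
    span_min = 2 * k + 3
    if n < span_min:
        return None
    for _ in range(40):
        i = rng.randrange(0, n - span_min + 1)
        j = rng.randrange(i + span_min - 1, n)
        positions = {i + t for t in range(k)} | {j - t for t in range(k)}
        if must_cover is not None and must_cover not in positions:
            continue
        if want_overlap is True and not positions & b.used[sid]:
            continue
        if want_overlap is False and positions & b.used[sid]:
            continue
        pairs = []
        ok = True
        for t in range(k):
            if not b.try_pair((sid, i + t), (sid, j - t), gc_only=gc_only):
                ok = False
                break
            pairs.append(BasePair((sid, i + t), (sid, j - t)))
        if ok:
            return pairs
    return None


def _inter_helix(
    b: _SeqBuilder,
    s1: str,
    s2: str,
    rng: random.Random,
    k: int,
    gc_only: bool = False,
    want_overlap: Optional[bool] = None,
    must_cover: Optional[Tuple[str, int]] = None,
) -> Optional[List[BasePair]]:
    """One duplex of k pairs between two strands (antiparallel)."""
    n1, n2 = b.length(s1), b.length(s2)
    if n1 < k or n2 < k:
        return None
    for _ in range(40):
        p = rng.randrange(0, n1 - k + 1)
        q = rng.randrange(k - 1, n2)
        positions = {(s1, p + t) for t in range(k)} | {(s2, q - t) for t in range(k)}
        if must_cover is not None and must_cover not in positions:
            continue
        touched = {
            (sid, pos) for sid, pos in positions if pos in b.used[sid]
        }
        if want_overlap is True and not touched:
            continue
        if want_overlap is False and touched:
            continue
        pairs = []
        ok = True
        for t in range(k):
            if not b.try_pair((s1, p + t), (s2, q - t), gc_only=gc_only):
                ok = False
                break
            pairs.append(BasePair((s1, p + t), (s2, q - t)))
        if ok:
            return pairs
    return None


def _generate_once(spec: InstanceSpec, seed: int) -> Optional[Instance]:
    rng = random.Random(seed)
    ids = [f"S{i + 1}" for i in range(spec.n_strands)]
    lo, hi = spec.length_range
    lengths = [rng.randint(lo, hi) for _ in ids]
    if spec.duplicate_strands:
        lengths[1] = lengths[0]
    b = _SeqBuilder(ids, lengths, rng)

    planted_structs: Dict[str, FrozenSet[BasePair]] = {}
    planted_inters: List[FrozenSet[BasePair]] = []
    structures: List[StructureVertex] = []
    interactions: List[InteractionVertex] = []

    plant_ids = ids if not spec.duplicate_strands else [i for i in ids if i != ids[1]]
    if spec.plant_optimum:
        # strong GC hairpin per strand, strong GC duplex between consecutive
        # strands; sizes adapt to the positions still free on each strand
        for sid in plant_ids:
            helix = None
            for stem in range(min(4, (b.length(sid) - 3) // 2), 2, -1):
                helix = _intra_helix(b, sid, rng, stem, gc_only=True, want_overlap=False)
                if helix is not None:
                    break
            if helix is None:
                return None
            planted_structs[sid] = frozenset(helix)
            b.mark_used(helix)
            structures.append(
                StructureVertex(sid, frozenset(helix), source="planted")
            )
        for s1, s2 in zip(plant_ids, plant_ids[1:]):
            free1 = b.length(s1) - len(b.used[s1])
            free2 = b.length(s2) - len(b.used[s2])
            duplex = None
            for k in range(min(6, free1, free2), 2, -1):
                duplex = _inter_helix(b, s1, s2, rng, k, gc_only=True, want_overlap=False)
                if duplex is not None:
                    break
            if duplex is None:
                return None
            planted_inters.append(frozenset(duplex))
            b.mark_used(duplex)
            interactions.append(
                InteractionVertex((s1, s2), frozenset(duplex), source="planted")
            )

    # decoy / ordinary candidates
    for sid in (plant_ids if spec.duplicate_strands else ids):
        n_cands = spec.structures_per_strand - (1 if spec.plant_optimum else 0)
        for _ in range(max(0, n_cands)):
            klo, khi = spec.helix_len_range
            k = rng.randint(klo, khi) if not spec.plant_optimum else klo
            want_overlap = True if rng.random() < spec.overlap_prob else None
            helices = []
            h = _intra_helix(b, sid, rng, k, want_overlap=want_overlap)
            if h is None:
                continue
            helices.extend(h)
            if spec.pseudoknot_prob and rng.random() < spec.pseudoknot_prob:
                h2 = _intra_helix(b, sid, rng, max(2, k - 1))
                if h2 is not None:
                    try:
                        StructureVertex(sid, frozenset(helices + h2))
                        helices.extend(h2)
                    except InputError:
                        pass  # reused position inside one candidate: drop arm
            try:
                v = StructureVertex(sid, frozenset(helices))
            except InputError:
                continue
            b.mark_used(list(v.pairs))
            structures.append(v)

    pair_iter = [
        (a, c)
        for idx, a in enumerate(plant_ids if spec.duplicate_strands else ids)
        for c in (plant_ids if spec.duplicate_strands else ids)[idx + 1:]
    ]
    for s1, s2 in pair_iter:
        n_cands = spec.interactions_per_pair
        if spec.plant_optimum and frozenset((s1, s2)) in {
            frozenset(p) for p in zip(plant_ids, plant_ids[1:])
        }:
            n_cands -= 1
        for _ in range(max(0, n_cands)):
            klo, _khi = spec.helix_len_range
            k = klo if spec.plant_optimum else rng.randint(klo, min(_khi, 4))
            if spec.plant_optimum:
                # decoys must conflict with the plant: cover a planted position
                all_planted = [
                    ep
                    for ps in list(planted_structs.values()) + planted_inters
                    for p in ps
                    for ep in p.endpoints
                    if ep[0] in (s1, s2)
                ]
                if not all_planted:
                    continue
                cover = rng.choice(all_planted)
                h = _inter_helix(b, s1, s2, rng, k, must_cover=cover)
            else:
                want_overlap = True if rng.random() < spec.overlap_prob else None
                h = _inter_helix(b, s1, s2, rng, k, want_overlap=want_overlap)
            if h is None:
                continue
            try:
                v = InteractionVertex((s1, s2), frozenset(h))
            except InputError:
                continue
            b.mark_used(list(v.pairs))
            interactions.append(v)

    if spec.duplicate_strands:
        twin, original = ids[1], ids[0]
        b.letters[twin] = list(b.letters[original])
        extra_structs = [
            StructureVertex(twin, frozenset(
                BasePair((twin, p.a[1]), (twin, p.b[1])) for p in v.pairs
            ), source=v.source)
            for v in structures
            if v.strand_id == original
        ]
        extra_inters = []
        for v in interactions:
            if original in v.strand_pair and twin not in v.strand_pair:
                other = v.strand_pair[0] if v.strand_pair[1] == original else v.strand_pair[1]
                mapped = frozenset(
                    BasePair(
                        tuple((twin, ep[1]) if ep[0] == original else ep for ep in p.endpoints)[0],
                        tuple((twin, ep[1]) if ep[0] == original else ep for ep in p.endpoints)[1],
                    )
                    for p in v.pairs
                )
                try:
                    extra_inters.append(
                        InteractionVertex((twin, other), mapped, source=v.source)
                    )
                except InputError:
                    continue
        structures.extend(extra_structs)
        interactions.extend(extra_inters)

    if not interactions:
        return None

    strands = b.strand_set(ids)
    planted = (
        PlantedSolution(
            structure_pairs=dict(planted_structs),
            interaction_pairs=tuple(planted_inters),
        )
        if spec.plant_optimum
        else None
    )
    inst = Instance(
        strands=strands,
        structures=structures,
        interactions=interactions,
        planted=planted,
    )
    if spec.plant_optimum and not _plant_is_optimal(inst):
        return None
    return inst


def planted_members(g: CompatibilityGraph, planted: PlantedSolution) -> FrozenSet[int]:
    """Vertex ids of the planted selection in a built graph."""
    members: Set[int] = set()
    for v in g.vertices:
        if isinstance(v, StructureVertex):
            want = planted.structure_pairs.get(v.strand_id)
            if want is not None and v.pairs == want:
                members.add(v.vertex_id)
            elif want is None and v.is_empty:
                # strands without a planted structure take the empty one
                members.add(v.vertex_id)
        else:
            if v.pairs in planted.interaction_pairs:
                members.add(v.vertex_id)
    return frozenset(members)


def _plant_is_optimal(inst: Instance) -> bool:
    g = inst.graph()
    try:
        ranked = brute_force_optimum(g, top_k=2)
    except GuardExceeded:
        return False
    if not ranked:
        return False
    plant = planted_members(g, inst.planted)
    if ranked[0].members != plant:
        return False
    return len(ranked) < 2 or ranked[0].weight > ranked[1].weight + 1e-9


def generate_instance(spec: InstanceSpec) -> Instance:
    """Generate one instance; deterministic for a fixed spec (incl. seed).

    Planted instances are re-drawn (with seeds derived from ``spec.seed``)
    until the exhaustive oracle confirms the plant is the strictly dominant
    constrained optimum; well-formed specs converge in a draw or two.
    """
    attempts = 64 if spec.plant_optimum else 16
    for attempt in range(attempts):
        derived = (spec.seed * 1000003 + attempt) & 0x7FFFFFFF
        inst = _generate_once(spec, derived)
        if inst is not None:
            return inst
    raise InputError(
        f"could not generate a valid instance for {spec} in {attempts} draws"
    )


# ---------------------------------------------------------------------------
# exhaustive oracle


def brute_force_optimum(
    g: CompatibilityGraph,
    top_k: Optional[int] = None,
    guard: int = 2_000_000,
) -> List[Clique]:
    """Enumerate every valid constrained clique and rank by weight.

    The combination count (product of per-strand structure counts times
    2^interactions) must stay within ``guard``; beyond it the oracle refuses
    rather than risk silent truncation.
    """
    combos = 1
    for sid, vids in g.structure_ids_by_strand.items():
        combos *= max(1, len(vids))
    combos *= 2 ** len(g.interaction_ids)
    if combos > guard:
        raise GuardExceeded(
            f"{combos} combinations exceed the enumeration guard ({guard})"
        )

    adj = g.adjacency
    npairs = [len(v.pairs) for v in g.vertices]
    inters = g.interaction_ids
    results: List[Tuple[float, Tuple, FrozenSet[int]]] = []

    for struct_combo in itertools.product(*g.structure_ids_by_strand.values()):
        base_mask = 0
        for v in struct_combo:
            base_mask |= 1 << v
        base_pairs = sum(npairs[v] for v in struct_combo)
        # DFS over interaction subsets, pruning incompatible extensions
        stack = [(0, base_mask, base_pairs, ())]
        while stack:
            idx, mask, pairs, chosen = stack.pop()
            if idx == len(inters):
                if pairs > 0:
                    members = frozenset(struct_combo) | frozenset(chosen)
                    weight = sum(g.vertex(m).weight for m in members)
                    results.append((weight, members))
                continue
            v = inters[idx]
            stack.append((idx + 1, mask, pairs, chosen))
            if adj[v] & mask == mask:
                stack.append(
                    (idx + 1, mask | 1 << v, pairs + npairs[v], chosen + (v,))
                )

    def sort_key(item):
        weight, members = item
        serial = tuple(
            sorted(p.endpoints for m in members for p in g.vertex(m).pairs)
        )
        return (-weight, serial)

    results.sort(key=sort_key)
    if top_k is not None:
        results = results[:top_k]
    return [make_clique(members, g) for _, members in results]
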