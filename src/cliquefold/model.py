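"""Domain model: strands, base pairs, candidate vertices and the
compatibility graph.

An RNA complex is modelled as a selection of candidate *secondary
structures* (one per strand) and candidate *interaction sites* (between
strand pairs) that are mutually compatible.  Candidates are vertices of a
graph whose edges encode compatibility; a complex is then a clique subject
to two constraints: exactly one structure vertex per strand, and at least
one base pair overall (a "weak" clique with no pairs is not a complex).

Positions are 0-based throughout the in-memory model; 1-based coordinates
exist only at file boundaries (see :mod:`cliquefold.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import InputError

RNA_ALPHABET = frozenset("ACGU")

Endpoint = Tuple[str, int]


@dataclass(frozen=True)
class Strand:
    """A named RNA strand; the sequence is normalized to uppercase A/C/G/U."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if not self.id:
            raise InputError("strand id must be non-empty")
        if len(seq) < 1:
            raise InputError(f"strand {self.id!r}: empty sequence")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise InputError(
                f"strand {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class StrandSet:
    """Ordered collection of uniquely named strands."""

    def __init__(self, strands: Iterable[Strand]):
        self._strands: Dict[str, Strand] = {}
        for s in strands:
            if s.id in self._strands:
                raise InputError(f"duplicate strand id {s.id!r}")
            self._strands[s.id] = s
        if not self._strands:
            raise InputError("a StrandSet needs at least one strand")

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "StrandSet":
        return cls(Strand(k, v) for k, v in d.items())

    def __iter__(self):
        return iter(self._strands.values())

    def __len__(self) -> int:
        return len(self._strands)

    def __contains__(self, strand_id: str) -> bool:
        return strand_id in self._strands

    def __getitem__(self, strand_id: str) -> Strand:
        try:
            return self._strands[strand_id]
        except KeyError:
            raise InputError(f"unknown strand id {strand_id!r}") from None

    @property
    def ids(self) -> List[str]:
        return list(self._strands)

    def nucleotide(self, endpoint: Endpoint) -> str:
        sid, pos = endpoint
        return self[sid].sequence[pos]

    def total_length(self) -> int:
        return sum(len(s) for s in self)


@dataclass(frozen=True)
class BasePair:
    """An unordered base pair between two (strand, position) endpoints.

    Stored in canonical lexicographic order so equality is order-insensitive.
    """

    a: Endpoint
    b: Endpoint

    def __post_init__(self) -> None:
        a, b = (tuple(self.a), tuple(self.b))
        if a == b:
            raise InputError(f"degenerate base pair at {a}")
        if b < a:
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def endpoints(self) -> Tuple[Endpoint, Endpoint]:
        return (self.a, self.b)

    def validate(self, strands: StrandSet) -> None:
        for sid, pos in self.endpoints:
            strand = strands[sid]
            if not 0 <= pos < len(strand):
                raise InputError(
                    f"position {pos} out of range for strand {sid!r} "
                    f"(length {len(strand)})"
                )


def _paired_positions(pairs: Iterable[BasePair]) -> FrozenSet[Endpoint]:
    seen = set()
    for p in pairs:
        for ep in p.endpoints:
            if ep in seen:
                raise InputError(f"position {ep} used by more than one base pair")
            seen.add(ep)
    return frozenset(seen)


def _is_crossing_intra(pairs: Sequence[Tuple[int, int]]) -> bool:
    arcs = sorted((min(i, j), max(i, j)) for i, j in pairs)
    for k, (i, j) in enumerate(arcs):
        for (a, b) in arcs[k + 1:]:
            if i < a < j < b:
                return True
    return False


@dataclass(frozen=True)
class StructureVertex:
    """A candidate secondary structure of a single strand.

    ``energy`` is the free energy in kcal/mol (negative = stabilizing);
    ``weight`` is the solver weight derived from it (see energy module).
    """

    strand_id: str
    pairs: FrozenSet[BasePair]
    energy: float = 0.0
    weight: float = 0.0
    vertex_id: int = -1
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        for p in self.pairs:
            for sid, _ in p.endpoints:
                if sid != self.strand_id:
                    raise InputError(
                        f"structure candidate on strand {self.strand_id!r} "
                        f"contains a pair touching strand {sid!r}"
                    )
        _paired_positions(self.pairs)  # rejects reused positions

    @property
    def is_empty(self) -> bool:
        return not self.pairs

    @property
    def is_pseudoknotted(self) -> bool:
        return _is_crossing_intra([(p.a[1], p.b[1]) for p in self.pairs])

    @property
    def paired_positions(self) -> FrozenSet[Endpoint]:
        return _paired_positions(self.pairs)

    def validate(self, strands: StrandSet) -> None:
        if self.strand_id not in strands:
            raise InputError(f"unknown strand id {self.strand_id!r}")
        for p in self.pairs:
            p.validate(strands)


@dataclass(frozen=True)
class InteractionVertex:
    """A candidate interaction site: inter-strand base pairs between two
    strands, non-crossing within the site (crossing interactions arise only
    between distinct sites)."""

    strand_pair: Tuple[str, str]
    pairs: FrozenSet[BasePair]
    energy: float = 0.0
    weight: float = 0.0
    vertex_id: int = -1
    source: str = ""

    def __post_init__(self) -> None:
        s1, s2 = sorted(self.strand_pair)
        if s1 == s2:
            raise InputError("an interaction needs two distinct strands")
        object.__setattr__(self, "strand_pair", (s1, s2))
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        if not self.pairs:
            raise InputError("an interaction site needs at least one base pair")
        for p in self.pairs:
            sids = {sid for sid, _ in p.endpoints}
            if sids != {s1, s2}:
                raise InputError(
                    f"interaction {s1!r}-{s2!r} contains a pair on strands "
                    f"{sorted(sids)}"
                )
        _paired_positions(self.pairs)
        # Orient each pair as (pos on s1, pos on s2); with the concatenation
        # s1+s2, two arcs cross iff both coordinates increase together.
        arcs = []
        for p in self.pairs:
            d = dict((sid, pos) for sid, pos in p.endpoints)
            arcs.append((d[s1], d[s2]))
        arcs.sort()
        for k in range(len(arcs) - 1):
            (p1, q1), (p2, q2) = arcs[k], arcs[k + 1]
            if q2 > q1:
                raise InputError(
                    f"interaction {s1!r}-{s2!r}: pairs ({p1},{q1}) and "
                    f"({p2},{q2}) cross within one site"
                )

    @property
    def is_empty(self) -> bool:
        return False

    @property
    def paired_positions(self) -> FrozenSet[Endpoint]:
        return _paired_positions(self.pairs)

    def validate(self, strands: StrandSet) -> None:
        for sid in self.strand_pair:
            if sid not in strands:
                raise InputError(f"unknown strand id {sid!r}")
        for p in self.pairs:
            p.validate(strands)


def are_compatible(u, v) -> bool:
    """Two candidates are compatible iff they are not two structures of the
    same strand and no nucleotide position is paired in both.

    Crossing between compatible candidates (interleaved, disjoint pairs) is
    allowed: pseudoknots and crossing interactions are legitimate motifs.
    """
    u_struct = isinstance(u, StructureVertex)
    v_struct = isinstance(v, StructureVertex)
    if u_struct and v_struct and u.strand_id == v.strand_id:
        return False
    return not (u.paired_positions & v.paired_positions)


class CompatibilityGraph:
    """Candidate vertices plus the pairwise compatibility relation.

    Vertices get contiguous integer ids on construction; adjacency is stored
    as one bitmask per vertex (bit ``j`` of ``adjacency[i]`` set iff ``i`` and
    ``j`` are compatible), which the solver relies on for speed.
    """

    def __init__(self, strands: StrandSet, vertices: Sequence):
        self.strands = strands
        self.vertices: List = list(vertices)
        self.structure_ids_by_strand: Dict[str, List[int]] = {
            sid: [] for sid in strands.ids
        }
        self.interaction_ids: List[int] = []
        for v in self.vertices:
            if isinstance(v, StructureVertex):
                self.structure_ids_by_strand[v.strand_id].append(v.vertex_id)
            else:
                self.interaction_ids.append(v.vertex_id)
        n = len(self.vertices)
        self.adjacency: List[int] = [0] * n
        pos_sets = [v.paired_positions for v in self.vertices]
        for i in range(n):
            vi = self.vertices[i]
            for j in range(i + 1, n):
                vj = self.vertices[j]
                if isinstance(vi, StructureVertex) and isinstance(
                    vj, StructureVertex
                ) and vi.strand_id == vj.strand_id:
                    continue
                if pos_sets[i] & pos_sets[j]:
                    continue
                self.adjacency[i] |= 1 << j
                self.adjacency[j] |= 1 << i

    def __len__(self) -> int:
        return len(self.vertices)

    def vertex(self, vertex_id: int):
        return self.vertices[vertex_id]

    def adjacent(self, u: int, v: int) -> bool:
        return bool(self.adjacency[u] >> v & 1)

    def is_interaction(self, vertex_id: int) -> bool:
        return isinstance(self.vertices[vertex_id], InteractionVertex)

    def empty_structure_id(self, strand_id: str) -> int:
        for vid in self.structure_ids_by_strand[strand_id]:
            if self.vertices[vid].is_empty:
                return vid
        raise AssertionError("auto-inserted empty structure missing")

    def to_networkx(self):
        """Export as a networkx.Graph (vertex ids as nodes, weights as
        node attributes) for interoperability and cross-checking."""
        import networkx as nx

        g = nx.Graph()
        for v in self.vertices:
            g.add_node(v.vertex_id, weight=v.weight, energy=v.energy)
        n = len(self.vertices)
        for i in range(n):
            mask = self.adjacency[i] >> (i + 1) << (i + 1)
            while mask:
                j = (mask & -mask).bit_length() - 1
                g.add_edge(i, j)
                mask &= mask - 1
        return g


def build_graph(
    strands: StrandSet,
    structures: Mapping[str, Iterable[StructureVertex]] | Iterable[StructureVertex],
    interactions: Iterable[InteractionVertex],
) -> CompatibilityGraph:
    """Assemble the compatibility graph from validated candidates.

    Duplicates (same strand scope and pair set) collapse onto the first
    occurrence; every strand additionally gets one empty structure vertex if
    none was supplied, guaranteeing feasibility of the one-per-strand
    constraint.
    """
    if isinstance(structures, Mapping):
        struct_list: List[StructureVertex] = []
        for sid, cands in structures.items():
            for c in cands:
                if c.strand_id != sid:
                    raise InputError(
                        f"candidate for strand {sid!r} declares strand "
                        f"{c.strand_id!r}"
                    )
                struct_list.append(c)
    else:
        struct_list = list(structures)

    ordered: List = []
    seen = set()
    for v in struct_list:
        v.validate(strands)
        key = ("S", v.strand_id, v.pairs)
        if key not in seen:
            seen.add(key)
            ordered.append(v)
    for sid in strands.ids:
        key = ("S", sid, frozenset())
        if key not in seen:
            seen.add(key)
            ordered.append(StructureVertex(sid, frozenset(), source="auto-empty"))
    for v in interactions:
        if not isinstance(v, InteractionVertex):
            raise InputError("interaction candidate of wrong type")
        v.validate(strands)
        key = ("I", v.strand_pair, v.pairs)
        if key not in seen:
            seen.add(key)
            ordered.append(v)

    from dataclasses import replace

    renumbered = [replace(v, vertex_id=i) for i, v in enumerate(ordered)]
    return CompatibilityGraph(strands, renumbered)


@dataclass(frozen=True)
class Clique:
    """A set of mutually compatible vertices with its summed weight and its
    total base-pair count (a clique with zero pairs is *weak*)."""

    members: FrozenSet[int]
    weight: float
    total_pairs: int

    @property
    def is_weak(self) -> bool:
        return self.total_pairs == 0


def make_clique(members: Iterable[int], g: CompatibilityGraph) -> Clique:
    members = frozenset(members)
    return Clique(
        members=members,
        weight=clique_weight(members, g),
        total_pairs=sum(len(g.vertex(m).pairs) for m in members),
    )


def clique_weight(members: Iterable[int], g: CompatibilityGraph) -> float:
    """Exact sum of member weights (0 for the empty set)."""
    return sum(g.vertex(m).weight for m in members)


def is_valid_constrained_clique(c: Clique | Iterable[int], g: CompatibilityGraph) -> bool:
    """True iff members are pairwise compatible, there is exactly one
    structure vertex per strand, and the clique is not weak."""
    members = sorted(c.members if isinstance(c, Clique) else set(c))
    for i, u in enumerate(members):
        for v in members[i + 1:]:
            if not g.adjacent(u, v):
                return False
    per_strand = {sid: 0 for sid in g.strands.ids}
    total_pairs = 0
    for m in members:
        v = g.vertex(m)
        total_pairs += len(v.pairs)
        if isinstance(v, StructureVertex):
            per_strand[v.strand_id] += 1
    if any(count != 1 for count in per_strand.values()):
        return False
    return total_pairs > 0


@dataclass(frozen=True)
class ComplexPrediction:
    """A ranked RNA complex: the clique, the union of its base pairs, and
    the total free energy (sum of member energies; more negative = more
    stable)."""

    clique: Clique
    all_pairs: FrozenSet[BasePair]
    energy: float
    rank: int = 0


def complex_from_clique(
    members: Iterable[int], g: CompatibilityGraph, rank: int = 0
) -> ComplexPrediction:
    clique = make_clique(members, g)
    pairs: set = set()
    energy = 0.0
    for m in clique.members:
        v = g.vertex(m)
        pairs.update(v.pairs)
        energy += v.energy
    return ComplexPrediction(
        clique=clique, all_pairs=frozenset(pairs), energy=energy, rank=rank
    )
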