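"""Free-energy models for candidate vertices.

Two models are used, mirroring how multi-source candidates are put on a
common energy scale:

* a nearest-neighbor (Turner 2004) loop decomposition for pseudoknot-free
  secondary structures and for inter-strand interaction sites (scored as
  duplexes), and
* a plain sum of stacking energies for pseudoknotted structures, where the
  loop decomposition is undefined.

The solver weight of a vertex is ``max(0, -energy)``: the search maximizes
total weight, i.e. minimizes total free energy over stabilizing candidates,
and a destabilizing candidate is never preferred over the empty structure.

All energies are kcal/mol at 37 degrees C; no dangling-end or coaxial
stacking terms are included (see docs/methods.md for the convention).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

from ..errors import ScoringError
from ..model import (
    BasePair,
    CompatibilityGraph,
    InteractionVertex,
    StrandSet,
    StructureVertex,
)
from .params import NNModelParams, StackTable, is_canonical, load_params

__all__ = [
    "NNModelParams",
    "StackTable",
    "load_params",
    "stacking_sum_energy",
    "nn_structure_energy",
    "interaction_energy",
    "assign_energies",
    "assign_weights",
    "score_graph",
]


def _check_canonical(pairs: Iterable[BasePair], strands: StrandSet) -> None:
    for p in pairs:
        x = strands.nucleotide(p.a)
        y = strands.nucleotide(p.b)
        if not is_canonical(x, y):
            raise ScoringError(
                f"non-canonical base pair {p.a}-{p.b} ({x}-{y}); only "
                "A-U, G-C and G-U pairs can be scored"
            )


def stacking_sum_energy(
    pairs: FrozenSet[BasePair] | set,
    strands: StrandSet,
    params: Optional[NNModelParams] = None,
) -> float:
    """Sum of stacking energies over all stacked adjacencies in ``pairs``.

    Two pairs stack when, in canonical endpoint order, one is exactly the
    other shifted inward by one position on both endpoints: (i, j) and
    (i+1, j-1) on one strand, or the analogous adjacent-on-both-strands
    relation for inter-strand pairs.  Isolated pairs contribute nothing, so
    the model is well defined for arbitrarily crossing (pseudoknotted) pair
    sets.
    """
    params = params or load_params()
    _check_canonical(pairs, strands)
    by_endpoints = {p.endpoints: p for p in pairs}
    total = 0.0
    for ((sa, pa), (sb, pb)) in by_endpoints:
        inner = ((sa, pa + 1), (sb, pb - 1))
        if pb - 1 < 0 or inner not in by_endpoints:
            continue
        xi = strands.nucleotide((sa, pa))
        xj = strands.nucleotide((sb, pb))
        xp = strands.nucleotide(inner[0])
        xq = strands.nucleotide(inner[1])
        try:
            total += params.stack.stack_energy(xi, xj, xp, xq)
        except KeyError as e:  # canonical pairs always resolve; guard anyway
            raise ScoringError(str(e)) from None
    return total


def _two_loop_energy(
    n1: int,
    n2: int,
    outer: Tuple[str, str],
    inner: Tuple[str, str],
    mismatches: Tuple[str, str, str, str],
    params: NNModelParams,
) -> float:
    """Energy of the loop between two pairs: stack, bulge or internal loop.

    ``outer`` is (x_i, x_j); ``inner`` is (x_p, x_q) for the enclosed pair;
    ``mismatches`` holds (x_{i+1}, x_{j-1}, x_{p-1}, x_{q+1}).  n1/n2 are the
    unpaired counts on the two sides.
    """
    xi, xj = outer
    xp, xq = inner
    if n1 == 0 and n2 == 0:
        return params.stack.stack_energy(xi, xj, xp, xq)
    if n1 == 0 or n2 == 0:  # bulge
        size = n1 + n2
        e = params.loop_penalty(params.bulge_length, size)
        if size == 1:
            e += params.stack.stack_energy(xi, xj, xp, xq)
        else:
            e += params.terminal_penalty(xi + xj)
            e += params.terminal_penalty(xq + xp)
        return e
    si1, sj1, sp1, sq1 = mismatches
    e = params.loop_penalty(params.internal_length, n1 + n2)
    e += min(params.ninio_max_asym, abs(n1 - n2) * params.ninio_per_asym)
    e += params.mismatch_internal[(xi + xj, si1, sj1)]
    e += params.mismatch_internal[(xq + xp, sq1, sp1)]
    return e


def _hairpin_energy(i: int, j: int, seq: str, params: NNModelParams) -> float:
    size = j - i - 1
    pair = seq[i] + seq[j]
    if size in (3, 4, 6):
        special = params.special_hairpins.get(seq[i : j + 1])
        if special is not None:
            if size == 3:
                return special + params.terminal_penalty(pair)
            return special
    e = params.loop_penalty(params.hairpin_length, size)
    if size == 3:
        e += params.terminal_penalty(pair)
    else:
        e += params.mismatch_hairpin[(pair, seq[i + 1], seq[j - 1])]
    return e


def _nesting_children(arcs: List[Tuple[int, int]]) -> Dict[Tuple[int, int], list]:
    """Direct-nesting children for a non-crossing arc set (None = root)."""
    children: Dict = {None: []}
    stack: List[Tuple[int, int]] = []
    for arc in sorted(arcs):
        while stack and arc[0] > stack[-1][1]:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(arc, [])
        children[parent].append(arc)
        stack.append(arc)
    return children


def nn_structure_energy(
    v: StructureVertex,
    strands: StrandSet,
    params: Optional[NNModelParams] = None,
) -> float:
    """Nearest-neighbor free energy of a pseudoknot-free secondary structure.

    Decomposes the structure into hairpins, stacks, bulges, internal loops,
    multiloops and the exterior loop.  The empty structure scores 0.
    """
    params = params or load_params()
    if v.is_empty:
        return 0.0
    if v.is_pseudoknotted:
        raise ScoringError(
            "nearest-neighbor model is undefined for pseudoknotted "
            "structures; use stacking_sum_energy"
        )
    _check_canonical(v.pairs, strands)
    seq = strands[v.strand_id].sequence
    arcs = sorted((min(p.a[1], p.b[1]), max(p.a[1], p.b[1])) for p in v.pairs)
    children = _nesting_children(arcs)

    total = 0.0
    for (i, j) in children[None]:  # exterior-loop branches
        total += params.terminal_penalty(seq[i] + seq[j])
    for arc, kids in children.items():
        if arc is None:
            continue
        i, j = arc
        if not kids:
            total += _hairpin_energy(i, j, seq, params)
        elif len(kids) == 1:
            (p, q) = kids[0]
            total += _two_loop_energy(
                p - i - 1,
                j - q - 1,
                (seq[i], seq[j]),
                (seq[p], seq[q]),
                (seq[i + 1], seq[j - 1], seq[p - 1], seq[q + 1]),
                params,
            )
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for (p, q) in kids)
            total += (
                params.ml_closing
                + params.ml_branch * (len(kids) + 1)
                + params.ml_unpaired * unpaired
                + params.terminal_penalty(seq[i] + seq[j])
                + sum(params.terminal_penalty(seq[p] + seq[q]) for (p, q) in kids)
            )
    return total


def interaction_energy(
    v: InteractionVertex,
    strands: StrandSet,
    params: Optional[NNModelParams] = None,
) -> float:
    """Free energy of an interaction site scored as an RNA-RNA duplex:
    duplex initiation + stacks between consecutive pairs + bulge/internal
    loop penalties for gaps + terminal AU/GU penalties at both ends."""
    params = params or load_params()
    _check_canonical(v.pairs, strands)
    s1, s2 = v.strand_pair
    seq1 = strands[s1].sequence
    seq2 = strands[s2].sequence
    arcs = sorted(
        (dict(p.endpoints)[s1], dict(p.endpoints)[s2]) for p in v.pairs
    )
    e = params.duplex_init
    p0, q0 = arcs[0]
    pn, qn = arcs[-1]
    e += params.terminal_penalty(seq1[p0] + seq2[q0])
    e += params.terminal_penalty(seq1[pn] + seq2[qn])
    for (pa, qa), (pb, qb) in zip(arcs, arcs[1:]):
        n1 = pb - pa - 1
        n2 = qa - qb - 1
        e += _two_loop_energy(
            n1,
            n2,
            (seq1[pa], seq2[qa]),
            (seq1[pb], seq2[qb]),
            (seq1[pa + 1], seq2[qa - 1], seq1[pb - 1], seq2[qb + 1]),
            params,
        )
    return e


def vertex_energy(v, strands: StrandSet, params: Optional[NNModelParams] = None) -> float:
    """Route a vertex to its model: nearest-neighbor for pseudoknot-free
    structures and for interactions, stacking sum for pseudoknotted ones."""
    params = params or load_params()
    if isinstance(v, InteractionVertex):
        return interaction_energy(v, strands, params)
    if v.is_empty:
        return 0.0
    if v.is_pseudoknotted:
        return stacking_sum_energy(v.pairs, strands, params)
    return nn_structure_energy(v, strands, params)


def assign_energies(
    g: CompatibilityGraph, params: Optional[NNModelParams] = None
) -> CompatibilityGraph:
    """Compute and store the free energy of every vertex in place."""
    params = params or load_params()
    for i, v in enumerate(g.vertices):
        g.vertices[i] = replace(v, energy=vertex_energy(v, g.strands, params))
    return g


def assign_weights(g: CompatibilityGraph) -> CompatibilityGraph:
    """Set weight(v) = max(0, -energy(v)) so that maximizing total weight
    minimizes total free energy over stabilizing candidates."""
    for i, v in enumerate(g.vertices):
        g.vertices[i] = replace(v, weight=max(0.0, -v.energy))
    return g


def score_graph(
    g: CompatibilityGraph, params: Optional[NNModelParams] = None
) -> CompatibilityGraph:
    """Energies then weights, in one call."""
    return assign_weights(assign_energies(g, params))
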