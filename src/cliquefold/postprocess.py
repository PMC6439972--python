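"""From archived cliques to ranked complex predictions.

When several strands carry character-identical sequences, relabeling those
strands maps one valid complex onto another ("symmetrical" duplicates).
Such duplicates are collapsed by canonicalizing every complex over all
within-class strand permutations before ranking by free energy.
"""

from __future__ import annotations

import itertools
import logging
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

from .model import (
    BasePair,
    Clique,
    CompatibilityGraph,
    ComplexPrediction,
    StrandSet,
    complex_from_clique,
)

logger = logging.getLogger(__name__)

DEFAULT_CLASS_CAP = 6


class SymmetryGroups:
    """Partition of strand ids into classes of identical sequences."""

    def __init__(self, strands: StrandSet):
        by_seq: Dict[str, List[str]] = {}
        for s in strands:
            by_seq.setdefault(s.sequence, []).append(s.id)
        self.classes: List[List[str]] = list(by_seq.values())

    def nontrivial(self) -> List[List[str]]:
        return [c for c in self.classes if len(c) > 1]


def _relabel_pairs(
    pairs: Iterable[BasePair], mapping: Dict[str, str]
) -> FrozenSet[BasePair]:
    return frozenset(
        BasePair(
            (mapping.get(p.a[0], p.a[0]), p.a[1]),
            (mapping.get(p.b[0], p.b[0]), p.b[1]),
        )
        for p in pairs
    )


def _serialize(pairs: Iterable[BasePair]) -> Tuple:
    return tuple(sorted(p.endpoints for p in pairs))


def canonical_form(
    pairs: Iterable[BasePair],
    groups: SymmetryGroups,
    class_cap: int = DEFAULT_CLASS_CAP,
) -> Tuple:
    """Lexicographically minimal serialization of ``pairs`` over all
    permutations of strand ids within each identical-sequence class.

    Classes larger than ``class_cap`` fall back to the identity permutation
    (with a warning) to avoid factorial blowup; real complexes rarely have
    more than a handful of identical strands.
    """
    pairs = list(pairs)
    classes = groups.nontrivial()
    for cls in classes:
        if len(cls) > class_cap:
            logger.warning(
                "symmetry class of size %d exceeds cap %d; using identity "
                "permutation",
                len(cls),
                class_cap,
            )
            return _serialize(pairs)
    best = None
    perm_sets = [list(itertools.permutations(cls)) for cls in classes]
    for combo in itertools.product(*perm_sets):
        mapping: Dict[str, str] = {}
        for cls, perm in zip(classes, combo):
            mapping.update(dict(zip(cls, perm)))
        key = _serialize(_relabel_pairs(pairs, mapping))
        if best is None or key < best:
            best = key
    return best if best is not None else _serialize(pairs)


def dedup_and_rank(
    archive: Sequence[Clique],
    g: CompatibilityGraph,
    groups: SymmetryGroups | None = None,
    max_solutions: int = 10,
    class_cap: int = DEFAULT_CLASS_CAP,
) -> List[ComplexPrediction]:
    """One representative per canonical form (lowest energy, first
    encountered on ties), sorted by non-decreasing free energy (ties broken
    by canonical key for determinism), truncated to ``max_solutions``."""
    groups = groups or SymmetryGroups(g.strands)
    best_by_key: Dict[Tuple, Tuple[float, int, ComplexPrediction]] = {}
    for order, clique in enumerate(archive):
        pred = complex_from_clique(clique.members, g)
        key = canonical_form(pred.all_pairs, groups, class_cap)
        incumbent = best_by_key.get(key)
        if incumbent is None or pred.energy < incumbent[0] - 1e-12:
            best_by_key[key] = (pred.energy, order, pred)
    ranked = sorted(
        ((energy, key, pred) for key, (energy, _, pred) in best_by_key.items()),
        key=lambda t: (t[0], t[1]),
    )
    out: List[ComplexPrediction] = []
    for rank, (_, _, pred) in enumerate(ranked[:max_solutions], start=1):
        out.append(
            ComplexPrediction(
                clique=pred.clique,
                all_pairs=pred.all_pairs,
                energy=pred.energy,
                rank=rank,
            )
        )
    return out
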