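"""Base-pair-level scoring of predicted complexes against a reference.

TP/FP/FN count base pairs; TN counts the remaining unordered pairs of
nucleotide positions over the whole complex (intra- and inter-strand), so
the universe size is N(N-1)/2 for N total nucleotides.  Four statistics are
derived: sensitivity (recall), PPV (precision), their harmonic mean F1, and
the Matthews correlation coefficient.  Degenerate zero denominators return
0 by convention so means over many complexes stay defined.

Before counting, both pair sets are canonicalized over identical-sequence
strand permutations so a symmetric relabeling is never penalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .errors import EvaluationError
from .model import BasePair, ComplexPrediction, StrandSet
from .postprocess import SymmetryGroups, canonical_form


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be non-negative")


def _checked(pairs: Iterable[BasePair], strands: StrandSet) -> FrozenSet[BasePair]:
    pairs = frozenset(pairs)
    for p in pairs:
        for sid, pos in p.endpoints:
            if sid not in strands:
                raise EvaluationError(f"pair references unknown strand {sid!r}")
            if not 0 <= pos < len(strands[sid]):
                raise EvaluationError(
                    f"pair position {pos} out of range on strand {sid!r}"
                )
    return pairs


def confusion_counts(
    predicted: Iterable[BasePair],
    reference: Iterable[BasePair],
    strands: StrandSet,
    symmetric: bool = True,
) -> ConfusionCounts:
    """Count TP/FP/FN/TN base pairs of ``predicted`` against ``reference``.

    With ``symmetric=True`` (default) the predicted set is first mapped to
    the within-class strand relabeling that maximizes agreement with the
    reference, so complexes of identical strands are compared up to
    symmetry.
    """
    predicted = _checked(predicted, strands)
    reference = _checked(reference, strands)
    if symmetric:
        groups = SymmetryGroups(strands)
        if groups.nontrivial():
            predicted = _best_relabeling(predicted, reference, groups)
    n = strands.total_length()
    universe = n * (n - 1) // 2
    tp = len(predicted & reference)
    fp = len(predicted - reference)
    fn = len(reference - predicted)
    tn = universe - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _best_relabeling(
    predicted: FrozenSet[BasePair],
    reference: FrozenSet[BasePair],
    groups: SymmetryGroups,
) -> FrozenSet[BasePair]:
    import itertools

    from .postprocess import _relabel_pairs

    classes = groups.nontrivial()
    perm_sets = [list(itertools.permutations(cls)) for cls in classes]
    best = predicted
    best_tp = len(predicted & reference)
    for combo in itertools.product(*perm_sets):
        mapping: Dict[str, str] = {}
        for cls, perm in zip(classes, combo):
            mapping.update(dict(zip(cls, perm)))
        relabeled = _relabel_pairs(predicted, mapping)
        tp = len(relabeled & reference)
        if tp > best_tp:
            best, best_tp = relabeled, tp
    return best


def sensitivity(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def ppv(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def f1(c: ConfusionCounts) -> float:
    s, p = sensitivity(c), ppv(c)
    return 2 * s * p / (s + p) if s + p else 0.0


def mcc(c: ConfusionCounts) -> float:
    denom = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return (c.tp * c.tn - c.fp * c.fn) / denom if denom else 0.0


def all_statistics(c: ConfusionCounts) -> Dict[str, float]:
    return {
        "sensitivity": sensitivity(c),
        "ppv": ppv(c),
        "f1": f1(c),
        "mcc": mcc(c),
    }


@dataclass(frozen=True)
class RankStatistics:
    rank: int
    energy: float
    counts: ConfusionCounts
    sensitivity: float
    ppv: float
    f1: float
    mcc: float


def evaluate_run(
    predictions: Sequence[ComplexPrediction] | Sequence[Tuple[int, float, FrozenSet[BasePair]]],
    reference: Iterable[BasePair],
    strands: StrandSet,
    top_k: int = 10,
) -> Tuple[List[RankStatistics], Dict[str, float]]:
    """Per-rank statistics plus the best-over-top-k summary.

    ``predictions`` may be ComplexPrediction objects or (rank, energy,
    pairs) triples as returned by the TSV reader.  The summary reports the
    maximum of each statistic over the first ``top_k`` ranks.
    """
    rows: List[RankStatistics] = []
    reference = frozenset(reference)
    for item in predictions:
        if isinstance(item, ComplexPrediction):
            rank, energy, pairs = item.rank, item.energy, item.all_pairs
        else:
            rank, energy, pairs = item
        c = confusion_counts(pairs, reference, strands)
        stats = all_statistics(c)
        rows.append(RankStatistics(rank=rank, energy=energy, counts=c, **stats))
    top = [r for r in rows if r.rank <= top_k] or rows
    summary = {
        f"max_{name}_top{top_k}": max(getattr(r, name) for r in top)
        for name in ("sensitivity", "ppv", "f1", "mcc")
    } if rows else {}
    return rows, summary


def mean_summaries(summaries: Sequence[Dict[str, float]]) -> Dict[str, float]:
    """Aggregate per-run best-over-top-k summaries as plain means (the
    repeated-executions protocol for a stochastic solver)."""
    if not summaries:
        return {}
    keys = summaries[0].keys()
    return {k: sum(s[k] for s in summaries) / len(summaries) for k in keys}


def write_report(
    rows: Sequence[RankStatistics], summary: Dict[str, float], path
) -> None:
    """TSV report: one line per rank plus summary comment lines."""
    from pathlib import Path

    lines = ["rank\tenergy\tTP\tFP\tFN\tTN\tsens\tppv\tf1\tmcc"]
    for r in rows:
        c = r.counts
        lines.append(
            f"{r.rank}\t{r.energy:.4f}\t{c.tp}\t{c.fp}\t{c.fn}\t{c.tn}\t"
            f"{r.sensitivity:.4f}\t{r.ppv:.4f}\t{r.f1:.4f}\t{r.mcc:.4f}"
        )
    for k, v in summary.items():
        lines.append(f"# {k}\t{v:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
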