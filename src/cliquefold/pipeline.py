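"""End-to-end prediction pipeline: candidates in, ranked complexes out."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

from .energy import score_graph
from .model import (
    CompatibilityGraph,
    ComplexPrediction,
    InteractionVertex,
    StrandSet,
    StructureVertex,
    build_graph,
)
from .postprocess import SymmetryGroups, dedup_and_rank
from .solver import SolverConfig, run as solve


def predict_complexes(
    strands: StrandSet,
    structures: Sequence[StructureVertex],
    interactions: Sequence[InteractionVertex],
    config: Optional[SolverConfig] = None,
) -> Tuple[List[ComplexPrediction], CompatibilityGraph]:
    """Score candidates, build the compatibility graph, run the clique
    search and return the deduplicated energy-ranked predictions."""
    config = config or SolverConfig()
    g = score_graph(build_graph(strands, structures, interactions))
    archive = solve(g, config)
    predictions = dedup_and_rank(
        archive, g, SymmetryGroups(strands), max_solutions=config.max_solutions
    )
    return predictions, g
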