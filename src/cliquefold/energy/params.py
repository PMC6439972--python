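"""Loading of the embedded Turner 2004 nearest-neighbor parameter tables.

The tables live in ``data/turner2004.txt`` in a documented plain-text
format (one ``key value`` entry per line under ``[section]`` headers, free
energies in kcal/mol at 37 degrees C) so that energies are reproducible
bit-exactly across installs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, Tuple

CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

MAX_TABULATED_LOOP = 30


def is_canonical(x: str, y: str) -> bool:
    return x + y in CANONICAL_PAIRS


@dataclass
class StackTable:
    """Stacking free energies.

    ``get(p1, p2)`` returns the energy of pair ``p1`` = (x_i, x_j) stacked on
    the enclosed pair (x_{i+1}, x_{j-1}), with ``p2`` given in the reversed
    orientation (x_{j-1}, x_{i+1}) as is conventional for 5'->3' reading of
    the second strand.
    """

    table: Dict[Tuple[str, str], float]

    def get(self, pair_outer: str, pair_inner_reversed: str) -> float:
        key = (pair_outer, pair_inner_reversed)
        if key not in self.table:
            raise KeyError(
                f"no stacking entry for {pair_outer}/{pair_inner_reversed}: "
                "non-canonical pair"
            )
        return self.table[key]

    def stack_energy(self, xi: str, xj: str, xp: str, xq: str) -> float:
        """Energy of pair (xi, xj) with pair (xp, xq) = (x_{i+1}, x_{j-1})
        stacked directly inside it."""
        return self.get(xi + xj, xq + xp)


@dataclass
class NNModelParams:
    """Turner 2004 nearest-neighbor parameter set (subset used here)."""

    stack: StackTable
    hairpin_length: Dict[int, float]
    bulge_length: Dict[int, float]
    internal_length: Dict[int, float]
    mismatch_hairpin: Dict[Tuple[str, str, str], float]
    mismatch_internal: Dict[Tuple[str, str, str], float]
    ml_unpaired: float
    ml_closing: float
    ml_branch: float
    ninio_per_asym: float
    ninio_max_asym: float
    duplex_init: float
    terminal_au: float
    lxc: float
    special_hairpins: Dict[str, float]

    def loop_penalty(self, table: Dict[int, float], size: int) -> float:
        """Length penalty with the standard logarithmic extrapolation
        beyond the tabulated maximum of 30."""
        if size in table:
            return table[size]
        if size > MAX_TABULATED_LOOP:
            return table[MAX_TABULATED_LOOP] + self.lxc * math.log(
                size / MAX_TABULATED_LOOP
            )
        raise KeyError(f"loop size {size} undefined")

    def terminal_penalty(self, pair: str) -> float:
        """AU/UA/GU/UG helix-end penalty; zero for GC/CG closings."""
        return 0.0 if pair in ("GC", "CG") else self.terminal_au


@lru_cache(maxsize=1)
def load_params() -> NNModelParams:
    text = (
        resources.files("cliquefold.energy").joinpath("data/turner2004.txt").read_text()
    )
    sections: Dict[str, list] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = []
            continue
        sections[current].append(line.split())

    stack = {}
    for p1, p2, v in sections["stack"]:
        stack[(p1, p2)] = float(v)

    def length_table(name: str) -> Dict[int, float]:
        return {int(size): float(v) for size, v in sections[name]}

    def mismatch_table(name: str) -> Dict[Tuple[str, str, str], float]:
        return {(p, a, b): float(v) for p, a, b, v in sections[name]}

    scalars = {row[0]: float(row[1]) for row in sections["misc"]}
    ml = {row[0]: float(row[1]) for row in sections["multiloop"]}
    ninio = {row[0]: float(row[1]) for row in sections["ninio"]}

    return NNModelParams(
        stack=StackTable(stack),
        hairpin_length=length_table("hairpin_length"),
        bulge_length=length_table("bulge_length"),
        internal_length=length_table("internal_length"),
        mismatch_hairpin=mismatch_table("mismatch_hairpin"),
        mismatch_internal=mismatch_table("mismatch_internal"),
        ml_unpaired=ml["unpaired"],
        ml_closing=ml["closing"],
        ml_branch=ml["branch"],
        ninio_per_asym=ninio["per_asym"],
        ninio_max_asym=ninio["max_asym"],
        duplex_init=scalars["duplex_init"],
        terminal_au=scalars["terminal_au"],
        lxc=scalars["lxc"],
        special_hairpins={row[0]: float(row[1]) for row in sections["special_hairpins"]},
    )
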