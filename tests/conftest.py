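import re
import subprocess

import pytest

from cliquefold.model import BasePair, Strand, StrandSet


def bp(s1, p1, s2, p2):
    return BasePair((s1, p1), (s2, p2))


@pytest.fixture
def two_strands():
    return StrandSet.from_dict({"A": "GGGAAAACCC", "B": "GGGCCCAAAA"})


@pytest.fixture
def hairpin_strand():
    return StrandSet([Strand("A", "GGGAAAACCC")])


def rnaeval_d0(sequence: str, structure: str) -> float:
    """Independent nearest-neighbor reference: ViennaRNA's RNAeval without
    dangling-end contributions.  Multi-strand inputs join strands with '&'."""
    proc = subprocess.run(
        ["RNAeval", "-d0"],
        input=f"{sequence}\n{structure}\n",
        capture_output=True,
        text=True,
        check=True,
    )
    match = re.search(r"\(\s*(-?\d+\.\d+)\)", proc.stdout)
    assert match, f"unparseable RNAeval output: {proc.stdout!r}"
    return float(match.group(1))
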