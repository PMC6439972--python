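"""File formats: FASTA sequences, dot-bracket structure candidates,
tab-separated interaction candidates, and the ranked complex report.

Conventions
-----------
* Coordinates are 1-based in every file and 0-based in memory; conversion
  happens here and only here.
* Structure candidate files: one candidate per line,
  ``strand_id<TAB>dot_bracket[<TAB>source]``; ``#`` starts a comment.
  Pseudoknots use additional bracket layers ``()``, ``[]``, ``{}``, ``<>``.
* Interaction candidate files: one site per line,
  ``strand1<TAB>strand2<TAB>p1-q1,p2-q2,...[<TAB>source]`` where ``pk``
  indexes strand1 and ``qk`` strand2, both 1-based.
* Complex reports: a human-readable text report plus a machine-readable
  TSV of (rank, energy, pair list); pair lists serialize each pair as
  ``strand:pos-strand:pos`` joined by ``;``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .errors import InputError
from .model import (
    BasePair,
    ComplexPrediction,
    InteractionVertex,
    Strand,
    StrandSet,
    StructureVertex,
)

BRACKET_LAYERS: Sequence[Tuple[str, str]] = (("(", ")"), ("[", "]"), ("{", "}"), ("<", ">"))


def read_fasta(path) -> StrandSet:
    """Read strands from FASTA; the first whitespace-delimited header token
    is the strand id; T is normalized to U and case folded to uppercase."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"sequence file not found: {path}")
    strands: List[Strand] = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        sid = record.id
        if sid in seen:
            raise InputError(f"{path}: duplicate strand id {sid!r}")
        seen.add(sid)
        try:
            strands.append(Strand(sid, str(record.seq)))
        except InputError as e:
            raise InputError(f"{path}: {e}") from None
    if not strands:
        raise InputError(f"{path}: no FASTA records found")
    return StrandSet(strands)


def parse_dotbracket(
    dotbracket: str,
    strand_id: str,
    strands: StrandSet,
    source: str = "",
) -> StructureVertex:
    """Parse one dot-bracket string into an (unscored) structure candidate.

    Each bracket layer is parsed with its own stack; the union of the layers
    is the pair set.  Whether the candidate is pseudoknotted is derived from
    the pairs themselves, not from the number of layers used.
    """
    strand = strands[strand_id]
    if len(dotbracket) != len(strand):
        raise InputError(
            f"structure for strand {strand_id!r} has length {len(dotbracket)}, "
            f"expected {len(strand)}"
        )
    openers = {o: k for k, (o, _) in enumerate(BRACKET_LAYERS)}
    closers = {c: k for k, (_, c) in enumerate(BRACKET_LAYERS)}
    stacks: List[List[int]] = [[] for _ in BRACKET_LAYERS]
    pairs: List[BasePair] = []
    for pos, ch in enumerate(dotbracket):
        if ch == ".":
            continue
        if ch in openers:
            stacks[openers[ch]].append(pos)
        elif ch in closers:
            layer = closers[ch]
            if not stacks[layer]:
                raise InputError(
                    f"strand {strand_id!r}: unbalanced {ch!r} at position {pos + 1}"
                )
            i = stacks[layer].pop()
            pairs.append(BasePair((strand_id, i), (strand_id, pos)))
        else:
            raise InputError(
                f"strand {strand_id!r}: illegal character {ch!r} at position "
                f"{pos + 1}"
            )
    for layer, stack in enumerate(stacks):
        if stack:
            raise InputError(
                f"strand {strand_id!r}: unbalanced "
                f"{BRACKET_LAYERS[layer][0]!r} at position {stack[-1] + 1}"
            )
    try:
        return StructureVertex(strand_id, frozenset(pairs), source=source)
    except InputError as e:
        raise InputError(f"strand {strand_id!r}: {e}") from None


def read_structures(path, strands: StrandSet) -> List[StructureVertex]:
    """Read a structure candidate file (see module docstring for format)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"structure file not found: {path}")
    out: List[StructureVertex] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise InputError(f"{path}:{lineno}: expected 'strand_id dot_bracket'")
        sid, db = fields[0], fields[1]
        source = fields[2] if len(fields) > 2 else ""
        if sid not in strands:
            raise InputError(f"{path}:{lineno}: unknown strand id {sid!r}")
        try:
            out.append(parse_dotbracket(db, sid, strands, source=source))
        except InputError as e:
            raise InputError(f"{path}:{lineno}: {e}") from None
    return out


def parse_interactions(path, strands: StrandSet) -> List[InteractionVertex]:
    """Read an interaction candidate file (1-based pair lists, converted to
    0-based here); crossing pairs within one record are rejected."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"interaction file not found: {path}")
    out: List[InteractionVertex] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise InputError(
                f"{path}:{lineno}: expected 'strand1 strand2 p1-q1,p2-q2,...'"
            )
        s1, s2, pairlist = fields[0], fields[1], fields[2]
        source = fields[3] if len(fields) > 3 else ""
        for sid in (s1, s2):
            if sid not in strands:
                raise InputError(f"{path}:{lineno}: unknown strand id {sid!r}")
        if s1 == s2:
            raise InputError(
                f"{path}:{lineno}: interaction strands must differ (got {s1!r})"
            )
        pairs = []
        for token in pairlist.split(","):
            token = token.strip()
            try:
                p_str, q_str = token.split("-")
                p, q = int(p_str), int(q_str)
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: malformed pair token {token!r}"
                ) from None
            for sid, pos in ((s1, p), (s2, q)):
                if not 1 <= pos <= len(strands[sid]):
                    raise InputError(
                        f"{path}:{lineno}: position {pos} out of range for "
                        f"strand {sid!r} (length {len(strands[sid])})"
                    )
            pairs.append(BasePair((s1, p - 1), (s2, q - 1)))
        try:
            out.append(
                InteractionVertex((s1, s2), frozenset(pairs), source=source)
            )
        except InputError as e:
            raise InputError(f"{path}:{lineno}: {e}") from None
    return out


# ---------------------------------------------------------------------------
# serialization of pair sets and complexes


def format_pairs(pairs: Iterable[BasePair]) -> str:
    """Serialize a pair set as 'sid:pos-sid:pos;...' (1-based, sorted)."""
    items = sorted(p.endpoints for p in pairs)
    return ";".join(
        f"{a_sid}:{a_pos + 1}-{b_sid}:{b_pos + 1}"
        for (a_sid, a_pos), (b_sid, b_pos) in items
    )


def parse_pairs(text: str, strands: StrandSet) -> FrozenSet[BasePair]:
    """Inverse of :func:`format_pairs`."""
    pairs = []
    text = text.strip()
    if not text:
        return frozenset()
    for token in text.split(";"):
        try:
            a, b = token.split("-")
            a_sid, a_pos = a.rsplit(":", 1)
            b_sid, b_pos = b.rsplit(":", 1)
            bp = BasePair((a_sid, int(a_pos) - 1), (b_sid, int(b_pos) - 1))
        except (ValueError, InputError):
            raise InputError(f"malformed pair token {token!r}") from None
        bp.validate(strands)
        pairs.append(bp)
    return frozenset(pairs)


def render_complex_dotbracket(
    pairs: Iterable[BasePair], strands: StrandSet
) -> Optional[str]:
    """Render a complex as '&'-joined dot-bracket over the strand order of
    the StrandSet, assigning each pair greedily to the first bracket layer
    that accepts it without crossing.  Returns None if four layers are not
    enough (caller falls back to the explicit pair list)."""
    offsets: Dict[str, int] = {}
    off = 0
    for s in strands:
        offsets[s.id] = off
        off += len(s)
    arcs = sorted(
        (offsets[p.a[0]] + p.a[1], offsets[p.b[0]] + p.b[1]) for p in pairs
    )
    layer_arcs: List[List[Tuple[int, int]]] = [[] for _ in BRACKET_LAYERS]
    assignment: Dict[Tuple[int, int], int] = {}
    for (i, j) in arcs:
        placed = False
        for layer, existing in enumerate(layer_arcs):
            if all(not (a < i < b < j or i < a < j < b) for (a, b) in existing):
                existing.append((i, j))
                assignment[(i, j)] = layer
                placed = True
                break
        if not placed:
            return None
    chars = ["."] * strands.total_length()
    for (i, j), layer in assignment.items():
        chars[i] = BRACKET_LAYERS[layer][0]
        chars[j] = BRACKET_LAYERS[layer][1]
    parts = []
    for s in strands:
        parts.append("".join(chars[offsets[s.id] : offsets[s.id] + len(s)]))
    return "&".join(parts)


def write_complexes(
    predictions: Sequence[ComplexPrediction],
    strands: StrandSet,
    report_path,
    tsv_path=None,
    graph=None,
) -> None:
    """Write the ranked complex report (and optional machine-readable TSV).

    Predictions must already be sorted by non-decreasing free energy.
    Output is deterministic for a fixed input.
    """
    lines = [
        "# cliquefold ranked RNA complexes",
        "# strands: " + " ".join(f"{s.id}({len(s)}nt)" for s in strands),
    ]
    for pred in predictions:
        lines.append("")
        lines.append(f"complex {pred.rank}")
        lines.append(f"  energy: {pred.energy:.2f} kcal/mol")
        lines.append(f"  base pairs: {len(pred.all_pairs)}")
        if graph is not None:
            for m in sorted(pred.clique.members):
                v = graph.vertex(m)
                kind = (
                    f"structure[{v.strand_id}]"
                    if hasattr(v, "strand_id")
                    else f"interaction[{v.strand_pair[0]}-{v.strand_pair[1]}]"
                )
                tag = f" source={v.source}" if v.source else ""
                lines.append(
                    f"  member v{m}: {kind} pairs={len(v.pairs)} "
                    f"energy={v.energy:.2f}{tag}"
                )
        db = render_complex_dotbracket(pred.all_pairs, strands)
        if db is not None:
            lines.append("  structure: " + db)
        else:
            lines.append(
                "  structure: [needs more than "
                f"{len(BRACKET_LAYERS)} bracket layers; explicit pair list]"
            )
        lines.append("  pairs: " + format_pairs(pred.all_pairs))
    Path(report_path).write_text("\n".join(lines) + "\n")

    if tsv_path is not None:
        rows = ["rank\tenergy\tn_pairs\tpairs"]
        for pred in predictions:
            rows.append(
                f"{pred.rank}\t{pred.energy:.4f}\t{len(pred.all_pairs)}\t"
                + format_pairs(pred.all_pairs)
            )
        Path(tsv_path).write_text("\n".join(rows) + "\n")


def read_complexes_tsv(path, strands: StrandSet) -> List[Tuple[int, float, FrozenSet[BasePair]]]:
    """Read a machine-readable complex TSV back as (rank, energy, pairs)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"complex file not found: {path}")
    out = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("rank\t") or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise InputError(f"{path}:{lineno}: expected 4 tab-separated fields")
        try:
            rank = int(fields[0])
            energy = float(fields[1])
        except ValueError:
            raise InputError(f"{path}:{lineno}: malformed rank/energy") from None
        out.append((rank, energy, parse_pairs(fields[3], strands)))
    return out


def write_fasta(strands: StrandSet, path) -> None:
    lines = []
    for s in strands:
        lines.append(f">{s.id}")
        lines.append(s.sequence)
    Path(path).write_text("\n".join(lines) + "\n")


def write_structures(candidates: Sequence[StructureVertex], strands: StrandSet, path) -> None:
    """Write structure candidates as dot-bracket lines (inverse of
    :func:`read_structures`); pseudoknotted candidates use extra layers."""
    lines = ["# strand_id\tdot_bracket\tsource"]
    for v in candidates:
        sub = StrandSet([strands[v.strand_id]])
        db = render_complex_dotbracket(v.pairs, sub)
        if db is None:
            raise InputError(
                f"structure candidate on {v.strand_id!r} needs more than "
                f"{len(BRACKET_LAYERS)} bracket layers"
            )
        lines.append(f"{v.strand_id}\t{db}" + (f"\t{v.source}" if v.source else ""))
    Path(path).write_text("\n".join(lines) + "\n")


def write_interactions(candidates: Sequence[InteractionVertex], path) -> None:
    """Inverse of :func:`parse_interactions` (writes 1-based pair lists)."""
    lines = ["# strand1\tstrand2\tpairs(1-based)\tsource"]
    for v in candidates:
        s1, s2 = v.strand_pair
        arcs = sorted((dict(p.endpoints)[s1], dict(p.endpoints)[s2]) for p in v.pairs)
        pairlist = ",".join(f"{p + 1}-{q + 1}" for p, q in arcs)
        lines.append(f"{s1}\t{s2}\t{pairlist}" + (f"\t{v.source}" if v.source else ""))
    Path(path).write_text("\n".join(lines) + "\n")
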