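"""REPuter-style detection of long oligonucleotide repeat pairs.

Four kinds are distinguished by how the second copy is transformed before
position-wise comparison with the first:

==============  ==========================================
forward         identical on the same strand
reverse         reversed (no complementation)
complement      complemented (not reversed)
palindromic     reverse complement (inverted repeat)
==============  ==========================================

Identity is Hamming (mismatches only, no gaps). A reported pair is maximal:
it cannot be extended on either side without dropping below the identity
floor. The genome-scale inverted repeat of the quadripartite structure is
itself detected as a palindromic repeat and flagged ``is_genomic_ir`` so
per-genome tallies can exclude it.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._diagonal import find_diagonal_repeats
from .records import PlastomeRecord
from .structure import QuadripartiteStructure
from .util import complement, revcomp

KINDS = ("forward", "reverse", "complement", "palindromic")


@dataclass(frozen=True)
class OligoRepeat:
    kind: str
    length: int
    pos1: int  # 1-based start of the left copy
    pos2: int  # 1-based start of the right copy (pos1 <= pos2)
    identity: float
    mismatches: int
    is_genomic_ir: bool = False


def _transform(seq: str, kind: str) -> str:
    if kind == "forward":
        return seq
    if kind == "reverse":
        return seq[::-1]
    if kind == "complement":
        return complement(seq)
    if kind == "palindromic":
        return revcomp(seq)
    raise ValueError(f"unknown repeat kind {kind!r}")


def _copy2_start(kind: str, j: int, length: int, n: int) -> int:
    """Map a window start in the transformed string back to the + strand."""
    if kind in ("forward", "complement"):
        return j
    return n - j - length  # reversed coordinate systems


def find_oligo_repeats(
    rec: PlastomeRecord | str,
    min_len: int = 30,
    min_identity: float = 0.90,
    kinds: tuple[str, ...] = KINDS,
    structure: QuadripartiteStructure | None = None,
    seed_k: int = 11,
) -> list[OligoRepeat]:
    """All maximal repeat pairs of the requested kinds.

    ``structure``, when given, is used to flag the quadripartite IR
    duplication itself (palindromic, coinciding with IRb/IRa); without it,
    palindromic repeats of >= 10 kb are flagged heuristically.
    """
    seq = rec.sequence if isinstance(rec, PlastomeRecord) else rec.upper()
    n = len(seq)
    if n < 2 * min_len:
        raise ValueError(f"sequence of {n} bp cannot hold two copies of {min_len} bp")
    out: list[OligoRepeat] = []
    for kind in kinds:
        b = _transform(seq, kind)
        seen: set[tuple[int, int, int]] = set()
        for w in find_diagonal_repeats(seq, b, min_len, min_identity, seed_k=seed_k):
            if kind == "forward" and w.j == w.i:
                continue  # trivial self-diagonal
            p2 = _copy2_start(kind, w.j, w.length, n)
            if p2 == w.i:
                continue  # a copy paired with itself
            lo, hi = sorted((w.i, p2))
            key = (lo, hi, w.length)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                OligoRepeat(
                    kind=kind,
                    length=w.length,
                    pos1=lo + 1,
                    pos2=hi + 1,
                    identity=round(w.identity, 4),
                    mismatches=w.mismatches,
                    is_genomic_ir=_flags_ir(kind, lo + 1, hi + 1, w.length, structure),
                )
            )
    out.sort(key=lambda r: (r.pos1, r.pos2, r.kind))
    return out


def _flags_ir(
    kind: str, pos1: int, pos2: int, length: int, structure: QuadripartiteStructure | None
) -> bool:
    if kind != "palindromic":
        return False
    if structure is None:
        return length >= 10_000
    off = structure.origin_offset
    n = structure.genome_length
    # map record coordinates into the normalized frame
    p1 = (pos1 - 1 - off) % n + 1
    p2 = (pos2 - 1 - off) % n + 1
    return _overlaps_most(p1, length, structure.irb, n) and _overlaps_most(
        p2, length, structure.ira, n
    )


def _overlaps_most(start: int, length: int, iv: tuple[int, int], n: int) -> bool:
    end = start + length - 1
    if end > n:  # wraps the origin; treat conservatively as overlap by halves
        return True
    ov = max(0, min(end, iv[1]) - max(start, iv[0]) + 1)
    return ov >= 0.9 * length


def summarize_repeat_kinds(
    repeats: list[OligoRepeat], include_genomic_ir: bool = False
) -> dict[str, int]:
    """Counts per kind, in the order forward/reverse/complement/palindromic."""
    counts = {k: 0 for k in KINDS}
    for r in repeats:
        if r.is_genomic_ir and not include_genomic_ir:
            continue
        counts[r.kind] += 1
    return counts
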