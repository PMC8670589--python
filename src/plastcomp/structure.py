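"""Quadripartite structure detection and region-level statistics.

A plastome circle is tiled as LSC + IRb + SSC + IRa, where IRa is the
reverse complement of IRb (up to a small number of mismatches), LSC is the
longer of the two single-copy arcs, and IRb is the inverted-repeat copy
immediately downstream of the LSC. Detection is automated seed-and-extend
(exact 21-mer seeds between the doubled circle and its reverse complement),
so records in any rotation are handled; all reported coordinates refer to
the rotation-normalized frame in which the LSC starts at base 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._diagonal import find_diagonal_repeats
from .records import PlastomeRecord, rotate_record
from .util import gc_fraction, interval_len, revcomp


class NoIRFoundError(ValueError):
    """No inverted duplication meeting the length/identity thresholds."""


class AmbiguousIRError(ValueError):
    """Multiple non-nested maximal inverted duplications of equal length."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(f"ambiguous IR candidates: {candidates}")


@dataclass(frozen=True)
class QuadripartiteStructure:
    """Region coordinates, 1-based inclusive, in the LSC-first frame.

    ``origin_offset`` is the 0-based rotation that maps the source record
    onto this frame (0 when the record already starts at the LSC).
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    ir_identity: float
    origin_offset: int = 0

    def __post_init__(self):
        if interval_len(self.irb) != interval_len(self.ira):
            raise ValueError("IR copies differ in length")
        if interval_len(self.lsc) <= interval_len(self.ssc):
            raise ValueError("LSC must be longer than SSC")
        expect = self.lsc[1] + 1
        for name, iv in (("irb", self.irb), ("ssc", self.ssc), ("ira", self.ira)):
            if iv[0] != expect:
                raise ValueError(f"regions do not tile: {name} starts at {iv[0]}, expected {expect}")
            expect = iv[1] + 1

    @property
    def genome_length(self) -> int:
        return self.ira[1]

    @property
    def ir_length(self) -> int:
        return interval_len(self.irb)

    def region_of(self, pos: int) -> str:
        """Region name for a 1-based position in the normalized frame."""
        for name, iv in (("LSC", self.lsc), ("IRb", self.irb), ("SSC", self.ssc), ("IRa", self.ira)):
            if iv[0] <= pos <= iv[1]:
                return name
        raise ValueError(f"position {pos} outside genome of length {self.genome_length}")


@dataclass(frozen=True)
class RegionStats:
    lengths: dict[str, int]
    gc: dict[str, float]
    total_length: int
    total_gc: float


@dataclass(frozen=True)
class GeneCensus:
    unique_genes: int
    duplicated_in_ir: int
    total_genes: int
    unique_by_category: dict[str, int] = field(default_factory=dict)


def find_inverted_duplications(seq: str, min_len: int, min_identity: float, seed_k: int = 21):
    """Maximal inverted-duplication pairs on the circular sequence.

    Returns tuples (start1, start2, length, mismatches) with 0-based starts
    on the circle, start1 canonical (pair reported once), copies disjoint.
    """
    n = len(seq)
    doubled = seq + seq
    rc = revcomp(doubled)
    pairs = {}
    for w in find_diagonal_repeats(doubled, rc, min_len=min_len, min_identity=min_identity, seed_k=seed_k):
        if w.length > n:
            continue
        a0 = w.i % n
        b0 = (2 * n - w.j - w.length) % n
        key = tuple(sorted([(a0, w.length), (b0, w.length)]))
        a0, b0 = key[0][0], key[1][0]
        # discard pairs whose copies overlap on the circle
        if _arcs_overlap(a0, b0, w.length, n):
            continue
        prev = pairs.get(key)
        if prev is None or w.mismatches < prev[3]:
            pairs[key] = (a0, b0, w.length, w.mismatches)
    out = sorted(pairs.values(), key=lambda p: (-p[2], p[0]))
    # drop pairs wholly contained in a longer pair (clipped images of the same
    # physical duplication seen through the doubled circle)
    kept = []
    for p in out:
        if not any(_pair_contains(q, p, n) for q in kept):
            kept.append(p)
    return kept


def _arc_contains(outer_start: int, outer_len: int, inner_start: int, inner_len: int, n: int) -> bool:
    rel = (inner_start - outer_start) % n
    return rel + inner_len <= outer_len


def _pair_contains(q, p, n: int) -> bool:
    qa, qb, ql, _ = q
    pa, pb, pl, _ = p
    if pl > ql:
        return False
    return (
        _arc_contains(qa, ql, pa, pl, n) and _arc_contains(qb, ql, pb, pl, n)
    ) or (
        _arc_contains(qa, ql, pb, pl, n) and _arc_contains(qb, ql, pa, pl, n)
    )


def _arcs_overlap(a0: int, b0: int, length: int, n: int) -> bool:
    # arc positions mod n: [a0, a0+length) and [b0, b0+length)
    gap_ab = (b0 - (a0 + length)) % n
    gap_ba = (a0 - (b0 + length)) % n
    return gap_ab + gap_ba + 2 * length != n


def detect_quadripartite(
    rec: PlastomeRecord, min_ir_len: int = 10_000, min_identity: float = 0.99
) -> QuadripartiteStructure:
    """Locate LSC/IRb/SSC/IRa on the circular genome.

    Raises :class:`NoIRFoundError` when no inverted duplication of at least
    ``min_ir_len`` bases at ``min_identity`` exists, and
    :class:`AmbiguousIRError` when several distinct maximal candidates tie.
    """
    n = rec.length
    if n < 2 * min_ir_len:
        raise NoIRFoundError(
            f"genome of {n} bp cannot hold two IR copies of >= {min_ir_len} bp"
        )
    cands = find_inverted_duplications(rec.sequence, min_ir_len, min_identity)
    if not cands:
        raise NoIRFoundError(
            f"no inverted duplication >= {min_ir_len} bp at >= {min_identity:.0%} identity"
        )
    best_len = cands[0][2]
    top = [c for c in cands if c[2] == best_len]
    if len(top) > 1:
        raise AmbiguousIRError(top)
    a0, b0, length, mism = top[0]
    gap_ab = (b0 - (a0 + length)) % n  # arc from end of copy A to start of copy B
    gap_ba = (a0 - (b0 + length)) % n
    if gap_ab >= gap_ba:
        lsc_len, ssc_len = gap_ab, gap_ba
        lsc_start = (a0 + length) % n
    else:
        lsc_len, ssc_len = gap_ba, gap_ab
        lsc_start = (b0 + length) % n
    return QuadripartiteStructure(
        lsc=(1, lsc_len),
        irb=(lsc_len + 1, lsc_len + length),
        ssc=(lsc_len + length + 1, lsc_len + length + ssc_len),
        ira=(lsc_len + length + ssc_len + 1, n),
        ir_identity=1.0 - mism / length,
        origin_offset=lsc_start,
    )


def detect_and_normalize(
    rec: PlastomeRecord, min_ir_len: int = 10_000, min_identity: float = 0.99
) -> tuple[PlastomeRecord, QuadripartiteStructure]:
    """Detect the structure and rotate the record so the LSC starts at base 1."""
    structure = detect_quadripartite(rec, min_ir_len, min_identity)
    if structure.origin_offset:
        rec = rotate_record(rec, structure.origin_offset)
        structure = QuadripartiteStructure(
            lsc=structure.lsc,
            irb=structure.irb,
            ssc=structure.ssc,
            ira=structure.ira,
            ir_identity=structure.ir_identity,
            origin_offset=0,
        )
    return rec, structure


def _normalized_sequence(rec: PlastomeRecord, structure: QuadripartiteStructure) -> str:
    if structure.genome_length != rec.length:
        raise ValueError("structure does not match record length")
    off = structure.origin_offset
    return rec.sequence[off:] + rec.sequence[:off] if off else rec.sequence


def region_stats(rec: PlastomeRecord, structure: QuadripartiteStructure) -> RegionStats:
    """Per-region lengths and GC fractions (N excluded from GC entirely)."""
    seq = _normalized_sequence(rec, structure)
    lengths, gc = {}, {}
    for name, iv in (("LSC", structure.lsc), ("IRb", structure.irb), ("SSC", structure.ssc), ("IRa", structure.ira)):
        sub = seq[iv[0] - 1 : iv[1]]
        lengths[name] = len(sub)
        gc[name] = gc_fraction(sub)
    return RegionStats(
        lengths=lengths, gc=gc, total_length=len(seq), total_gc=gc_fraction(seq)
    )


def gene_census(rec: PlastomeRecord, structure: QuadripartiteStructure) -> GeneCensus:
    """Count unique genes and IR-duplicated copies.

    A name counts as IR-duplicated when annotations sharing it lie (by
    midpoint) in the two different IR copies; such groups contribute one
    unique gene plus (k-1) duplicated copies.
    """
    off = structure.origin_offset
    n = rec.length
    groups: dict[str, list] = {}
    for ann in rec.annotations:
        if "pseudogene" in ann.notes:  # IR-truncated fragments are not loci
            continue
        groups.setdefault(ann.name, []).append(ann)
    unique = 0
    duplicated = 0
    by_cat: dict[str, int] = {}
    for name, anns in sorted(groups.items()):
        unique += 1
        cat = anns[0].category
        by_cat[cat] = by_cat.get(cat, 0) + 1
        regions = set()
        for ann in anns:
            mid = int(ann.midpoint)
            mid_norm = (mid - 1 - off) % n + 1
            regions.add(structure.region_of(mid_norm))
        if len(anns) >= 2 and {"IRb", "IRa"} <= regions:
            duplicated += len(anns) - 1
            if len(anns) > 2:
                warnings.warn(
                    f"gene {name!r} annotated {len(anns)} times; counted once unique "
                    f"+ {len(anns) - 1} duplicated"
                )
        elif len(anns) >= 2:
            warnings.warn(
                f"gene {name!r} annotated {len(anns)} times outside an IR pair; "
                "collapsed to one unique locus"
            )
    return GeneCensus(
        unique_genes=unique,
        duplicated_in_ir=duplicated,
        total_genes=unique + duplicated,
        unique_by_category=by_cat,
    )
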