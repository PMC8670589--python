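"""Gene context at the four single-copy / inverted-repeat junctions.

Junction names follow the standard plastome convention:

=====  =============================
JLB    LSC - IRb boundary
JSB    IRb - SSC boundary
JSA    SSC - IRa boundary
JLA    IRa - LSC boundary (wraps the circle back to base 1)
=====  =============================

For each junction the report gives the gene spanning it (with the number of
bases on each region side) or the nearest gene on each side with its
distance, measured in bases strictly between the junction boundary and the
gene (a gene ending exactly at the junction has distance 0). IR-truncated
gene fragments (name shared with a junction-spanning gene on the opposite
IR copy) are labelled pseudogene fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import GeneAnnotation, PlastomeRecord
from .structure import QuadripartiteStructure

JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")


@dataclass(frozen=True)
class JunctionEntry:
    junction: str
    gene: str  # "none" when no annotation within the search window
    relation: str  # spans | upstream | downstream | none
    side_a_bp: int | None  # spanning: bases on the upstream-region side; else distance
    side_b_bp: int | None  # spanning: bases on the downstream-region side
    pseudogene: bool = False


def _junction_positions(structure: QuadripartiteStructure) -> dict[str, int]:
    """Last base of the upstream region at each junction (normalized frame)."""
    return {
        "JLB": structure.lsc[1],
        "JSB": structure.irb[1],
        "JSA": structure.ssc[1],
        "JLA": structure.ira[1],  # == genome length; next base is 1 (circular)
    }


def junction_report(
    rec: PlastomeRecord,
    structure: QuadripartiteStructure,
    window: int = 2000,
) -> list[JunctionEntry]:
    """Junction context entries; spanning genes yield one entry, otherwise the
    nearest gene on each side (within ``window`` bp) yields one entry per side."""
    if structure.origin_offset:
        raise ValueError("junction_report expects a rotation-normalized record/structure")
    n = structure.genome_length
    genes = sorted(rec.annotations, key=lambda a: a.start)
    spanners: dict[str, str] = {}
    entries: list[JunctionEntry] = []
    jpos = _junction_positions(structure)
    for junction in JUNCTIONS:
        b = jpos[junction]  # boundary between base b and base b+1 (mod n)
        nxt = b % n + 1
        if junction == "JLA":
            spanning = []  # annotations are stored linearly; none wraps the origin
        else:
            spanning = [g for g in genes if g.start <= b and g.end >= nxt]
        if spanning:
            g = max(spanning, key=lambda g: g.length)
            entries.append(
                JunctionEntry(
                    junction=junction,
                    gene=g.name,
                    relation="spans",
                    side_a_bp=b - g.start + 1,
                    side_b_bp=g.end - b,
                )
            )
            spanners[junction] = g.name
            continue
        upstream = [g for g in genes if g.end <= b]
        downstream = [g for g in genes if g.start >= nxt]
        if junction == "JLA":
            # downstream of JLA is the start of the LSC (positions 1, 2, ...)
            downstream = [g for g in genes if g.start >= 1 and g.end <= structure.lsc[1]]
            up = max(upstream, key=lambda g: g.end) if upstream else None
            down = min(downstream, key=lambda g: g.start) if downstream else None
            sides = [
                ("upstream", up, (b - up.end) if up else None),
                ("downstream", down, (down.start - 1) if down else None),
            ]
        else:
            up = max(upstream, key=lambda g: g.end) if upstream else None
            down = min(downstream, key=lambda g: g.start) if downstream else None
            sides = [
                ("upstream", up, (b - up.end) if up else None),
                ("downstream", down, (down.start - nxt) if down else None),
            ]
        emitted = False
        for relation, g, dist in sides:
            if g is not None and dist is not None and dist <= window:
                entries.append(
                    JunctionEntry(
                        junction=junction,
                        gene=g.name,
                        relation=relation,
                        side_a_bp=dist,
                        side_b_bp=None,
                    )
                )
                emitted = True
        if not emitted:
            entries.append(
                JunctionEntry(junction=junction, gene="none", relation="none", side_a_bp=None, side_b_bp=None)
            )
    # mark IR-truncated fragments: a non-spanning entry whose gene name matches
    # a gene spanning the mirrored junction on the other IR copy
    mirror = {"JSB": "JSA", "JSA": "JSB", "JLB": "JLA", "JLA": "JLB"}
    out = []
    for e in entries:
        pseudo = (
            e.relation in ("upstream", "downstream")
            and spanners.get(mirror[e.junction]) == e.gene
        )
        out.append(
            JunctionEntry(
                junction=e.junction,
                gene=e.gene,
                relation=e.relation,
                side_a_bp=e.side_a_bp,
                side_b_bp=e.side_b_bp,
                pseudogene=pseudo,
            )
        )
    return out
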