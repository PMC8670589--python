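"""Synthetic quadripartite plastomes with ground-truth logs.

The generator emits circular genomes laid out as LSC + IRb + SSC + IRa
(IRa the exact reverse complement of IRb) at configurable region sizes and
GC content, with a gene catalog (protein-coding ORFs, tRNA, rRNA; a subset
duplicated across the IR copies), planted microsatellites, planted
oligonucleotide repeat pairs, and genes placed at controlled offsets from
the region junctions. Every planted feature and every divergence event is
logged, so each analysis stage can be tested closed-loop against known
truth without external data.

Defaults emulate the scale of real Calycanthaceae plastomes (~153 kb,
LSC ~87 kb / SSC ~20 kb / IR ~23 kb, GC ~0.38, 113 unique genes of which
15 are IR-duplicated) and genus-level divergence (a few hundred
substitutions per genome pair, Ts:Tv ~1.5, ~10x fewer InDels of geometric
length, mean 4 bp, capped at 50 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import IndelEvent, SubstitutionEvent
from .records import GeneAnnotation, PlastomeRecord
from .repeats import OligoRepeat
from .ssr import DEFAULT_THRESHOLDS, SSRLocus, find_ssrs
from .selection import CODON_TO_AA, STOP_CODONS
from .util import revcomp

BASES = "ACGT"


@dataclass(frozen=True)
class GeneCatalogSpec:
    n_protein_coding: int = 79
    n_trna: int = 30
    n_rrna: int = 4
    # IR-duplicated uniques, by category (placed in IRb, mirrored into IRa)
    ir_protein_coding: int = 4
    ir_trna: int = 7
    ir_rrna: int = 4
    protein_len_range: tuple[int, int] = (300, 1500)  # codindg length, rounded to codons
    trna_len: int = 75
    rrna_len_range: tuple[int, int] = (1500, 2900)


@dataclass(frozen=True)
class PlantedSSRSpec:
    motif: str
    copies: int
    region: str  # LSC | SSC | IRb
    count: int = 1


@dataclass(frozen=True)
class PlantedRepeatSpec:
    kind: str  # forward | reverse | complement | palindromic
    length: int = 40
    mismatches: int = 0
    region: str = "LSC"
    count: int = 1


@dataclass(frozen=True)
class JunctionGeneSpec:
    """A gene at a controlled offset from a junction.

    relation 'spans' places the gene across the junction with ``ir_side``
    bases on the IR side; 'upstream'/'downstream' place it wholly on one
    side with ``distance`` bases strictly between gene and junction.
    """

    name: str
    junction: str  # JLB | JSB | JSA | JLA
    relation: str  # spans | upstream | downstream
    length: int = 300
    distance: int = 0
    ir_side: int = 0
    category: str = "protein_coding"
    strand: str = "+"


@dataclass(frozen=True)
class DivergenceSpec:
    substitution_rate: float = 0.002  # per bp
    ts_tv: float = 1.5
    indel_rate: float = 0.0002  # events per bp
    indel_mean_len: float = 4.0
    indel_max_len: int = 50
    n_substitutions: int | None = None  # exact counts override the rates
    n_indels: int | None = None
    # minimum separation between an InDel and any other event; keeps the
    # event decomposition of the derived/ancestor pair unambiguous so the
    # truth log is exactly recoverable by alignment (0 disables)
    guard_gap: int = 10
    preserve_ir: bool = False  # restrict events to the single-copy regions
    avoid_cds_stops: bool = True  # resample substitutions that would create stops
    indels_avoid_cds: bool = True
    # optional shared mutation-rate landscape: gamma-distributed multiplier per
    # window, applied to substitution and InDel intensities alike (mutation
    # hotspots); shape None disables it
    hotspot_gamma_shape: float | None = None
    hotspot_window: int = 1000


@dataclass(frozen=True)
class GeneratorConfig:
    lsc_len: int = 87_000
    ssc_len: int = 20_000
    ir_len: int = 23_000
    gc: float = 0.38
    seed: int = 0
    genes: GeneCatalogSpec = field(default_factory=GeneCatalogSpec)
    ssrs: tuple[PlantedSSRSpec, ...] = ()
    repeats: tuple[PlantedRepeatSpec, ...] = ()
    junction_genes: tuple[JunctionGeneSpec, ...] = ()
    scrub_background_ssrs: bool = True
    record_id: str = "synthetic"

    def __post_init__(self):
        for name, v in (("lsc_len", self.lsc_len), ("ssc_len", self.ssc_len), ("ir_len", self.ir_len)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.lsc_len <= self.ssc_len:
            raise ValueError("lsc_len must exceed ssc_len")


@dataclass
class TruthLog:
    config: GeneratorConfig | None = None
    ssrs: list[SSRLocus] = field(default_factory=list)
    repeats: list[OligoRepeat] = field(default_factory=list)
    gene_layout: list[GeneAnnotation] = field(default_factory=list)
    junction_offsets: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    substitutions: list[SubstitutionEvent] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)


class PlantingError(ValueError):
    """Planting demands exceed region capacity."""


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    lut = np.array(list("ACGT"))
    return list(lut[idx])


def _random_orf(rng: np.random.Generator, coding_len: int) -> str:
    """In-frame ORF: ATG + non-stop codons + TAA, total length coding_len."""
    n_codons = max(coding_len // 3, 3)
    body = []
    while len(body) < n_codons - 2:
        codon = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if codon not in STOP_CODONS and codon != "ATG":
            body.append(codon)
    return "ATG" + "".join(body) + "TAA"


class _RegionAllocator:
    """Tracks free intervals (1-based inclusive, genome coordinates) per region."""

    def __init__(self, regions: dict[str, tuple[int, int]], margin: int = 25):
        self.free: dict[str, list[tuple[int, int]]] = {
            name: [iv] for name, iv in regions.items()
        }
        self.margin = margin

    def take(self, region: str, length: int, rng: np.random.Generator,
             at: int | None = None) -> int:
        """Claim ``length`` bases in ``region``; returns the 1-based start.
        ``at`` pins an exact start position."""
        slots = self.free.get(region, [])
        if at is not None:
            for idx, (s, e) in enumerate(slots):
                if s <= at and at + length - 1 <= e:
                    self._split(region, idx, at, at + length - 1)
                    return at
            raise PlantingError(f"cannot place feature at {at} (+{length}) in {region}")
        m = self.margin
        candidates = [
            (idx, s, e) for idx, (s, e) in enumerate(slots) if e - s + 1 >= length + 2 * m
        ]
        if not candidates:
            raise PlantingError(
                f"no free slot of {length} bp left in {region}"
            )
        idx, s, e = candidates[int(rng.integers(0, len(candidates)))]
        start = int(rng.integers(s + m, e - m - length + 2))
        self._split(region, idx, start, start + length - 1)
        return start

    def _split(self, region: str, idx: int, s: int, e: int) -> None:
        fs, fe = self.free[region][idx]
        new = []
        if s - 1 >= fs:
            new.append((fs, s - 1))
        if e + 1 <= fe:
            new.append((e + 1, fe))
        self.free[region][idx : idx + 1] = new


def _mirror_interval(iv: tuple[int, int], src: tuple[int, int], dst: tuple[int, int]) -> tuple[int, int]:
    """Map an interval in one IR copy onto the other (positions reverse)."""
    s, e = iv
    return (dst[0] + (src[1] - e), dst[0] + (src[1] - s))


def generate_plastome(config: GeneratorConfig) -> tuple[PlastomeRecord, TruthLog]:
    """Build a synthetic plastome and its truth log. Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    L, I, S = config.lsc_len, config.ir_len, config.ssc_len
    n = L + 2 * I + S
    lsc = (1, L)
    irb = (L + 1, L + I)
    ssc = (L + I + 1, L + I + S)
    ira = (L + I + S + 1, n)

    seq = _random_bases(rng, L + I + S, config.gc)  # LSC + IRb + SSC; IRa derived
    seq.extend(["?"] * I)  # placeholder, filled at the end

    alloc = _RegionAllocator({"LSC": lsc, "IRb": irb, "SSC": ssc})
    truth = TruthLog(config=config)
    annotations: list[GeneAnnotation] = []

    def write(start: int, payload: str) -> None:
        seq[start - 1 : start - 1 + len(payload)] = list(payload)

    # --- junction-pinned genes first (they need exact coordinates) ---------
    jpos = {"JLB": lsc[1], "JSB": irb[1], "JSA": ssc[1], "JLA": ira[1]}
    for jg in config.junction_genes:
        start, end = _junction_gene_interval(jg, jpos, n)
        payload_len = end - start + 1
        regions_touched = _regions_for_interval((start, end), lsc, irb, ssc, ira)
        ir_part = None
        if "IRa" in regions_touched and len(regions_touched) == 1:
            # wholly inside IRa: realized via the IRb mirror at the end
            ir_part = (start, end)
        body = (
            _random_orf(rng, payload_len)
            if jg.category == "protein_coding"
            else "".join(_random_bases(rng, payload_len, config.gc))
        )
        body = body[:payload_len]
        if jg.strand == "-":
            body = revcomp(body)
        del ir_part
        if "IRa" not in regions_touched:
            _claim_span(alloc, (start, end), lsc, irb, ssc)
            write(start, body)
        else:
            # write any pre-IRa part directly; the IRa part via the IRb mirror
            split = ssc[1]  # JSA boundary: IRa begins at split + 1
            if start <= split:
                _claim_span(alloc, (start, split), lsc, irb, ssc)
                write(start, body[: split - start + 1])
            ira_piece = (max(start, ira[0]), end)
            mirror_iv = _mirror_interval(ira_piece, ira, irb)
            piece = body[len(body) - (ira_piece[1] - ira_piece[0] + 1) :]
            _claim_span(alloc, mirror_iv, lsc, irb, ssc)
            write(mirror_iv[0], revcomp(piece))
        ann = GeneAnnotation(
            name=jg.name, category=jg.category, strand=jg.strand,
            exons=((start, end),), notes=f"junction:{jg.junction}",
        )
        annotations.append(ann)
        truth.junction_offsets[jg.name] = (jg.junction, jg.relation,
                                           jg.ir_side if jg.relation == "spans" else jg.distance)
        if jg.relation == "spans" and jg.ir_side > 0:
            # truncated (pseudogene) copy arises on the opposite IR copy
            if "IRa" in regions_touched:
                frag = _mirror_interval((ira[0], ira[0] + jg.ir_side - 1), ira, irb)
            else:
                frag = _mirror_interval((irb[1] - jg.ir_side + 1, irb[1]), irb, ira)
            annotations.append(
                GeneAnnotation(
                    name=jg.name, category=jg.category,
                    strand="+" if jg.strand == "-" else "-",
                    exons=(frag,), notes="pseudogene fragment (IR truncation)",
                )
            )

    # --- gene catalog ------------------------------------------------------
    g = config.genes
    catalog = (
        [("protein_coding", True)] * g.ir_protein_coding
        + [("tRNA", True)] * g.ir_trna
        + [("rRNA", True)] * g.ir_rrna
        + [("protein_coding", False)]
        * max(0, g.n_protein_coding - g.ir_protein_coding - _n_junction(config, "protein_coding"))
        + [("tRNA", False)] * max(0, g.n_trna - g.ir_trna - _n_junction(config, "tRNA"))
        + [("rRNA", False)] * max(0, g.n_rrna - g.ir_rrna - _n_junction(config, "rRNA"))
    )
    counters = {"protein_coding": 0, "tRNA": 0, "rRNA": 0}
    prefix = {"protein_coding": "pcg", "tRNA": "trn", "rRNA": "rrn"}
    for category, in_ir in catalog:
        counters[category] += 1
        name = f"{prefix[category]}{counters[category]:03d}"
        if category == "protein_coding":
            lo, hi = g.protein_len_range
            length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        elif category == "tRNA":
            length = g.trna_len
        else:
            lo, hi = g.rrna_len_range
            length = int(rng.integers(lo, hi + 1))
        region = "IRb" if in_ir else ("LSC" if rng.random() < L / (L + S) else "SSC")
        strand = "+" if rng.random() < 0.5 else "-"
        try:
            start = alloc.take(region, length, rng)
        except PlantingError:
            if in_ir:
                raise
            region = "SSC" if region == "LSC" else "LSC"  # other SC region
            start = alloc.take(region, length, rng)
        body = _random_orf(rng, length)[:length] if category == "protein_coding" else "".join(
            _random_bases(rng, length, config.gc)
        )
        if strand == "-":
            body = revcomp(body)
        write(start, body)
        ann = GeneAnnotation(name=name, category=category, strand=strand,
                             exons=((start, start + length - 1),))
        annotations.append(ann)
        if in_ir:
            mirror = _mirror_interval((start, start + length - 1), irb, ira)
            annotations.append(
                GeneAnnotation(name=name, category=category,
                               strand="+" if strand == "-" else "-", exons=(mirror,))
            )

    # --- assemble IRa and optionally scrub accidental background SSRs ------
    def finalize() -> str:
        # pin the junction-adjacent columns so the planted IR pair is exactly
        # maximal: a chance match there would legitimately extend the palindrome
        occupied_pos = {p for a in annotations for s, e in a.exons for p in (s, e)}

        def pin(p_fix: int, p_ref: int) -> None:
            if p_fix in occupied_pos or seq[p_fix - 1] == "?":
                return
            bad = _COMP1.get(seq[p_ref - 1])
            if bad and seq[p_fix - 1] == bad:
                seq[p_fix - 1] = next(b for b in BASES if b != bad and b != seq[p_fix - 1])

        pin(ssc[1], ssc[0])   # inner columns (IRb end+1 vs IRa start-1)
        pin(lsc[1], lsc[0])   # outer columns across the origin
        irb_seq = "".join(seq[irb[0] - 1 : irb[1]])
        seq[ira[0] - 1 : ira[1]] = list(revcomp(irb_seq))
        return "".join(seq)

    if config.scrub_background_ssrs:
        _scrub_ssrs(seq, ssc[1], annotations, rng)

    # --- planted SSRs -------------------------------------------------------
    for spec in config.ssrs:
        for _ in range(spec.count):
            locus = _plant_ssr(seq, spec, alloc, rng)
            truth.ssrs.append(locus)

    # --- planted oligonucleotide repeats ------------------------------------
    for spec in config.repeats:
        for _ in range(spec.count):
            truth.repeats.append(_plant_repeat(seq, spec, alloc, rng, config.gc))

    full = finalize()
    annotations.sort(key=lambda a: a.start)
    truth.gene_layout = list(annotations)
    rec = PlastomeRecord(
        id=config.record_id, sequence=full, annotations=annotations, source="synthetic"
    )
    return rec, truth


def _n_junction(config: GeneratorConfig, category: str) -> int:
    return sum(1 for jg in config.junction_genes if jg.category == category)


def _junction_gene_interval(jg: JunctionGeneSpec, jpos: dict[str, int], n: int) -> tuple[int, int]:
    b = jpos[jg.junction]
    if jg.relation == "spans":
        if not 0 < jg.ir_side < jg.length:
            raise ValueError(f"{jg.name}: ir_side must lie strictly inside the gene")
        if jg.junction == "JSA":  # gene runs from SSC into IRa
            start = b - (jg.length - jg.ir_side) + 1
            return start, start + jg.length - 1
        if jg.junction == "JLB":  # gene starts inside IRb, extends back into LSC
            start = b - (jg.length - jg.ir_side) + 1
            return start, start + jg.length - 1
        raise ValueError(f"{jg.name}: spanning placement supported at JSA/JLB only")
    if jg.relation == "upstream":  # gene before the junction, distance bases between
        end = b - jg.distance
        return end - jg.length + 1, end
    if jg.relation == "downstream":
        if jg.junction == "JLA":  # downstream of JLA is LSC base 1
            start = 1 + jg.distance
        else:
            start = b + 1 + jg.distance
        return start, start + jg.length - 1
    raise ValueError(f"unknown relation {jg.relation!r}")


def _regions_for_interval(iv, lsc, irb, ssc, ira) -> set[str]:
    out = set()
    for name, region in (("LSC", lsc), ("IRb", irb), ("SSC", ssc), ("IRa", ira)):
        if iv[0] <= region[1] and iv[1] >= region[0]:
            out.add(name)
    return out


def _claim_span(alloc: _RegionAllocator, iv: tuple[int, int], lsc, irb, ssc) -> None:
    for name, region in (("LSC", lsc), ("IRb", irb), ("SSC", ssc)):
        s = max(iv[0], region[0])
        e = min(iv[1], region[1])
        if s <= e:
            alloc.take(name, e - s + 1, np.random.default_rng(0), at=s)


def _scrub_ssrs(seq: list[str], upto: int, annotations, rng: np.random.Generator,
                max_rounds: int = 6) -> None:
    """Break accidental microsatellites in the assembled LSC+IRb+SSC portion
    (IRa is a mirror of IRb and needs no separate pass)."""
    cds_positions = _cds_frames(annotations)
    for _ in range(max_rounds):
        probe = PlastomeRecord(id="probe", sequence="".join(seq[:upto]))
        loci = find_ssrs(probe)
        if not loci:
            break
        hit = False
        for locus in loci:
            mid = (locus.start + locus.end) // 2
            if _break_position(seq, mid, cds_positions, rng):
                hit = True
        if not hit:
            break


def _cds_frames(annotations) -> dict[int, tuple[str, int, str]]:
    """Map genome position -> (codon-so-far context) for stop avoidance.
    Values: (strand, index within spliced CDS, gene name)."""
    out: dict[int, tuple[str, int, str]] = {}
    for ann in annotations:
        if ann.category != "protein_coding" or "pseudogene" in ann.notes:
            continue
        spliced: list[int] = []
        for s, e in sorted(ann.exons):
            spliced.extend(range(s, e + 1))
        if ann.strand == "-":
            spliced.reverse()
        for idx, pos in enumerate(spliced):
            out[pos] = (ann.strand, idx, ann.name)
    return out


_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _codon_at(seq: list[str], pos: int, cds: dict[int, tuple[str, int, str]]) -> tuple[list[int], str, int] | None:
    """Genome positions, coding-strand codon and within-codon offset for pos."""
    info = cds.get(pos)
    if info is None:
        return None
    strand, idx, _ = info
    off = idx % 3
    step = 1 if strand == "+" else -1
    first = pos - off * step
    positions = [first, first + step, first + 2 * step]
    codon = "".join(
        seq[p - 1] if strand == "+" else _COMP1.get(seq[p - 1], "N") for p in positions
    )
    return positions, codon, off


def _break_position(seq: list[str], pos: int, cds, rng: np.random.Generator) -> bool:
    cur = seq[pos - 1]
    if cur not in _COMP1:
        return False
    options = [b for b in BASES if b != cur]
    rng.shuffle(options)
    ctx = _codon_at(seq, pos, cds)
    for b in options:
        if ctx is None:
            seq[pos - 1] = b
            return True
        positions, codon, off = ctx
        strand = "+" if positions[1] > positions[0] else "-"
        nb = b if strand == "+" else _COMP1[b]
        new_codon = codon[:off] + nb + codon[off + 1 :]
        if new_codon not in STOP_CODONS and codon[:1] != "?" and CODON_TO_AA.get(new_codon):
            seq[pos - 1] = b
            return True
    return False


def _plant_ssr(seq: list[str], spec: PlantedSSRSpec, alloc: _RegionAllocator,
               rng: np.random.Generator) -> SSRLocus:
    u = len(spec.motif)
    if not 1 <= u <= 6:
        raise ValueError("SSR motif unit length must be 1-6")
    if spec.copies < DEFAULT_THRESHOLDS[u]:
        raise ValueError(
            f"planted SSR {spec.motif}x{spec.copies} below the detection threshold"
        )
    run = spec.motif * spec.copies
    total = len(run) + 2  # one breaking flank base each side
    start = alloc.take(spec.region, total, rng) + 1
    seq[start - 2 : start - 2 + total] = list("?" + run + "?")
    # left flank must break period-u continuation: differs from run[u-1] ... the
    # base u positions to its right; right flank differs from the base u to its left
    left_bad = {run[u - 1], "N"}
    right_bad = {run[-u], "N"}
    seq[start - 2] = next(b for b in BASES if b not in left_bad)
    seq[start + len(run) - 1] = next(b for b in BASES if b not in right_bad)
    return SSRLocus(
        motif=spec.motif, unit_length=u, copies=spec.copies,
        start=start, end=start + len(run) - 1, region=spec.region,
        context="non-coding",
    )


def _plant_repeat(seq: list[str], spec: PlantedRepeatSpec, alloc: _RegionAllocator,
                  rng: np.random.Generator, gc: float) -> OligoRepeat:
    from .repeats import _transform  # shared kind semantics

    L = spec.length
    core = "".join(_random_bases(rng, L, gc))
    copy2 = _transform(core, spec.kind)
    mism_pos = sorted(rng.choice(np.arange(1, L - 1), size=spec.mismatches, replace=False)) if spec.mismatches else []
    copy2 = list(copy2)
    for p in mism_pos:
        copy2[p] = next(b for b in BASES if b != copy2[p] and b != core[p])
    copy2 = "".join(copy2)
    s1 = alloc.take(spec.region, L + 2, rng) + 1
    s2 = alloc.take(spec.region, L + 2, rng) + 1
    for start, body in ((s1, core), (s2, copy2)):
        seq[start - 1 : start - 1 + L] = list(body)
    _mismatch_flanks(seq, s1, s2, L, spec.kind)
    lo, hi = sorted((s1, s2))
    ident = 1 - spec.mismatches / L
    return OligoRepeat(kind=spec.kind, length=L, pos1=lo, pos2=hi,
                       identity=round(ident, 4), mismatches=spec.mismatches)


def _mismatch_flanks(seq: list[str], s1: int, s2: int, L: int, kind: str) -> None:
    """Force the columns just outside the planted windows to mismatch so the
    detector cannot extend a planted repeat for free."""
    # pairs of (flank of copy1, corresponding partner position in copy2 frame)
    if kind in ("forward", "complement"):
        partners = [((s1 - 1), (s2 - 1)), ((s1 + L), (s2 + L))]
    else:  # reversed coordinate sense
        partners = [((s1 - 1), (s2 + L)), ((s1 + L), (s2 - 1))]
    for p1, p2 in partners:
        if p1 < 1 or p2 < 1 or p1 > len(seq) or p2 > len(seq):
            continue
        b1 = seq[p1 - 1]
        if b1 not in _COMP1:
            b1 = "A"
            seq[p1 - 1] = b1
        # choose the partner base so the transformed column mismatches
        if kind == "forward":
            forbidden = {b1}
        elif kind == "reverse":
            forbidden = {b1}
        elif kind == "complement":
            forbidden = {_COMP1[b1]}
        else:  # palindromic
            forbidden = {_COMP1[b1]}
        cur = seq[p2 - 1]
        if cur in forbidden or cur not in _COMP1:
            seq[p2 - 1] = next(b for b in BASES if b not in forbidden)


# --------------------------------------------------------------------------
# divergence
# --------------------------------------------------------------------------


def diverge(
    rec: PlastomeRecord,
    spec: DivergenceSpec,
    seed: int,
    structure_regions: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> tuple[PlastomeRecord, TruthLog]:
    """Apply substitutions and InDels to a record, logging every event in
    ancestor coordinates.

    ``structure_regions`` (lsc, ssc intervals) is only needed when
    ``preserve_ir`` restricts events to the single-copy regions.
    """
    rng = np.random.default_rng(seed)
    seq = list(rec.sequence)
    n = len(seq)
    allowed = np.ones(n + 1, dtype=bool)  # index by 1-based position
    allowed[0] = False
    if spec.preserve_ir:
        if structure_regions is None:
            raise ValueError("preserve_ir requires structure_regions=(lsc, ssc)")
        allowed[:] = False
        for s, e in structure_regions:
            allowed[s : e + 1] = True

    weights = np.ones(n + 1, dtype=float)
    if spec.hotspot_gamma_shape is not None:
        k = spec.hotspot_gamma_shape
        n_windows = (n + spec.hotspot_window - 1) // spec.hotspot_window
        mult = rng.gamma(k, 1.0 / k, size=n_windows)
        weights[1:] = np.repeat(mult, spec.hotspot_window)[:n]
    weights[~allowed] = 0.0

    cds = _cds_frames(rec.annotations)
    truth = TruthLog()

    # --- substitutions ------------------------------------------------------
    if spec.n_substitutions is not None:
        n_sub = spec.n_substitutions
    else:
        n_sub = rng.binomial(int(allowed.sum()) - 1, spec.substitution_rate)
    probs = weights / weights.sum()
    sub_pos = rng.choice(np.arange(n + 1), size=min(n_sub, n), replace=False, p=probs)
    p_ts = spec.ts_tv / (1.0 + spec.ts_tv)
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    occupied = np.zeros(n + 2, dtype=bool)
    for pos in sorted(int(p) for p in sub_pos):
        ref = seq[pos - 1]
        if ref not in _COMP1:
            continue
        if rng.random() < p_ts:
            alt = transition[ref]
        else:
            alt = transversions[ref][int(rng.integers(0, 2))]
        if spec.avoid_cds_stops and pos in cds:
            alt2 = _stop_safe_alt(seq, pos, alt, ref, cds, p_ts, rng)
            if alt2 is None:
                continue
            alt = alt2
        seq[pos - 1] = alt
        occupied[pos] = True
        truth.substitutions.append(SubstitutionEvent(ref_pos=pos, ref_base=ref, qry_base=alt))

    # --- InDels -------------------------------------------------------------
    if spec.n_indels is not None:
        n_ind = spec.n_indels
    else:
        n_ind = rng.binomial(int(allowed.sum()) - 1, spec.indel_rate)
    indels: list[IndelEvent] = []
    attempts = 0
    while len(indels) < n_ind and attempts < 50 * max(n_ind, 1):
        attempts += 1
        pos = int(rng.choice(np.arange(n + 1), p=probs))
        length = min(int(rng.geometric(1.0 / spec.indel_mean_len)), spec.indel_max_len)
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        end = pos + length if kind == "deletion" else pos + 1
        if end > n:
            continue
        # guard gap: an InDel flanked too closely by another event admits
        # several equal-score event decompositions, making truth ill-defined
        g = spec.guard_gap
        guard = range(max(pos - g, 1), min(end + g, n) + 1)
        span = range(pos, end + 1)
        if any(occupied[p] for p in guard) or not all(allowed[p] for p in span):
            continue
        if spec.indels_avoid_cds and any((pos + d) in cds for d in range(-1, length + 2)):
            continue
        for p in span:
            occupied[p] = True
        indels.append(IndelEvent(ref_pos=pos, length=length, kind=kind))
    indels.sort(key=lambda e: e.ref_pos)
    truth.indels = indels

    ins_payload_raw = {
        e.ref_pos: "".join(BASES[i] for i in rng.integers(0, 4, size=e.length))
        for e in indels
        if e.kind == "insertion"
    }
    # log left-shift-canonical coordinates (the aligner normalizes gap runs
    # to the lowest reference coordinate; mirror that convention here)
    truth.indels = [
        _left_shift_event(e, seq, ins_payload_raw.get(e.ref_pos)) for e in indels
    ]
    truth.indels.sort(key=lambda e: e.ref_pos)

    # --- apply InDels back-to-front so earlier coordinates stay valid -------
    ins_payload = ins_payload_raw
    for e in reversed(indels):
        if e.kind == "deletion":
            del seq[e.ref_pos - 1 : e.ref_pos - 1 + e.length]
        else:
            payload = ins_payload[e.ref_pos]
            seq[e.ref_pos : e.ref_pos] = list(payload)

    new_annotations = _lift_annotations(rec.annotations, indels)
    derived = PlastomeRecord(
        id=f"{rec.id}_derived",
        sequence="".join(seq),
        annotations=new_annotations,
        source=f"diverged from {rec.id} (seed {seed})",
    )
    return derived, truth


def _left_shift_event(e: IndelEvent, anc: list[str], payload: str | None) -> IndelEvent:
    """Left-shift an InDel to its lowest-coordinate equivalent on the ancestor."""
    p = e.ref_pos
    if e.kind == "deletion":
        while p > 1 and anc[p - 2] == anc[p + e.length - 2]:
            p -= 1
    else:
        pay = list(payload or "")
        while p > 0 and pay and pay[-1] == anc[p - 1]:
            pay = [anc[p - 1]] + pay[:-1]
            p -= 1
    return IndelEvent(ref_pos=p, length=e.length, kind=e.kind)


def _stop_safe_alt(seq, pos, alt, ref, cds, p_ts, rng) -> str | None:
    ctx = _codon_at(seq, pos, cds)
    if ctx is None:
        return alt
    positions, codon, off = ctx
    strand = "+" if len(positions) < 2 or positions[1] > positions[0] else "-"
    candidates = [alt] + [b for b in BASES if b not in (alt, ref)]
    for b in candidates:
        nb = b if strand == "+" else _COMP1[b]
        new_codon = codon[:off] + nb + codon[off + 1 :]
        if new_codon not in STOP_CODONS:
            return b
    return None


def _lift_annotations(annotations, indels) -> list[GeneAnnotation]:
    """Shift annotation coordinates through the applied InDels. Exons whose
    boundaries fall inside a deletion are clamped to the deletion edge."""
    if not indels:
        return list(annotations)
    events = sorted(indels, key=lambda e: e.ref_pos)

    def lift(p: int) -> int:
        shift = 0
        for e in events:
            if e.kind == "insertion":
                if e.ref_pos < p:
                    shift += e.length
            else:
                if e.ref_pos + e.length - 1 < p:
                    shift -= e.length
                elif e.ref_pos <= p:
                    p_clamped = e.ref_pos - 1
                    return p_clamped + shift
        return p + shift

    out = []
    for ann in annotations:
        exons = tuple((max(lift(s), 1), max(lift(e), 1)) for s, e in ann.exons)
        exons = tuple((s, e) for s, e in exons if s <= e)
        if exons:
            out.append(replace(ann, exons=exons))
    return out


# --------------------------------------------------------------------------
# codon-pair simulation for Ka/Ks recovery
# --------------------------------------------------------------------------


def simulate_codon_pair(
    n_codons: int, omega: float, mu: float, rng: np.random.Generator
) -> tuple[str, str]:
    """A CDS and a diverged copy in which proposed substitutions are accepted
    with probability 1 for synonymous and ``omega`` for non-synonymous
    changes (changes creating stops are rejected), so the expected Ka/Ks of
    the pair is ``omega``."""
    anc = _random_orf(rng, 3 * (n_codons + 2))[3:-3]  # strip start/stop
    der = list(anc)
    for i in range(len(der)):
        if rng.random() >= mu:
            continue
        cur = der[i]
        alt = BASES[int(rng.integers(0, 4))]
        if alt == cur:
            continue
        c0 = 3 * (i // 3)
        codon = "".join(der[c0 : c0 + 3])
        new_codon = codon[: i % 3] + alt + codon[i % 3 + 1 :]
        if new_codon in STOP_CODONS:
            continue
        syn = CODON_TO_AA[new_codon] == CODON_TO_AA[codon]
        if syn or rng.random() < omega:
            der[i] = alt
    return anc, "".join(der)
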