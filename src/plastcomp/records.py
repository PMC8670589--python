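"""Plastome records: circular DNA plus gene annotations, read from GenBank or
FASTA + tab-separated annotation tables.

Coordinates are 1-based inclusive throughout (GenBank convention). A record's
``sequence`` is the linearized circle; helper :func:`rotate_record` re-origins
it (used to normalize a genome so the large single-copy region starts at 1).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

CATEGORIES = ("protein_coding", "tRNA", "rRNA")

_FEATURE_CATEGORY = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}


class PlastomeParseError(ValueError):
    """Raised when an input file does not parse under the named standard."""


class PlastomeValidationError(ValueError):
    """Raised when a record violates a structural invariant."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene locus; multi-exon genes carry several intervals."""

    name: str
    category: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    notes: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise PlastomeValidationError(
                f"gene {self.name!r}: unknown category {self.category!r}"
            )
        if self.strand not in "+-":
            raise PlastomeValidationError(f"gene {self.name!r}: bad strand {self.strand!r}")
        if not self.exons:
            raise PlastomeValidationError(f"gene {self.name!r}: no exons")
        for s, e in self.exons:
            if not (1 <= s <= e):
                raise PlastomeValidationError(
                    f"gene {self.name!r}: malformed exon interval ({s}, {e})"
                )

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class PlastomeRecord:
    id: str
    sequence: str
    annotations: list[GeneAnnotation] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        if not self.id:
            raise PlastomeValidationError("record id must be non-empty")
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise PlastomeValidationError(f"record {self.id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise PlastomeValidationError(
                f"record {self.id}: non-ACGTN characters {sorted(bad)}"
            )
        n = len(self.sequence)
        for ann in self.annotations:
            if ann.end > n:
                raise PlastomeValidationError(
                    f"record {self.id}: gene {ann.name!r} exon end {ann.end} "
                    f"outside sequence of length {n}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


def _annotation_from_feature(feat, name: str) -> GeneAnnotation:
    strand = "-" if feat.location.strand == -1 else "+"
    exons = tuple(
        sorted((int(part.start) + 1, int(part.end)) for part in feat.location.parts)
    )
    return GeneAnnotation(name=name, category=_FEATURE_CATEGORY[feat.type], strand=strand, exons=exons)


def read_genbank(path: str | Path) -> PlastomeRecord:
    path = Path(path)
    try:
        seqrec = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise PlastomeParseError(f"{path}: not a parseable GenBank record ({exc})") from exc
    annotations = []
    seen: set[tuple] = set()
    for feat in seqrec.features:
        if feat.type not in _FEATURE_CATEGORY:
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
        ann = _annotation_from_feature(feat, name)
        key = (ann.name, ann.exons)
        if key in seen:  # CDS + gene feature pairs collapse to one locus
            continue
        seen.add(key)
        annotations.append(ann)
    return PlastomeRecord(
        id=seqrec.id or path.stem,
        sequence=str(seqrec.seq),
        annotations=annotations,
        source=str(path),
    )


def read_fasta_tsv(fasta_path: str | Path, tsv_path: str | Path) -> PlastomeRecord:
    """FASTA plus a table with columns gene, category, strand, exon_start, exon_end
    (one row per exon; rows of one gene grouped by name)."""
    fasta_path, tsv_path = Path(fasta_path), Path(tsv_path)
    try:
        seqrec = next(SeqIO.parse(str(fasta_path), "fasta"))
    except StopIteration:
        raise PlastomeParseError(f"{fasta_path}: no FASTA record found") from None
    exons_by_gene: dict[str, dict] = {}
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene", "category", "strand", "exon_start", "exon_end"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise PlastomeParseError(
                f"{tsv_path}: header must contain {sorted(required)}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                s, e = int(row["exon_start"]), int(row["exon_end"])
            except ValueError:
                raise PlastomeParseError(f"{tsv_path}: line {i}: non-integer exon bounds") from None
            entry = exons_by_gene.setdefault(
                row["gene"], {"category": row["category"], "strand": row["strand"], "exons": []}
            )
            entry["exons"].append((s, e))
    annotations = [
        GeneAnnotation(
            name=g, category=d["category"], strand=d["strand"], exons=tuple(sorted(d["exons"]))
        )
        for g, d in exons_by_gene.items()
    ]
    return PlastomeRecord(
        id=seqrec.id or fasta_path.stem,
        sequence=str(seqrec.seq),
        annotations=annotations,
        source=str(fasta_path),
    )


def read_plastome(path: str | Path, format: str = "auto", tsv: str | Path | None = None) -> PlastomeRecord:
    """Read a plastome record.

    ``format`` is ``genbank``, ``fasta+gff`` (FASTA plus annotation table, the
    table path given as ``tsv`` or inferred by swapping the suffix for ``.tsv``)
    or ``auto`` (by suffix).
    """
    path = Path(path)
    if format == "auto":
        format = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta+gff"
    if format == "genbank":
        return read_genbank(path)
    if format == "fasta+gff":
        tsv = Path(tsv) if tsv else path.with_suffix(".tsv")
        return read_fasta_tsv(path, tsv)
    raise ValueError(f"unknown format {format!r}")


def write_fasta_tsv(rec: PlastomeRecord, fasta_path: str | Path, tsv_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{rec.id}\n")
        for i in range(0, rec.length, 70):
            fh.write(rec.sequence[i : i + 70] + "\n")
    with open(tsv_path, "w") as fh:
        fh.write("gene\tcategory\tstrand\texon_start\texon_end\n")
        for ann in rec.annotations:
            for s, e in ann.exons:
                fh.write(f"{ann.name}\t{ann.category}\t{ann.strand}\t{s}\t{e}\n")


def rotate_record(rec: PlastomeRecord, offset: int) -> PlastomeRecord:
    """Re-origin the circular sequence so 0-based position ``offset`` becomes base 1.

    Annotations are shifted accordingly; a gene whose exon would wrap the new
    origin raises, since downstream coordinates are strictly linear.
    """
    n = rec.length
    offset %= n
    if offset == 0:
        return rec
    seq = rec.sequence[offset:] + rec.sequence[:offset]
    annotations = []
    for ann in rec.annotations:
        new_exons = []
        for s, e in ann.exons:
            ns = (s - 1 - offset) % n + 1
            ne = (e - 1 - offset) % n + 1
            if ne < ns:
                raise PlastomeValidationError(
                    f"gene {ann.name!r} spans the new origin after rotation"
                )
            new_exons.append((ns, ne))
        annotations.append(replace(ann, exons=tuple(sorted(new_exons))))
    annotations.sort(key=lambda a: a.start)
    return PlastomeRecord(id=rec.id, sequence=seq, annotations=annotations, source=rec.source)
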