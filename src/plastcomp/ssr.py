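"""Microsatellite (SSR) detection under MISA-style copy-number thresholds.

Defaults follow the common plastome convention: mononucleotide runs of at
least 10 copies, dinucleotide >= 5, trinucleotide >= 4 and tetra-/penta-/
hexanucleotide >= 3. Only perfect (uninterrupted) repeats are reported; a
run that is perfect under several unit lengths is reported once, at the
smallest unit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .records import GeneAnnotation, PlastomeRecord
from .structure import QuadripartiteStructure
from .util import revcomp

DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRLocus:
    motif: str
    unit_length: int
    copies: int
    start: int  # 1-based inclusive
    end: int
    region: str = ""
    context: str = ""
    junction_spanning: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _is_primitive(motif: str) -> bool:
    """True when the motif is not itself a repetition of a shorter unit."""
    u = len(motif)
    for p in range(1, u):
        if u % p == 0 and motif == motif[:p] * (u // p):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation of the unit."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def motif_class(motif: str) -> str:
    """Reporting class merging a canonical motif with its reverse complement,
    e.g. A/T, AT/AT, AAG/CTT."""
    a = canonical_motif(motif)
    b = canonical_motif(revcomp(motif))
    return "/".join(sorted((a, b)))


def find_ssrs(
    rec: PlastomeRecord, thresholds: dict[int, int] | None = None
) -> list[SSRLocus]:
    """Maximal perfect SSRs meeting the per-unit-length copy thresholds.

    N bases terminate any run. Loci are sorted by start position.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    missing = set(range(1, 7)) - set(thresholds)
    if missing:
        raise ValueError(f"thresholds missing for unit lengths {sorted(missing)}")
    seq = rec.sequence
    n = len(seq)
    loci: list[SSRLocus] = []
    claimed: list[tuple[int, int]] = []  # intervals already reported at a smaller unit
    for u in range(1, 7):
        i = 0
        while i + u <= n:
            if "N" in seq[i : i + u]:
                i += 1
                continue
            # extend the period-u run starting at i
            j = i + u
            while j < n and seq[j] == seq[j - u] and seq[j] != "N":
                j += 1
            run_len = j - i
            copies = run_len // u
            if copies >= thresholds[u]:
                start0, end0 = i, i + copies * u - 1  # 0-based
                motif = seq[i : i + u]
                if _is_primitive(motif) and not any(
                    s <= start0 and end0 <= e for s, e in claimed
                ):
                    loci.append(
                        SSRLocus(
                            motif=motif,
                            unit_length=u,
                            copies=copies,
                            start=start0 + 1,
                            end=end0 + 1,
                        )
                    )
                    claimed.append((i, j - 1))
                i = j  # maximality: nothing inside this run restarts at unit u
            else:
                # sub-runs of this maximal period-u stretch are shorter still
                i = max(i + 1, j - u + 1)
        # after each unit pass nothing to reset: claimed spans grow monotonically
    loci.sort(key=lambda l: (l.start, l.unit_length))
    return loci


def classify_ssrs(
    loci: list[SSRLocus],
    structure: QuadripartiteStructure,
    annotations: list[GeneAnnotation],
) -> list[SSRLocus]:
    """Assign each locus its region (by start position) and coding context.

    Loci spanning a region junction keep the start's region and are flagged.
    """
    exon_ivs = sorted(
        (s, e) for ann in annotations for (s, e) in ann.exons
    )
    out = []
    for loc in loci:
        region = structure.region_of(loc.start)
        spans = structure.region_of(loc.end) != region
        coding = any(s <= loc.start <= e for s, e in exon_ivs)
        out.append(
            replace(
                loc,
                region=region,
                context="coding" if coding else "non-coding",
                junction_spanning=spans,
            )
        )
    return out


def summarize_ssrs(loci: list[SSRLocus]) -> pd.DataFrame:
    """Counts by motif class x region x context."""
    rows = [
        {
            "motif_class": motif_class(l.motif),
            "unit_length": l.unit_length,
            "region": l.region or "?",
            "context": l.context or "?",
        }
        for l in loci
    ]
    if not rows:
        return pd.DataFrame(columns=["motif_class", "unit_length", "region", "context", "count"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["motif_class", "unit_length", "region", "context"])
        .size()
        .reset_index(name="count")
        .sort_values(["unit_length", "motif_class", "region", "context"])
        .reset_index(drop=True)
    )


def ssr_table(loci: list[SSRLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": l.motif,
                "unit_length": l.unit_length,
                "copies": l.copies,
                "start": l.start,
                "end": l.end,
                "region": l.region,
                "context": l.context,
            }
            for l in loci
        ]
    )
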