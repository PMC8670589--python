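"""Per-gene Ka/Ks estimation (Nei-Gojobori 1986 counting with Jukes-Cantor
multiple-hit correction), selection categorization, and codon-usage /
amino-acid-frequency profiling.

The NG86 estimator counts synonymous (S) and non-synonymous (N) sites per
codon as the fraction of the three possible changes at each position that
preserve the encoded amino acid (changes creating a stop codon count as
non-synonymous); sites are averaged over both sequences. Observed
differences between a codon pair are averaged over all minimal mutational
pathways, excluding pathways that pass through a stop codon. The standard
genetic code is used (plastid CDS; internal stops are treated as errors).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

BASES = "ACGT"
STOP_CODONS = set(standard_dna_table.stop_codons)
CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

AA3_FREQ_ORDER = sorted(set(standard_dna_table.forward_table.values()))


class InternalStopError(ValueError):
    pass


def _syn_site_fraction(codon: str) -> float:
    """Synonymous fraction of the 9 possible single-base changes (NG86 sites)."""
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TO_AA[alt] == aa and alt not in STOP_CODONS:
                s += 1 / 3
    return s


_SYN_SITES = {c: _syn_site_fraction(c) for c in CODON_TO_AA if c not in STOP_CODONS}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons, averaged
    over all minimal mutational pathways that avoid stop codons."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot, nsyn_tot, n_paths = 0.0, 0.0, 0
    for order in permutations(diff_pos):
        cur = c1
        syn, nsyn = 0, 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nsyn_tot += nsyn
            n_paths += 1
    if n_paths == 0:
        # every pathway crosses a stop; fall back to averaging over all orders
        for order in permutations(diff_pos):
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                    syn_tot += 1
                else:
                    nsyn_tot += 1
                cur = nxt
            n_paths += 1
    return syn_tot / n_paths, nsyn_tot / n_paths


def codon_align(ref_cds: str, qry_cds: str, gene: str = "?") -> list[tuple[str, str]]:
    """Protein-guided codon pairing of two CDS.

    Terminal stop codons are trimmed; codon pairs containing gaps, N or
    ambiguity are excluded. An internal stop raises
    :class:`InternalStopError` naming the gene and codon position.
    """
    codons = []
    for cds in (ref_cds, qry_cds):
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"gene {gene}: CDS length {len(cds)} not divisible by 3")
        cs = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if cs and cs[-1] in STOP_CODONS:
            cs = cs[:-1]
        for idx, c in enumerate(cs):
            if c in STOP_CODONS:
                raise InternalStopError(f"gene {gene}: internal stop at codon {idx + 1}")
        codons.append(cs)
    ref_c, qry_c = codons
    ref_p = "".join(CODON_TO_AA.get(c, "X") for c in ref_c)
    qry_p = "".join(CODON_TO_AA.get(c, "X") for c in qry_c)
    if ref_p == qry_p or len(ref_p) == len(qry_p):
        pairs = list(zip(ref_c, qry_c))
    else:
        aligner = PairwiseAligner(scoring="blastp")
        aligner.mode = "global"
        aln = aligner.align(ref_p, qry_p)[0]
        pairs = []
        for (rs, re_), (qs, qe) in zip(*aln.aligned):
            pairs.extend(zip(ref_c[rs:re_], qry_c[qs:qe]))
    return [
        (a, b)
        for a, b in pairs
        if set(a) <= set(BASES) and set(b) <= set(BASES)
    ]


def ng86(pairs: list[tuple[str, str]]) -> tuple[float | None, float | None]:
    """(ka, ks) for a paired codon list; None where undefined (no sites, or
    proportion of differences beyond the Jukes-Cantor horizon of 3/4)."""
    if not pairs:
        raise ValueError("ng86 requires at least one codon pair")
    S = 0.0
    Sd, Nd = 0.0, 0.0
    for a, b in pairs:
        S += (_SYN_SITES[a] + _SYN_SITES[b]) / 2
        sd, nd = _pathway_counts(a, b)
        Sd += sd
        Nd += nd
    total_sites = 3 * len(pairs)
    N = total_sites - S
    ks = _jc_rate(Sd, S)
    ka = _jc_rate(Nd, N)
    return ka, ks


def _jc_rate(d: float, sites: float) -> float | None:
    if sites <= 0:
        return None
    p = d / sites
    if p >= 0.75:
        return None
    if p == 0:
        return 0.0
    return -0.75 * math.log(1 - 4 * p / 3)


DEFAULT_BANDS = {
    "positive": 1.05,  # ratio above
    "neutral": 0.95,  # 0.95..1.05
    "near_neutral": 0.80,  # 0.80..0.95
}


def categorize_selection(ratio: float | None, bands: dict[str, float] | None = None) -> str:
    """Selection category from a Ka/Ks ratio.

    Default banding: >1.05 positive; 0.95-1.05 neutral; 0.80-0.95 ~neutral;
    <0.80 purifying; undefined ratios are 'unclassified'.
    """
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return "unclassified"
    if ratio < 0:
        raise ValueError("Ka/Ks ratio cannot be negative")
    b = DEFAULT_BANDS if bands is None else bands
    if ratio > b["positive"]:
        return "positive"
    if ratio >= b["neutral"]:
        return "neutral"
    if ratio >= b["near_neutral"]:
        return "~neutral"
    return "purifying"


@dataclass(frozen=True)
class GeneSelectionEstimate:
    gene: str
    ka: float | None
    ks: float | None
    ratio: float | None
    category: str


def gene_selection(gene: str, ref_cds: str, qry_cds: str) -> GeneSelectionEstimate:
    pairs = codon_align(ref_cds, qry_cds, gene=gene)
    ka, ks = ng86(pairs)
    ratio = (ka / ks) if (ka is not None and ks is not None and ks > 0) else None
    return GeneSelectionEstimate(
        gene=gene, ka=ka, ks=ks, ratio=ratio, category=categorize_selection(ratio)
    )


@dataclass(frozen=True)
class CodonProfile:
    codon_counts: dict[str, int]
    aa_frequencies: dict[str, float]  # over non-stop residues
    stop_count: int
    rscu: dict[str, float]
    at_ending: int  # third position A/T tally
    gc_ending: int
    skipped_codons: int  # non-ACGT codons


def codon_profile(cds_set: list[str]) -> CodonProfile:
    """Pooled codon counts, amino-acid frequencies (stops excluded), RSCU and
    the third-position A/T vs G/C tally."""
    counts = {a + b + c: 0 for a in BASES for b in BASES for c in BASES}
    skipped = 0
    for cds in cds_set:
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"CDS length {len(cds)} not divisible by 3")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if set(codon) <= set(BASES):
                counts[codon] += 1
            else:
                skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} codons containing non-ACGT characters")
    aa_counts: dict[str, int] = {}
    stop_count = 0
    at_end = gc_end = 0
    for codon, c in counts.items():
        if c == 0:
            continue
        aa = CODON_TO_AA[codon]
        if aa == "*":
            stop_count += c
        else:
            aa_counts[aa] = aa_counts.get(aa, 0) + c
            if codon[2] in "AT":
                at_end += c
            else:
                gc_end += c
    total_aa = sum(aa_counts.values())
    aa_freq = {aa: aa_counts.get(aa, 0) / total_aa for aa in AA3_FREQ_ORDER} if total_aa else {}
    # RSCU: observed / (family total / family size), per synonymous family
    families: dict[str, list[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        if aa != "*":
            families.setdefault(aa, []).append(codon)
    rscu: dict[str, float] = {}
    for aa, codons in families.items():
        fam_total = sum(counts[c] for c in codons)
        for c in codons:
            rscu[c] = (counts[c] * len(codons) / fam_total) if fam_total else float("nan")
    return CodonProfile(
        codon_counts=counts,
        aa_frequencies=aa_freq,
        stop_count=stop_count,
        rscu=rscu,
        at_ending=at_end,
        gc_ending=gc_end,
        skipped_codons=skipped,
    )


def translate(cds: str) -> str:
    return str(Seq(cds).translate())
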