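"""Global alignment of near-identical sequences and mutational-event
extraction.

The aligner targets the >=95%-identity regime of congeneric plastomes: it
anchors on shared unique 21-mers, chains them colinearly, and closes the
inter-anchor segments with affine-gap Needleman-Wunsch (match +1, mismatch
-2, gap open -5, gap extend -1). Gap runs are left-shifted to the lowest
reference coordinate so InDel coordinates are deterministic in repeat
contexts.

Substitutions are classified into the six unordered base-pair categories
(A/C, C/T, A/G, A/T, C/G, G/T); C/T and A/G are transitions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .records import PlastomeRecord
from .util import revcomp

GAP = "-"

TRANSITIONS = {frozenset("AG"), frozenset("CT")}
PAIR_CATEGORIES = ("A/C", "C/T", "A/G", "A/T", "C/G", "G/T")


class DivergenceError(ValueError):
    """Sequences too divergent for the anchored near-identity aligner."""


@dataclass
class PairwiseAlignment:
    ref_id: str
    qry_id: str
    ref_aln: str
    qry_aln: str

    def __post_init__(self):
        if len(self.ref_aln) != len(self.qry_aln):
            raise ValueError("aligned rows differ in length")
        for r, q in zip(self.ref_aln, self.qry_aln):
            if r == GAP and q == GAP:
                raise ValueError("column gapped in both rows")

    @property
    def ref_seq(self) -> str:
        return self.ref_aln.replace(GAP, "")

    @property
    def qry_seq(self) -> str:
        return self.qry_aln.replace(GAP, "")


@dataclass(frozen=True)
class SubstitutionEvent:
    ref_pos: int  # 1-based reference position
    ref_base: str
    qry_base: str

    @property
    def pair_category(self) -> str:
        return "/".join(sorted((self.ref_base, self.qry_base)))

    @property
    def is_transition(self) -> bool:
        return frozenset((self.ref_base, self.qry_base)) in TRANSITIONS


@dataclass(frozen=True)
class IndelEvent:
    ref_pos: int  # first deleted ref base, or ref base preceding an insertion
    length: int
    kind: str  # "insertion" | "deletion" relative to the reference


@dataclass(frozen=True)
class SubstitutionSummary:
    counts: dict[str, int]
    ts_count: int
    tv_count: int
    ts_tv_ratio: float | None  # None when tv_count == 0

    @property
    def total(self) -> int:
        return self.ts_count + self.tv_count


def _gotoh(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-1):
    """Affine-gap global alignment of two short segments; returns aligned rows."""
    n, m = len(a), len(b)
    if n == 0:
        return GAP * m, b
    if m == 0:
        return a, GAP * n
    NEG = -(10**9)
    # DP over three states: M (match/mismatch), X (gap in b), Y (gap in a)
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], match, mismatch)
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        best_prev = np.maximum(np.maximum(Mi1, Xi1), Yi1)
        M[i, 1:] = best_prev[:-1] + sub
        X[i, 1:] = np.maximum(best_prev[1:] + gap_open, X[i - 1, 1:] + gap_extend)
        # Y must be filled left-to-right (depends on same row)
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, m + 1):
            Yi[j] = max(
                max(Mi[j - 1], Xi[j - 1]) + gap_open, Yi[j - 1] + gap_extend
            )
    # traceback
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ra, rb = [], []
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                state = 1 if j == 0 else 2
                continue
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev)) if (i or j) else 0
            # consistency: prev best + s must equal current; argmax suffices
            del s
        elif state == 1:  # gap in b: consume a[i-1]
            ra.append(a[i - 1])
            rb.append(GAP)
            if i > 1 and X[i, j] == X[i - 1, j] + gap_extend:
                state = 1
            else:
                prev = [M[i - 1, j], NEG, Y[i - 1, j]]
                state = int(np.argmax(prev))
            i -= 1
        else:  # gap in a: consume b[j-1]
            ra.append(GAP)
            rb.append(b[j - 1])
            if j > 1 and Y[i, j] == Y[i, j - 1] + gap_extend:
                state = 2
            else:
                prev = [M[i, j - 1], X[i, j - 1], NEG]
                state = int(np.argmax(prev))
            j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb))


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    counts: Counter[str] = Counter()
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] += 1
        pos[kmer] = i
    return {kmer: i for kmer, i in pos.items() if counts[kmer] == 1 and "N" not in kmer}


def _chain_anchors(ref: str, qry: str, k: int) -> list[tuple[int, int]]:
    """Colinear chain of shared unique k-mer anchors (longest increasing chain)."""
    ru = _unique_kmer_positions(ref, k)
    qu = _unique_kmer_positions(qry, k)
    shared = [(ru[kmer], qu[kmer]) for kmer in ru.keys() & qu.keys()]
    shared.sort()
    if not shared:
        return []
    # longest strictly-increasing subsequence in qry coordinate
    import bisect

    tails: list[int] = []
    tails_idx: list[int] = []
    back = [-1] * len(shared)
    for idx, (_, q) in enumerate(shared):
        at = bisect.bisect_left(tails, q)
        if at == len(tails):
            tails.append(q)
            tails_idx.append(idx)
        else:
            tails[at] = q
            tails_idx[at] = idx
        back[idx] = tails_idx[at - 1] if at > 0 else -1
    chain = []
    cur = tails_idx[-1]
    while cur != -1:
        chain.append(shared[cur])
        cur = back[cur]
    chain.reverse()
    return chain


def _merge_chain(chain: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Merge adjacent anchors on the same diagonal into exact blocks
    (ref_start, qry_start, length), non-overlapping and colinear."""
    blocks: list[list[int]] = []
    for r, q in chain:
        if blocks and r - blocks[-1][0] == q - blocks[-1][1] and r <= blocks[-1][0] + blocks[-1][2]:
            blocks[-1][2] = r + k - blocks[-1][0]
        else:
            blocks.append([r, q, k])
    # enforce non-overlap between consecutive blocks (trim block starts)
    out: list[tuple[int, int, int]] = []
    prev_r_end, prev_q_end = 0, 0
    for r, q, ln in blocks:
        trim = max(prev_r_end - r, prev_q_end - q, 0)
        r, q, ln = r + trim, q + trim, ln - trim
        if ln > 0:
            out.append((r, q, ln))
            prev_r_end, prev_q_end = r + ln, q + ln
    return out


def align_near_identical(
    ref: str | PlastomeRecord,
    qry: str | PlastomeRecord,
    k: int = 21,
    max_segment: int = 20_000,
    ref_id: str = "ref",
    qry_id: str = "qry",
) -> PairwiseAlignment:
    """Anchored global alignment of two near-identical sequences.

    Raises :class:`DivergenceError` when no anchor chain is found or an
    inter-anchor segment is implausibly large for near-identical inputs.
    """
    if isinstance(ref, PlastomeRecord):
        ref_id, ref = ref.id, ref.sequence
    if isinstance(qry, PlastomeRecord):
        qry_id, qry = qry.id, qry.sequence
    ref, qry = ref.upper(), qry.upper()
    if ref == qry:
        return PairwiseAlignment(ref_id, qry_id, ref, qry)
    blocks = _merge_chain(_chain_anchors(ref, qry, k), k)
    if not blocks and (len(ref) > 2 * max_segment or len(qry) > 2 * max_segment):
        raise DivergenceError(
            "no shared unique k-mer anchors; sequences too divergent for this aligner"
        )
    ra_parts, qa_parts = [], []
    pr, pq = 0, 0
    for r, q, ln in blocks + [(len(ref), len(qry), 0)]:
        seg_r, seg_q = ref[pr:r], qry[pq:q]
        if max(len(seg_r), len(seg_q)) > max_segment:
            raise DivergenceError(
                f"unanchored segment of {max(len(seg_r), len(seg_q))} bp "
                "exceeds the near-identity regime; align externally"
            )
        if seg_r or seg_q:
            a, b = _gotoh(seg_r, seg_q)
            ra_parts.append(a)
            qa_parts.append(b)
        ra_parts.append(ref[r : r + ln])
        qa_parts.append(qry[q : q + ln])
        pr, pq = r + ln, q + ln
    aln = PairwiseAlignment(ref_id, qry_id, "".join(ra_parts), "".join(qa_parts))
    return _left_shift_gaps(aln)


def _left_shift_row(top: str, bottom: str) -> tuple[str, str]:
    """Shift gap runs in ``bottom`` leftwards while the flanking base matches."""
    t, b = list(top), list(bottom)
    n = len(b)
    i = 0
    while i < n:
        if b[i] == GAP:
            j = i
            while j + 1 < n and b[j + 1] == GAP:
                j += 1
            # try to shift the run [i, j] left
            while i > 0 and b[i - 1] != GAP and t[i - 1] != GAP and b[i - 1] == t[j]:
                b[j] = b[i - 1]
                b[i - 1] = GAP
                i -= 1
                j -= 1
            i = j + 1
        else:
            i += 1
    return "".join(t), "".join(b)


def _left_shift_gaps(aln: PairwiseAlignment) -> PairwiseAlignment:
    r, q = _left_shift_row(aln.ref_aln, aln.qry_aln)
    q2, r2 = _left_shift_row(q, r)
    return PairwiseAlignment(aln.ref_id, aln.qry_id, r2, q2)


def extract_events(aln: PairwiseAlignment) -> tuple[list[SubstitutionEvent], list[IndelEvent]]:
    """Substitutions per mismatching non-gap column (N skipped) and one InDel
    per maximal gap run; insertions anchor to the preceding reference base."""
    subs: list[SubstitutionEvent] = []
    indels: list[IndelEvent] = []
    ref_pos = 0
    run_kind: str | None = None
    run_len = 0
    run_anchor = 0
    for r, q in zip(aln.ref_aln, aln.qry_aln):
        if r != GAP:
            ref_pos += 1
        kind = "insertion" if r == GAP else ("deletion" if q == GAP else None)
        if kind != run_kind:
            if run_kind is not None:
                indels.append(IndelEvent(ref_pos=run_anchor, length=run_len, kind=run_kind))
            run_kind, run_len = kind, 0
            if kind == "deletion":
                run_anchor = ref_pos  # first deleted reference base
            elif kind == "insertion":
                run_anchor = ref_pos  # reference base preceding the run
        if kind is not None:
            run_len += 1
            continue
        if r != q and r != "N" and q != "N":
            subs.append(SubstitutionEvent(ref_pos=ref_pos, ref_base=r, qry_base=q))
    if run_kind is not None:
        indels.append(IndelEvent(ref_pos=run_anchor, length=run_len, kind=run_kind))
    return subs, indels


def summarize_substitutions(events: list[SubstitutionEvent]) -> SubstitutionSummary:
    counts = {cat: 0 for cat in PAIR_CATEGORIES}
    for ev in events:
        counts[ev.pair_category] += 1
    return summary_from_counts(counts)


def summary_from_counts(counts: dict[str, int]) -> SubstitutionSummary:
    """Build a Ts/Tv summary from six pair-category counts."""
    full = {cat: int(counts.get(cat, 0)) for cat in PAIR_CATEGORIES}
    ts = full["C/T"] + full["A/G"]
    tv = full["A/C"] + full["A/T"] + full["C/G"] + full["G/T"]
    ratio = round(ts / tv, 2) if tv else None
    return SubstitutionSummary(counts=full, ts_count=ts, tv_count=tv, ts_tv_ratio=ratio)


def concatenate_genes(rec: PlastomeRecord, gene_list: list[str]) -> str:
    """Splice each listed gene (strand-corrected to coding orientation) and
    concatenate in genome order of first exon."""
    by_name = {}
    for ann in rec.annotations:
        by_name.setdefault(ann.name, []).append(ann)
    missing = [g for g in gene_list if g not in by_name]
    if missing:
        raise KeyError(f"genes absent from record {rec.id}: {missing}")
    chosen = [min(by_name[g], key=lambda a: a.start) for g in gene_list]
    chosen.sort(key=lambda a: a.start)
    parts = []
    for ann in chosen:
        exons = sorted(ann.exons)
        spliced = "".join(rec.sequence[s - 1 : e] for s, e in exons)
        parts.append(revcomp(spliced) if ann.strand == "-" else spliced)
    return "".join(parts)
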