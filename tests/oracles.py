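"""Independent reference implementations used to cross-check the package.

These deliberately re-derive results by brute force / enumeration and do
not share code paths with the implementations they check (numpy is used
only for raw array comparison).
"""

from __future__ import annotations

import re

import numpy as np

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


# ---------------------------------------------------------------------------
# SSR oracle: exhaustive regex enumeration
# ---------------------------------------------------------------------------


def regex_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple]:
    """All maximal perfect SSRs as (motif, unit, copies, start1, end1),
    reported only at the smallest unit, primitive motifs only."""
    found = []
    for u in range(1, 7):
        t = thresholds[u]
        pat = re.compile(r"(?=(([ACGT]{%d})\2{%d,}))" % (u, t - 1))
        for m in pat.finditer(seq):
            whole, unit = m.group(1), m.group(2)
            copies = len(whole) // u
            start = m.start()
            # maximality left: preceding base must not extend the period
            if start >= u and seq[start - 1] == seq[start - 1 + u]:
                continue
            # primitivity of the unit
            if any(u % p == 0 and unit == unit[:p] * (u // p) for p in range(1, u)):
                continue
            # re-extend right maximally (regex is greedy in whole copies, but
            # confirm no further full unit follows)
            end = start + copies * u
            while seq[end : end + u] == unit:
                copies += 1
                end += u
            found.append((unit, u, copies, start + 1, start + copies * u))
    # smallest-unit rule: drop loci wholly inside a smaller-unit locus
    out = set()
    for motif, u, copies, s, e in found:
        covered = any(
            u2 < u and s2 <= s and e <= e2 for (_, u2, _, s2, e2) in found
        )
        if not covered:
            out.add((motif, u, copies, s, e))
    return out


# ---------------------------------------------------------------------------
# diagonal repeat oracle: exhaustive window enumeration with shared rules
# ---------------------------------------------------------------------------


def _match_array(a: str, b: str, d: int) -> tuple[int, list[bool]]:
    i0 = max(0, -d)
    i1 = min(len(a), len(b) - d)
    if i1 <= i0:
        return i0, []
    av = np.frombuffer(a.encode(), np.uint8)[i0:i1]
    bv = np.frombuffer(b.encode(), np.uint8)[i0 + d : i1 + d]
    m = (av == bv) & (av != ord("N"))
    return i0, m.tolist()


def _exhaustive_windows(match: list[bool], min_len: int, min_identity: float):
    """All maximal-by-inclusion valid windows via direct forward scanning."""
    n = len(match)
    pos = [i for i, v in enumerate(match) if v]
    if not pos:
        return []
    total_matches_after = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        total_matches_after[i] = total_matches_after[i + 1] + (1 if match[i] else 0)
    q = 1.0 - min_identity
    wins = []
    for x in pos:
        best_y = None
        mism = 0
        y = x
        while y < n:
            if not match[y]:
                mism += 1
            else:
                if mism <= q * (y - x + 1) + 1e-9:
                    best_y = y
            # prune: even converting every later match cannot repair validity
            # valid needs mism <= q/(1-q) * matches_in_window
            max_future_matches = (y - x + 1 - mism) + total_matches_after[y + 1]
            if mism > (q / (1.0 - q)) * max_future_matches + 1e-9:
                break
            y += 1
        if best_y is not None and best_y - x + 1 >= min_len:
            wins.append((x, best_y))
    # maximal by inclusion
    out = []
    best_end = -1
    for x, y in wins:
        if y > best_end:
            out.append((x, y))
            best_end = y
    return out


def _trim(match: list[bool], x: int, y: int, min_len: int, min_identity: float):
    """Independent re-implementation of the local end-trim rule."""
    runs = []
    i = x
    while i <= y:
        if match[i]:
            j = i
            while j + 1 <= y and match[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    while len(runs) > 1:
        m0 = runs[0][1] - runs[0][0] + 1
        g0 = runs[1][0] - runs[0][1] - 1
        mk = runs[-1][1] - runs[-1][0] + 1
        gk = runs[-1][0] - runs[-2][1] - 1
        if m0 / (m0 + g0) < min_identity - 1e-9:
            runs.pop(0)
        elif mk / (mk + gk) < min_identity - 1e-9:
            runs.pop()
        else:
            break
    if not runs:
        return None
    nx, ny = runs[0][0], runs[-1][1]
    if ny - nx + 1 < min_len:
        return None
    n_match = sum(e - s + 1 for s, e in runs)
    mism = (ny - nx + 1) - n_match
    if mism > (1 - min_identity) * (ny - nx + 1) + 1e-9:
        return None
    return nx, ny, mism


def _seeded_diagonals(a: str, b: str, k: int) -> set[int]:
    """Diagonals holding an exact k-mer match (any valid window at >= 90%
    identity and length >= 30 must contain an exact run of >= 7 by
    pigeonhole, so k=7 loses nothing)."""
    from collections import defaultdict

    idx = defaultdict(list)
    for j in range(len(b) - k + 1):
        idx[b[j : j + k]].append(j)
    out = set()
    for i in range(len(a) - k + 1):
        for j in idx.get(a[i : i + k], ()):
            out.add(j - i)
    return out


def oracle_oligo_repeats(seq: str, min_len: int, min_identity: float) -> set[tuple]:
    """All maximal repeat pairs of the four kinds, as
    (kind, pos1, pos2, length, mismatches) with 1-based pos1 <= pos2."""
    n = len(seq)
    transforms = {
        "forward": seq,
        "reverse": seq[::-1],
        "complement": seq.translate(COMP),
        "palindromic": revcomp(seq),
    }
    out = set()
    for kind, b in transforms.items():
        for d in sorted(_seeded_diagonals(seq, b, min(7, min_len))):
            if kind == "forward" and d == 0:
                continue
            i0, match = _match_array(seq, b, d)
            if len(match) < min_len:
                continue
            if not _has_run(match, min(7, min_len)):
                continue
            for x, y in _exhaustive_windows(match, min_len, min_identity):
                t = _trim(match, x, y, min_len, min_identity)
                if t is None:
                    continue
                nx, ny, mism = t
                i = i0 + nx
                j = i + d
                L = ny - nx + 1
                if kind in ("forward", "complement"):
                    p2 = j
                else:
                    p2 = n - j - L
                if p2 == i:
                    continue
                lo, hi = sorted((i, p2))
                out.add((kind, lo + 1, hi + 1, L, mism))
    return out


def _has_run(match: list[bool], k: int) -> bool:
    run = 0
    for v in match:
        run = run + 1 if v else 0
        if run >= k:
            return True
    return False


def oracle_longest_inverted_duplication(seq: str, min_len: int) -> list[tuple]:
    """Longest exact inverted-duplication pairs on the *linear* sequence:
    (start1, start2, length) 0-based, copies disjoint, longest first."""
    n = len(seq)
    rc = revcomp(seq)
    best = []
    for d in range(-(n - 1), n):
        _, match = _match_array(seq, rc, d)
        i0 = max(0, -d)
        run = 0
        for idx, v in enumerate(match):
            run = run + 1 if v else 0
            if run >= min_len and (idx + 1 == len(match) or not match[idx + 1]):
                i = i0 + idx - run + 1
                L = run
                j = i + d
                p2 = n - j - L
                a, b = sorted((i, p2))
                if a + L <= b:  # disjoint copies
                    best.append((a, b, L))
    best.sort(key=lambda t: (-t[2], t[0], t[1]))
    # dedupe mirrored hits
    seen, out = set(), []
    for a, b, L in best:
        if (a, b, L) not in seen:
            seen.add((a, b, L))
            out.append((a, b, L))
    return out


# ---------------------------------------------------------------------------
# plain affine Needleman-Wunsch oracle
# ---------------------------------------------------------------------------


def nw_affine(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-1):
    """Unbanded affine-gap global alignment, plain cubic-state DP.
    Returns (score, aligned_a, aligned_b)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    i, j = n, m
    scores = [M[i][j], X[i][j], Y[i][j]]
    state = scores.index(max(scores))
    best = scores[state]
    ra, rb = [], []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            ra.append(a[i - 1]); rb.append(b[j - 1])
            prev = [M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]]
            state = prev.index(max(prev))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            ra.append(a[i - 1]); rb.append("-")
            if X[i][j] == X[i - 1][j] + gap_extend and i > 1:
                state = 1
            elif X[i][j] == M[i - 1][j] + gap_open:
                state = 0
            elif X[i][j] == Y[i - 1][j] + gap_open:
                state = 2
            else:
                state = 0
            i -= 1
        elif state == 2 and j > 0:
            ra.append("-"); rb.append(b[j - 1])
            if Y[i][j] == Y[i][j - 1] + gap_extend and j > 1:
                state = 2
            elif Y[i][j] == M[i][j - 1] + gap_open:
                state = 0
            elif Y[i][j] == X[i][j - 1] + gap_open:
                state = 1
            else:
                state = 0
            j -= 1
        elif i > 0:
            state = 1
        else:
            state = 2
    return best, "".join(reversed(ra)), "".join(reversed(rb))


def alignment_score(ra: str, rb: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-1):
    """Score an aligned pair under the affine model."""
    score = 0
    in_gap = None
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            which = 0 if x == "-" else 1
            score += gap_extend if in_gap == which else gap_open
            in_gap = which
        else:
            in_gap = None
            score += match if x == y else mismatch
    return score


# ---------------------------------------------------------------------------
# misc small oracles
# ---------------------------------------------------------------------------


def histogram_counts(positions, ref_length: int, bin_size: int) -> list[int]:
    import math

    n_bins = math.ceil(ref_length / bin_size)
    counts = [0] * n_bins
    for p in positions:
        counts[(p - 1) // bin_size] += 1
    return counts


def gc_count(seq: str) -> float:
    acgt = [c for c in seq if c in "ACGT"]
    if not acgt:
        return float("nan")
    return sum(1 for c in acgt if c in "GC") / len(acgt)
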