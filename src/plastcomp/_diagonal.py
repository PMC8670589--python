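"""Seed-and-extend discovery of high-identity diagonal matches between two
strings.

A "window" on diagonal d (= j - i) is a pair of equal-length substrings
a[i:i+L] / b[i+d:i+d+L] compared position-wise (Hamming model, no gaps).
A window is *valid* when its ends are matching columns, its length is at
least ``min_len`` and its mismatch count is at most (1-min_identity)*L.
We report valid windows that are maximal by inclusion on their diagonal.

Candidate diagonals are located with exact seeds of length ``seed_k``; on
each seeded diagonal, enumeration of maximal windows is exact within a
padded neighbourhood of the seed cluster. N never matches anything.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .util import seq_to_array

_N = ord("N")


@dataclass(frozen=True)
class DiagonalMatch:
    """A maximal high-identity match: a[i : i+length] vs b[j : j+length]."""

    i: int
    j: int
    length: int
    mismatches: int

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.length


def seed_diagonals(a: str, b: str, k: int) -> dict[int, list[int]]:
    """Diagonals (j - i) holding at least one exact k-mer match, with the
    a-side seed start positions found on each."""
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(b) - k + 1):
        kmer = b[j : j + k]
        if "N" not in kmer:
            index[kmer].append(j)
    hits: dict[int, list[int]] = defaultdict(list)
    for i in range(len(a) - k + 1):
        kmer = a[i : i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            hits[j - i].append(i)
    return hits


def _diagonal_match_array(av: np.ndarray, bv: np.ndarray, d: int, lo: int, hi: int):
    """Boolean match array for diagonal d over a-positions [lo, hi)."""
    i0 = max(lo, 0, -d)
    i1 = min(hi, len(av), len(bv) - d)
    if i1 <= i0:
        return i0, np.zeros(0, dtype=bool)
    seg_a = av[i0:i1]
    seg_b = bv[i0 + d : i1 + d]
    return i0, (seg_a == seg_b) & (seg_a != _N)


def maximal_windows(
    match: np.ndarray, min_len: int, min_identity: float
) -> list[tuple[int, int, int]]:
    """Maximal-by-inclusion valid windows in a boolean match array.

    Returns (start, end, mismatches) with inclusive indices into ``match``.
    """
    if match.size == 0:
        return []
    q = 1.0 - min_identity
    mism = (~match).astype(np.int64)
    # g[y] = cum_mism(0..y) - q*(y+1); window (x,y) valid iff g[y] - g[x-1] <= eps
    g = np.cumsum(mism) - q * (np.arange(match.size) + 1)
    g_prev = np.concatenate(([0.0], g[:-1]))  # g[x-1] aligned with x
    pos = np.flatnonzero(match)
    if pos.size == 0:
        return []
    g_at = g[pos]
    # suffix minima over match positions -> non-decreasing array, binary searchable
    sm = np.minimum.accumulate(g_at[::-1])[::-1]
    eps = 1e-9
    candidates: list[tuple[int, int, int]] = []
    cum = np.concatenate(([0], np.cumsum(mism)))
    for xi in range(pos.size):
        x = pos[xi]
        thr = g_prev[x] + eps
        # largest index j in sm[xi:] with sm[j] <= thr
        lo_i, hi_i = xi, sm.size
        if sm[xi] > thr:
            continue
        while hi_i - lo_i > 1:
            mid = (lo_i + hi_i) // 2
            if sm[mid] <= thr:
                lo_i = mid
            else:
                hi_i = mid
        # walk back from lo_i to the nearest qualifying y (lo_i qualifies by construction
        # of the suffix minima boundary, but guard anyway)
        yi = lo_i
        while yi >= xi and g_at[yi] > thr:
            yi -= 1
        if yi < xi:
            continue
        y = pos[yi]
        if y - x + 1 >= min_len:
            candidates.append((int(x), int(y), int(cum[y + 1] - cum[x])))
    # containment filter: keep windows whose end exceeds every earlier end
    maximal: list[tuple[int, int, int]] = []
    best_end = -1
    for x, y, m in candidates:  # candidates sorted by x
        if y > best_end:
            maximal.append((x, y, m))
            best_end = y
    # end-trim: a maximal window may have soaked up sparse chance matches at
    # its flanks on the global mismatch budget; drop terminal match-run units
    # whose local identity (run / (run + adjacent gap)) is below the floor
    out: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for x, y, _ in maximal:
        trimmed = _trim_window(match, x, y, min_len, min_identity)
        if trimmed is not None and (trimmed[0], trimmed[1]) not in seen:
            seen.add((trimmed[0], trimmed[1]))
            out.append(trimmed)
    return out


def _trim_window(
    match: np.ndarray, x: int, y: int, min_len: int, min_identity: float
) -> tuple[int, int, int] | None:
    pos = np.flatnonzero(match[x : y + 1]) + x
    if pos.size == 0:
        return None
    # match runs as (start, end) pairs
    breaks = np.flatnonzero(np.diff(pos) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [pos.size - 1]))
    runs = [(int(pos[s]), int(pos[e])) for s, e in zip(starts, ends)]
    eps = 1e-9
    lo, hi = 0, len(runs) - 1
    changed = True
    while changed and lo < hi:
        changed = False
        m0 = runs[lo][1] - runs[lo][0] + 1
        g0 = runs[lo + 1][0] - runs[lo][1] - 1
        if m0 / (m0 + g0) < min_identity - eps:
            lo += 1
            changed = True
        if lo < hi:
            mk = runs[hi][1] - runs[hi][0] + 1
            gk = runs[hi][0] - runs[hi - 1][1] - 1
            if mk / (mk + gk) < min_identity - eps:
                hi -= 1
                changed = True
    nx, ny = runs[lo][0], runs[hi][1]
    length = ny - nx + 1
    if length < min_len:
        return None
    n_match = sum(e - s + 1 for s, e in runs[lo : hi + 1])
    mism = length - n_match
    if mism > (1.0 - min_identity) * length + eps:
        return None
    return nx, ny, mism


def find_diagonal_repeats(
    a: str,
    b: str,
    min_len: int,
    min_identity: float,
    seed_k: int = 11,
    cluster_gap: int = 1000,
    pad: int = 5000,
) -> list[DiagonalMatch]:
    """All maximal high-identity Hamming matches between a and b found via
    exact seeds of length ``seed_k`` (clipped to min_len)."""
    seed_k = min(seed_k, min_len)
    av, bv = seq_to_array(a), seq_to_array(b)
    hits = seed_diagonals(a, b, seed_k)
    out: list[DiagonalMatch] = []
    for d, starts in hits.items():
        starts.sort()
        # merge seed starts into clusters
        clusters: list[list[int]] = []
        for s in starts:
            if clusters and s - clusters[-1][1] <= cluster_gap:
                clusters[-1][1] = s
            else:
                clusters.append([s, s])
        seen: set[tuple[int, int]] = set()
        for clo, chi in clusters:
            i0, match = _diagonal_match_array(av, bv, d, clo - pad, chi + seed_k + pad)
            for x, y, m in maximal_windows(match, min_len, min_identity):
                key = (i0 + x, i0 + y)
                if key not in seen:
                    seen.add(key)
                    out.append(
                        DiagonalMatch(i=i0 + x, j=i0 + x + d, length=y - x + 1, mismatches=m)
                    )
    out.sort(key=lambda w: (w.i, w.j))
    return out


def longest_common_window(
    a: str, b: str, min_len: int, min_identity: float, seed_k: int
) -> list[DiagonalMatch]:
    """Convenience: all maximal matches, longest first."""
    ws = find_diagonal_repeats(a, b, min_len, min_identity, seed_k=seed_k)
    return sorted(ws, key=lambda w: -w.length)
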