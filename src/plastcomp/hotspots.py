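"""Binning of mutational events along a reference and correlation /
co-occurrence analysis among substitutions, InDels and oligonucleotide
repeats.

Events are histogrammed into fixed bins of 250 bp (default) anchored at
position 1; each repeat *copy* contributes one count at its start. Pearson
product-moment correlations are computed over all bins (empty bins
included by default), and correlation strength is labelled on the
conventional absolute-value scale ending at "perfect" for |r| = 1.

Co-occurrence of X with Y is, by default, the percentage of X *events*
lying in bins that contain at least one Y event; a bin-level variant
(percentage of X-bearing bins that also bear Y) is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alignment import IndelEvent, SubstitutionEvent
from .repeats import OligoRepeat

DEFAULT_BIN_SIZE = 250

STRENGTH_BANDS = (
    (0.10, "none"),
    (0.20, "negligible/very weak"),
    (0.30, "weak"),
    (0.40, "moderate"),
    (0.70, "strong"),
    (1.00, "very strong"),
)


@dataclass(frozen=True)
class BinnedEventTracks:
    ref_id: str
    ref_length: int
    bin_size: int
    substitutions: np.ndarray
    indels: np.ndarray
    repeats: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.substitutions)


@dataclass(frozen=True)
class CorrelationReport:
    r_sub_indel: float | None
    r_indel_repeat: float | None
    r_sub_repeat: float | None
    label_sub_indel: str
    label_indel_repeat: str
    label_sub_repeat: str
    cooccur_sub_with_indel: float | None  # % of substitutions in InDel-bearing bins
    cooccur_indel_with_repeat: float | None
    cooccur_sub_with_repeat: float | None


def _positions(events, ref_length: int, what: str) -> list[int]:
    pos = []
    for ev in events:
        if isinstance(ev, SubstitutionEvent):
            p = ev.ref_pos
        elif isinstance(ev, IndelEvent):
            p = ev.ref_pos
        elif isinstance(ev, OligoRepeat):
            raise TypeError("pass repeat copies through bin_events, not _positions")
        else:
            p = int(ev)
        if not 1 <= p <= ref_length:
            raise ValueError(f"{what} coordinate {p} outside [1, {ref_length}]")
        pos.append(p)
    return pos


def bin_events(
    substitutions,
    indels,
    repeats,
    ref_length: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    ref_id: str = "ref",
) -> BinnedEventTracks:
    """Histogram events into [1,250], [251,500], ... bins (final partial bin
    retained). ``repeats`` may be OligoRepeat objects — each *copy* counts —
    or plain integer positions."""
    n_bins = math.ceil(ref_length / bin_size)
    sub_pos = _positions(substitutions, ref_length, "substitution")
    ind_pos = _positions(indels, ref_length, "indel")
    rep_pos: list[int] = []
    for r in repeats:
        if isinstance(r, OligoRepeat):
            rep_pos.extend((r.pos1, r.pos2))
        else:
            rep_pos.append(int(r))
    for p in rep_pos:
        if not 1 <= p <= ref_length:
            raise ValueError(f"repeat coordinate {p} outside [1, {ref_length}]")
    edges = np.arange(0, n_bins * bin_size + 1, bin_size)

    def hist(pos):
        return np.histogram(np.asarray(pos, dtype=float) - 0.5, bins=edges)[0]

    return BinnedEventTracks(
        ref_id=ref_id,
        ref_length=ref_length,
        bin_size=bin_size,
        substitutions=hist(sub_pos),
        indels=hist(ind_pos),
        repeats=hist(rep_pos),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if len(x) < 3:
        raise ValueError("need at least 3 bins for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def correlate_tracks(tracks: BinnedEventTracks) -> tuple[float | None, float | None, float | None]:
    """(r_sub_indel, r_indel_repeat, r_sub_repeat) over all bins; None for a
    zero-variance track."""
    s, i, r = tracks.substitutions, tracks.indels, tracks.repeats
    return _pearson(s, i), _pearson(i, r), _pearson(s, r)


def strength_label(r: float | None) -> str:
    """Label |r| on half-open bands: [0,0.1) none, [0.1,0.2) negligible/very
    weak, [0.2,0.3) weak, [0.3,0.4) moderate, [0.4,0.7) strong, [0.7,1.0)
    very strong, 1.0 perfect."""
    if r is None or (isinstance(r, float) and math.isnan(r)):
        return "undefined"
    a = abs(r)
    if a > 1:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    for upper, label in STRENGTH_BANDS:
        if a < upper:
            return label
    return "perfect"


def cooccurrence(
    tracks: BinnedEventTracks, bin_level: bool = False
) -> tuple[float | None, float | None, float | None]:
    """Percentages (2 dp): substitutions with InDels, InDels with repeats,
    substitutions with repeats.

    Event-level (default): share of X events in bins containing >=1 Y event.
    Bin-level: share of X-bearing bins that also bear Y.
    """

    def pct(x: np.ndarray, y: np.ndarray) -> float | None:
        if bin_level:
            denom = int((x > 0).sum())
            numer = int(((x > 0) & (y > 0)).sum())
        else:
            denom = int(x.sum())
            numer = int(x[y > 0].sum())
        if denom == 0:
            return None
        return round(100.0 * numer / denom, 2)

    s, i, r = tracks.substitutions, tracks.indels, tracks.repeats
    return pct(s, i), pct(i, r), pct(s, r)


def correlation_report(tracks: BinnedEventTracks, bin_level: bool = False) -> CorrelationReport:
    r_si, r_ir, r_sr = correlate_tracks(tracks)
    c_si, c_ir, c_sr = cooccurrence(tracks, bin_level=bin_level)
    return CorrelationReport(
        r_sub_indel=None if r_si is None else round(r_si, 2),
        r_indel_repeat=None if r_ir is None else round(r_ir, 2),
        r_sub_repeat=None if r_sr is None else round(r_sr, 2),
        label_sub_indel=strength_label(r_si),
        label_indel_repeat=strength_label(r_ir),
        label_sub_repeat=strength_label(r_sr),
        cooccur_sub_with_indel=c_si,
        cooccur_indel_with_repeat=c_ir,
        cooccur_sub_with_repeat=c_sr,
    )
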