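"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of an upper-case DNA string for vectorized comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def gc_fraction(seq: str) -> float:
    """GC over unambiguous bases; N excluded from numerator and denominator."""
    g = seq.count("G") + seq.count("C")
    acgt = g + seq.count("A") + seq.count("T")
    return g / acgt if acgt else float("nan")


def interval_len(iv: tuple[int, int]) -> int:
    return iv[1] - iv[0] + 1
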