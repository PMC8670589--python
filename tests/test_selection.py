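import math
import warnings

import numpy as np
import pytest

from plastcomp.selection import (
    InternalStopError,
    categorize_selection,
    codon_align,
    codon_profile,
    gene_selection,
    ng86,
    translate,
)
from plastcomp.simulate import simulate_codon_pair

warnings.filterwarnings("ignore", category=Warning, module="Bio")


def _codons(s):
    return [s[i : i + 3] for i in range(0, len(s), 3)]


def test_identical_sequences_zero_rates():
    cds = "ATGTTTAAACCCGGG"
    ka, ks = ng86(list(zip(_codons(cds), _codons(cds))))
    assert ka == 0.0 and ks == 0.0


def test_single_codon_synonymous_change_hand_computed():
    """TTT->TTC (Phe->Phe): Sd=1, Nd=0; S=1/3 per codon so pS=3 exceeds the
    Jukes-Cantor horizon and ks is undefined."""
    ka, ks = ng86([("TTT", "TTC")])
    assert ka == 0.0
    assert ks is None  # pS = 1 / (1/3) >= 3/4


def test_ng86_matches_biopython_oracle():
    """Implementation agrees with the independent Bio.codonalign NG86 oracle
    on simulated pairs."""
    from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    rng = np.random.default_rng(99)
    for _ in range(6):
        a, b = simulate_codon_pair(150, omega=0.4, mu=0.05, rng=rng)
        ka, ks = ng86(list(zip(_codons(a), _codons(b))))
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert ka == pytest.approx(dn, abs=1e-9)
        assert ks == pytest.approx(ds, abs=1e-9)


def test_ng86_symmetric():
    rng = np.random.default_rng(5)
    a, b = simulate_codon_pair(120, omega=0.5, mu=0.06, rng=rng)
    assert ng86(list(zip(_codons(a), _codons(b)))) == ng86(list(zip(_codons(b), _codons(a))))


def test_pure_synonymous_edits_give_zero_ka():
    # one third-position synonymous change in ten codons
    a = "ATGCTTCCTGGTAAAATGCTTCCTGGTAAA"
    b = "ATGCTACCTGGTAAAATGCTTCCTGGTAAA"  # CTT->CTA (Leu->Leu)
    ka, ks = ng86(list(zip(_codons(a), _codons(b))))
    assert ka == 0.0
    assert ks is not None and ks > 0


def test_pure_nonsynonymous_edits_give_zero_ks():
    a = "ATGCTTCCT"
    b = "ATGGTTACT"  # L->V, P->T at first positions
    ka, ks = ng86(list(zip(_codons(a), _codons(b))))
    assert ks == 0.0
    assert ka is not None and ka > 0


def test_codon_align_trims_stops_and_excludes_gapped_codons():
    ref = "ATGAAACCCGGGTTTTAA"
    qry = "ATGAAACCCTTTTAA"  # one codon (GGG) missing
    pairs = codon_align(ref, qry, gene="demo")
    assert len(pairs) == 4  # stop trimmed; unaligned codon excluded
    assert ("TTT", "TTT") in pairs


def test_codon_align_internal_stop_named():
    with pytest.raises(InternalStopError, match="demo"):
        codon_align("ATGTAAAAATGA", "ATGAAAAAATGA", gene="demo")


def test_selection_categories_banding():
    assert categorize_selection(1.92) == "positive"
    assert categorize_selection(1.23) == "positive"
    assert categorize_selection(0.96) == "neutral"
    assert categorize_selection(0.86) == "~neutral"
    assert categorize_selection(0.50) == "purifying"
    assert categorize_selection(None) == "unclassified"


def test_omega_recovery_simulation():
    """Pooled NG86 estimates recover the simulated omega=0.2 within 0.05."""
    rng = np.random.default_rng(7)
    kas, kss = [], []
    for _ in range(120):
        a, b = simulate_codon_pair(200, omega=0.2, mu=0.05, rng=rng)
        ka, ks = ng86(list(zip(_codons(a), _codons(b))))
        if ka is not None and ks is not None:
            kas.append(ka)
            kss.append(ks)
    est = np.mean(kas) / np.mean(kss)
    assert abs(est - 0.2) <= 0.05


def test_codon_profile_simple_cds():
    prof = codon_profile(["ATGTTAAGA"])  # Met Leu Arg
    nz = {k: v for k, v in prof.codon_counts.items() if v}
    assert nz == {"ATG": 1, "TTA": 1, "AGA": 1}
    assert prof.aa_frequencies["M"] == pytest.approx(1 / 3)
    assert prof.aa_frequencies["L"] == pytest.approx(1 / 3)
    assert prof.aa_frequencies["R"] == pytest.approx(1 / 3)
    assert sum(prof.aa_frequencies.values()) == pytest.approx(1.0)


def test_rscu_family_mean_is_one(rng):
    from plastcomp.simulate import _random_orf

    cds = [_random_orf(rng, 600) for _ in range(20)]
    prof = codon_profile(cds)
    families = {}
    from plastcomp.selection import CODON_TO_AA

    for codon, aa in CODON_TO_AA.items():
        if aa != "*":
            families.setdefault(aa, []).append(codon)
    for aa, codons in families.items():
        if len(codons) < 2:
            continue
        vals = [prof.rscu[c] for c in codons]
        if any(math.isnan(v) for v in vals):
            continue
        assert np.mean(vals) == pytest.approx(1.0)


def test_codon_profile_skips_ambiguous_codons():
    with pytest.warns(UserWarning):
        prof = codon_profile(["ATGNNNAAA"])
    assert prof.skipped_codons == 1
    assert prof.codon_counts["AAA"] == 1


def test_gene_selection_end_to_end():
    rng = np.random.default_rng(3)
    a, b = simulate_codon_pair(300, omega=0.1, mu=0.06, rng=rng)
    est = gene_selection("demo", "ATG" + a + "TAA", "ATG" + b + "TAA")
    assert est.gene == "demo"
    assert est.category in {"purifying", "~neutral", "neutral", "positive", "unclassified"}
    assert est.ka is not None and est.ka >= 0
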